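"""Shared fixtures: brute-force oracles and the hand-built sweep dataset."""

from itertools import combinations

import numpy as np
import pytest

import sweepscan as sw
from sweepscan.pipeline import RunConfig, run_scan
from sweepscan.simulate import FIXTURE_SCAN_PARAMS, write_sweep_fixture

DATA_DIR = __import__("pathlib").Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the library implementations)
# ---------------------------------------------------------------------------


def bf_mean_pairwise(entries) -> float:
    entries = np.asarray(entries)
    k = entries.shape[0]
    if k < 2:
        return 0.0
    total = sum((entries[i] != entries[j]).sum() for i, j in combinations(range(k), 2))
    return total / (k * (k - 1) / 2)


def bf_sfs(entries) -> np.ndarray:
    entries = np.asarray(entries)
    n = entries.shape[0]
    xi = np.zeros(n - 1, dtype=int)
    for col in entries.T:
        c = int(col.sum())
        if 0 < c < n:
            xi[c - 1] += 1
    return xi


def bf_thetas(xi, n):
    """Direct evaluation of the defining sums."""
    xi = np.asarray(xi, dtype=float)
    i = np.arange(1, n)
    pairs = n * (n - 1) / 2
    a_n = sum(1.0 / k for k in range(1, n))
    return (
        float((xi * i * (n - i)).sum() / pairs),  # pi
        float((xi * i * i).sum() / pairs),  # theta_H
        float((xi * i).sum() / (n - 1)),  # theta_L
        float(xi.sum() / a_n),  # theta_W
    )


def bf_wc_fst(n1, d1, n2, d2) -> float:
    """Weir-Cockerham 1984 via the a/b variance-component route (r = 2,
    haploid), algebraically distinct from the ANOVA mean-square form."""
    r = 2
    p1, p2 = d1 / n1, d2 / n2
    nbar = (n1 + n2) / 2
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    inner = pbar * (1 - pbar) - s2 * (r - 1) / r
    a = (nbar / nc) * (s2 - inner / (nbar - 1))
    b = (nbar / (nbar - 1)) * inner
    return a / (a + b)


def bf_ld_r2(col_a, col_b) -> float:
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    n = a.size
    pab = float(((a == 1) & (b == 1)).sum()) / n
    pa, pb = a.mean(), b.mean()
    d = pab - pa * pb
    with np.errstate(invalid="ignore", divide="ignore"):
        return d * d / (pa * (1 - pa) * pb * (1 - pb))


def bf_dind(entries, positions, focal, n_flank, min_flank):
    """DIND via explicit nearest-site selection and pair enumeration.

    Returns (ipi_a, ipi_d) or None when the flanking requirement fails.
    """
    entries = np.asarray(entries)
    n = entries.shape[0]
    counts = entries.sum(axis=0)
    poly = [j for j in range(entries.shape[1]) if 0 < counts[j] < n]
    up = sorted(
        (j for j in poly if positions[j] < positions[focal]),
        key=lambda j: (positions[focal] - positions[j], positions[j]),
    )[:n_flank]
    down = sorted(
        (j for j in poly if positions[j] > positions[focal]),
        key=lambda j: (positions[j] - positions[focal], positions[j]),
    )[:n_flank]
    if len(up) < min_flank or len(down) < min_flank:
        return None
    cols = sorted(up + down)
    anc = entries[entries[:, focal] == 0][:, cols]
    der = entries[entries[:, focal] == 1][:, cols]
    return bf_mean_pairwise(anc), bf_mean_pairwise(der)


def bf_parsimony_ancestral(human_alleles, chimp, orang, mac):
    """Exhaustive small-parsimony oracle on (((human, chimp), orang), mac).

    Enumerates all labelings of the three internal nodes, minimizes the
    number of changes, and returns the human-chimp-ancestor state when
    it is unique across minimal labelings and present in the human
    sample; otherwise None (unresolved).
    """
    nucs = "ACGT"
    best_cost = None
    best_x: set = set()
    for x in nucs:
        for y in nucs:
            for z in nucs:
                cost = (
                    (0 if x in human_alleles else 1)
                    + (x != chimp)
                    + (x != y)
                    + (y != orang)
                    + (y != z)
                    + (z != mac)
                )
                if best_cost is None or cost < best_cost:
                    best_cost, best_x = cost, {x}
                elif cost == best_cost:
                    best_x.add(x)
    if len(best_x) == 1:
        (x,) = best_x
        if x in human_alleles:
            return x
    return None


def random_poly_matrix(rng, n_rows, n_cols):
    """Random 0/1 matrix with every column polymorphic."""
    m = rng.integers(0, 2, size=(n_rows, n_cols)).astype(np.int8)
    for j in range(n_cols):
        if m[:, j].sum() in (0, n_rows):
            m[rng.integers(n_rows), j] = 1 - m[0, j]
    return m


# ---------------------------------------------------------------------------
# shared datasets
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def sweep_fixture():
    return sw.make_sweep_fixture()


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """The sweep fixture pushed through the full file-based pipeline."""
    base = tmp_path_factory.mktemp("fixture")
    fxp = write_sweep_fixture(base)
    cfg = RunConfig(out_dir=str(base / "out"), seed=11, inputs=fxp["inputs"], **FIXTURE_SCAN_PARAMS)
    report = run_scan(cfg)
    return {
        "config": cfg,
        "report": report,
        "out_dir": base / "out",
        "base": base,
        "expected": fxp["expected"],
        "inputs": fxp["inputs"],
    }
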