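"""Per-SNP and per-window population-genetic statistics.

Everything here is computed from first principles on phased, polarized
haplotypes:

* Weir & Cockerham's F_ST (variance-components ANOVA on chromosome
  counts, appropriate for phased data),
* the unfolded site-frequency spectrum and the theta estimators built
  from it (pi, theta_H, theta_L, Watterson's theta_W),
* Fay & Wu's H and its variance-normalized form DH,
* DIND (derived intra-allelic nucleotide diversity): the ratio of mean
  pairwise flanking diversity among ancestral-allele carriers to that
  among derived-allele carriers at a focal SNP,
* linkage disequilibrium r^2 from haplotype counts.

A recently swept derived allele sits on a single haplotype background,
so its carriers show almost no flanking diversity (iπ_D ≈ 0) while
ancestral carriers retain normal diversity: DIND = iπ_A/iπ_D blows up.
DH turns negative when high-frequency derived variants are in excess,
the hallmark of hitchhiking around a (near-)completed sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING, HaplotypeMatrix

__all__ = [
    "SfsSummary",
    "ThetaSet",
    "DindResult",
    "wc_fst",
    "wc_fst_arrays",
    "mean_pairwise_diff",
    "unfolded_sfs",
    "theta_estimators",
    "fay_wu_h",
    "normalized_dh",
    "normalized_dh_from_sfs_vector",
    "dind",
    "ld_r2",
]


# ---------------------------------------------------------------------------
# site-frequency spectrum containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SfsSummary:
    """Unfolded site-frequency spectrum of one population sample.

    ``xi[i - 1]`` counts the segregating sites whose derived allele is
    carried by exactly ``i`` of the ``n`` chromosomes (i = 1..n-1).
    """

    n: int
    xi: np.ndarray

    def __post_init__(self) -> None:
        xi = np.asarray(self.xi, dtype=np.int64)
        object.__setattr__(self, "xi", xi)
        if self.n < 2:
            raise ValueError("SFS requires n >= 2 chromosomes")
        if xi.shape != (self.n - 1,):
            raise ValueError(f"xi must have length n - 1 = {self.n - 1}")
        if (xi < 0).any():
            raise ValueError("SFS counts must be non-negative")

    @property
    def S(self) -> int:
        """Number of segregating sites."""
        return int(self.xi.sum())


@dataclass(frozen=True)
class ThetaSet:
    """Estimators of the population mutation rate from one SFS."""

    theta_pi: float
    theta_H: float
    theta_L: float
    theta_W: float


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n + 1)))


def unfolded_sfs(matrix: HaplotypeMatrix, rows: np.ndarray | None = None) -> SfsSummary:
    """Unfolded SFS of the given chromosome rows (all sites polarized).

    Sites fixed ancestral or fixed derived in the subsample do not
    segregate and contribute nothing. Missing calls are not supported
    here: the SFS needs a constant sample size per site.
    """
    sub = matrix.entries if rows is None else matrix.entries[rows]
    if (sub == MISSING).any():
        raise ValueError("unfolded SFS requires complete (no-missing) haplotypes")
    n = sub.shape[0]
    if n < 2:
        raise ValueError("SFS requires at least two chromosomes")
    counts = sub.sum(axis=0)
    seg = counts[(counts > 0) & (counts < n)]
    xi = np.bincount(seg, minlength=n)[1:n]
    return SfsSummary(n=n, xi=xi)


def theta_estimators(sfs: SfsSummary) -> ThetaSet:
    """pi, theta_H, theta_L and Watterson's theta_W from the SFS.

    theta_pi = sum_i xi_i * i * (n - i) / C(n, 2)
    theta_H  = sum_i xi_i * i^2 / C(n, 2)
    theta_L  = sum_i xi_i * i / (n - 1)
    theta_W  = S / a_n,  a_n = sum_{i<n} 1/i

    The identity theta_pi + theta_H = 2 * theta_L holds exactly.
    """
    n = sfs.n
    i = np.arange(1, n, dtype=np.float64)
    xi = sfs.xi.astype(np.float64)
    pairs = n * (n - 1) / 2.0
    theta_pi = float((xi * i * (n - i)).sum() / pairs)
    theta_H = float((xi * i * i).sum() / pairs)
    theta_L = float((xi * i).sum() / (n - 1))
    theta_W = float(sfs.S / _harmonic(n - 1))
    return ThetaSet(theta_pi, theta_H, theta_L, theta_W)


def fay_wu_h(sfs: SfsSummary) -> float:
    """Fay & Wu's H = theta_pi - theta_H (NaN when S = 0)."""
    if sfs.S == 0:
        return math.nan
    t = theta_estimators(sfs)
    return t.theta_pi - t.theta_H


def normalized_dh(sfs: SfsSummary) -> float:
    """Variance-normalized Fay & Wu's H (the DH statistic).

    DH = (theta_pi - theta_L) / sqrt(Var(theta_pi - theta_L)) with the
    neutral-model variance

        Var = (n - 2) / (6 (n - 1)) * theta
            + [18 n^2 (3n + 2) b_{n+1} - (88 n^3 + 9 n^2 - 13 n + 6)]
              / (9 n (n - 1)^2) * theta^2

    where b_n = sum_{i<n} 1/i^2, theta is estimated by Watterson's
    theta_W and theta^2 by S (S - 1) / (a_n^2 + b_n). Note theta_pi -
    theta_L = (theta_pi - theta_H) / 2, so DH carries the sign of Fay &
    Wu's H. Returns NaN when S = 0 or the variance estimate is 0.
    """
    if sfs.S == 0:
        return math.nan
    n = sfs.n
    t = theta_estimators(sfs)
    var = _dh_variance(n, sfs.S)
    if var <= 0:
        return math.nan
    return (t.theta_pi - t.theta_L) / math.sqrt(var)


def _dh_variance(n: int, S: int) -> float:
    an = _harmonic(n - 1)
    bn = _harmonic(n - 1, 2)
    bn1 = bn + 1.0 / n**2
    theta = S / an
    theta2 = S * (S - 1) / (an**2 + bn)
    v1 = (n - 2) / (6.0 * (n - 1)) * theta
    v2 = (
        (18.0 * n**2 * (3 * n + 2) * bn1 - (88.0 * n**3 + 9 * n**2 - 13 * n + 6))
        / (9.0 * n * (n - 1) ** 2)
        * theta2
    )
    return v1 + v2


def normalized_dh_from_sfs_vector(xi, n: int) -> float:
    """Convenience wrapper taking a raw xi vector of length n - 1."""
    return normalized_dh(SfsSummary(n=n, xi=np.asarray(xi)))


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def wc_fst_arrays(n1, d1, n2, d2):
    """Vectorized Weir & Cockerham (1984) F_ST on chromosome counts.

    Haploid (allele-count) ANOVA formulation for two samples with n_i
    called chromosomes of which d_i carry one allele:

        MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
        n_c = (n_tot - sum n_i^2 / n_tot) / (r - 1)
        F_ST = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    with r = 2 samples. Negative estimates are returned as-is so
    empirical ranking stays monotone. Sites monomorphic in the pooled
    sample (or with n_i < 2) give NaN.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    d1 = np.asarray(d1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    d2 = np.asarray(d2, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = d1 / n1
        p2 = d2 / n2
        ntot = n1 + n2
        pbar = (d1 + d2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        nc = ntot - (n1**2 + n2**2) / ntot
        denom = msp + (nc - 1) * msg
        fst = (msp - msg) / denom
    pooled_poly = (d1 + d2 > 0) & (d1 + d2 < ntot)
    ok = pooled_poly & (n1 >= 2) & (n2 >= 2)
    return np.where(ok, fst, np.nan)


def wc_fst(n1: int, d1: int, n2: int, d2: int) -> float:
    """Scalar Weir & Cockerham F_ST; see :func:`wc_fst_arrays`."""
    return float(wc_fst_arrays(n1, d1, n2, d2))


# ---------------------------------------------------------------------------
# pairwise diversity and DIND
# ---------------------------------------------------------------------------


def mean_pairwise_diff(entries: np.ndarray) -> float:
    """Average Hamming distance over all unordered chromosome pairs.

    ``entries`` is a rows x sites 0/1 block (rows already restricted to
    the group of interest). Defined as 0 for fewer than two rows. With
    missing calls present, each site contributes the mean difference
    over the pairs called at that site (pairwise deletion).
    """
    entries = np.asarray(entries)
    k = entries.shape[0]
    if k < 2:
        return 0.0
    if not (entries == MISSING).any():
        d = (entries == 1).sum(axis=0)
        return float((d * (k - d)).sum() / (k * (k - 1) / 2.0))
    total = 0.0
    for col in entries.T:
        obs = col[col != MISSING]
        m = obs.size
        if m < 2:
            continue
        d = int((obs == 1).sum())
        total += d * (m - d) / (m * (m - 1) / 2.0)
    return float(total)


@dataclass(frozen=True)
class DindResult:
    """DIND outcome at one focal SNP in one population.

    ``value`` is iπ_A / iπ_D when defined. ``sentinel`` is True when
    iπ_D = 0; the numeric value is then left NaN until the class-level
    zero rule (class maximum + 20) resolves it against a null
    distribution. ``available`` is False when the flanking requirement
    could not be met, with ``reason`` saying why.
    """

    focal_pos: int
    ipi_a: float = math.nan
    ipi_d: float = math.nan
    value: float = math.nan
    sentinel: bool = False
    daf: float = math.nan
    n_flank_used: int = 0
    available: bool = True
    reason: str = ""


def dind(
    matrix: HaplotypeMatrix,
    focal: int,
    rows: np.ndarray | None = None,
    n_flank: int = 20,
    min_flank: int = 10,
) -> DindResult:
    """DIND at site column ``focal`` among the given chromosome rows.

    The flanking set is the ``n_flank`` nearest polymorphic sites (in
    these rows) upstream plus the same number downstream of the focal
    site, the focal site excluded; near region edges fewer are accepted
    down to ``min_flank`` per side, below which the result is
    not-available. Carrier groups with fewer than two chromosomes have
    mean pairwise diversity 0 by convention, so a singleton derived
    allele is a sentinel.
    """
    sub = matrix.entries if rows is None else matrix.entries[rows]
    col = sub[:, focal]
    called = col != MISSING
    n_called = int(called.sum())
    n_derived = int((col == 1).sum())
    if n_derived == 0 or n_derived == n_called:
        raise ValueError(f"focal site {focal} is monomorphic in the given rows")
    pos = int(matrix.positions[focal])

    derived, ncall = _column_counts(sub)
    poly = (derived > 0) & (derived < ncall)
    poly_idx = np.flatnonzero(poly)
    j = int(np.searchsorted(poly_idx, focal))
    up = poly_idx[max(0, j - n_flank) : j]
    down = poly_idx[j + 1 : j + 1 + n_flank]
    if len(up) < min_flank or len(down) < min_flank:
        return DindResult(
            focal_pos=pos,
            daf=n_derived / n_called,
            available=False,
            reason=f"only {len(up)} upstream / {len(down)} downstream flanking variants "
            f"(minimum {min_flank} per side)",
        )
    cols = np.concatenate([up, down])
    ipi_a = mean_pairwise_diff(sub[col == 0][:, cols])
    ipi_d = mean_pairwise_diff(sub[col == 1][:, cols])
    if ipi_d == 0.0:
        return DindResult(
            focal_pos=pos,
            ipi_a=ipi_a,
            ipi_d=0.0,
            sentinel=True,
            daf=n_derived / n_called,
            n_flank_used=len(cols),
        )
    return DindResult(
        focal_pos=pos,
        ipi_a=ipi_a,
        ipi_d=ipi_d,
        value=ipi_a / ipi_d,
        daf=n_derived / n_called,
        n_flank_used=len(cols),
    )


def _column_counts(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = (sub != MISSING).sum(axis=0)
    derived = (sub == 1).sum(axis=0)
    return derived, called


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """r^2 between two site columns over phased chromosomes.

    r^2 = D^2 / (pA (1-pA) pB (1-pB)) with D = pAB - pA pB from
    haplotype counts. Rows missing at either site are excluded pairwise.
    NaN when either site is monomorphic among the retained rows.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    keep = (a != MISSING) & (b != MISSING)
    a = a[keep].astype(np.float64)
    b = b[keep].astype(np.float64)
    if a.size == 0:
        return math.nan
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return math.nan
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))
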