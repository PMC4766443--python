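"""Per-SNP statistics against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sweepscan as sw
from sweepscan import stats
from sweepscan.datatypes import HaplotypeMatrix, PopulationPanel

from conftest import (
    bf_dind,
    bf_ld_r2,
    bf_mean_pairwise,
    bf_wc_fst,
    random_poly_matrix,
)


def _matrix(entries, positions=None):
    entries = np.asarray(entries, dtype=np.int8)
    n_samples = entries.shape[0] // 2
    ids = [f"s{i}" for i in range(n_samples)]
    panel = PopulationPanel({i: "p0" for i in ids})
    pos = positions if positions is not None else np.arange(1, entries.shape[1] + 1) * 10
    return HaplotypeMatrix(entries, pos, ids, panel)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n1,d1,n2,d2,expected",
    [
        (20, 20, 20, 0, 1.0),  # fixed difference
        (12, 9, 12, 0, 8.0 / 11.0),  # hand-derived mean-square evaluation
    ],
)
def test_wc_fst_known_values(n1, d1, n2, d2, expected):
    assert sw.wc_fst(n1, d1, n2, d2) == pytest.approx(expected, abs=1e-12)


def test_wc_fst_equal_frequencies_negative():
    # zero among-population variance but positive within-population mean square
    assert sw.wc_fst(20, 10, 20, 10) < 0


def test_wc_fst_monomorphic_pooled_is_nan():
    assert math.isnan(sw.wc_fst(20, 0, 20, 0))
    assert math.isnan(sw.wc_fst(20, 20, 20, 20))


def test_wc_fst_matches_variance_component_oracle():
    rng = np.random.default_rng(7)
    for _ in range(300):
        n1, n2 = rng.integers(2, 41, size=2)
        d1 = int(rng.integers(0, n1 + 1))
        d2 = int(rng.integers(0, n2 + 1))
        if d1 + d2 == 0 or d1 + d2 == n1 + n2:
            continue
        assert sw.wc_fst(n1, d1, n2, d2) == pytest.approx(
            bf_wc_fst(n1, d1, n2, d2), abs=1e-12
        )


def test_wc_fst_bounds_and_fixed_difference_characterization():
    rng = np.random.default_rng(8)
    for _ in range(300):
        n1, n2 = rng.integers(2, 21, size=2)
        d1 = int(rng.integers(0, n1 + 1))
        d2 = int(rng.integers(0, n2 + 1))
        if d1 + d2 == 0 or d1 + d2 == n1 + n2:
            continue
        v = sw.wc_fst(n1, d1, n2, d2)
        assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12
        fixed_diff = (d1 == n1 and d2 == 0) or (d1 == 0 and d2 == n2)
        assert (abs(v - 1.0) < 1e-12) == fixed_diff


# ---------------------------------------------------------------------------
# diversity / SFS / theta / H
# ---------------------------------------------------------------------------


def test_mean_pairwise_examples():
    assert stats.mean_pairwise_diff(np.array([[0, 1, 0], [0, 1, 0]])) == 0.0
    assert stats.mean_pairwise_diff(np.array([[0, 1, 1], [1, 1, 0]])) == 2.0
    assert stats.mean_pairwise_diff(np.empty((1, 4))) == 0.0


def test_mean_pairwise_matches_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(50):
        m = rng.integers(0, 2, size=(6, 8))
        assert stats.mean_pairwise_diff(m) == pytest.approx(bf_mean_pairwise(m), abs=1e-12)


def test_unfolded_sfs_counts():
    m = _matrix(np.zeros((6, 3)))
    assert sw.unfolded_sfs(m).S == 0
    ent = np.zeros((6, 5), dtype=np.int8)
    ent[:3, 2] = 1  # one site at derived count 3 of n = 6
    sfs = sw.unfolded_sfs(_matrix(ent))
    assert sfs.S == 1
    assert sfs.xi.tolist() == [0, 0, 1, 0, 0]


def test_unfolded_sfs_rejects_missing():
    ent = np.zeros((4, 2), dtype=np.int8)
    ent[0, 0] = -1
    with pytest.raises(ValueError):
        sw.unfolded_sfs(_matrix(ent))


def test_theta_estimators_singleton_n4():
    t = sw.theta_estimators(stats.SfsSummary(4, np.array([1, 0, 0])))
    assert t.theta_pi == pytest.approx(0.5, abs=1e-12)
    assert t.theta_H == pytest.approx(1 / 6, abs=1e-12)
    assert t.theta_L == pytest.approx(1 / 3, abs=1e-12)
    assert t.theta_W == pytest.approx(6 / 11, abs=1e-12)


@settings(max_examples=200, derandomize=True)
@given(
    st.integers(min_value=2, max_value=30).flatmap(
        lambda n: st.tuples(
            st.just(n),
            st.lists(st.integers(0, 50), min_size=n - 1, max_size=n - 1),
        )
    )
)
def test_theta_identity_property(nx):
    n, xi = nx
    t = sw.theta_estimators(stats.SfsSummary(n, np.array(xi)))
    assert t.theta_pi + t.theta_H == pytest.approx(2 * t.theta_L, abs=1e-12)


def test_fay_wu_h_signs_and_value():
    assert sw.fay_wu_h(stats.SfsSummary(10, np.array([5, 0, 0, 0, 0, 0, 0, 0, 0]))) > 0
    assert sw.fay_wu_h(stats.SfsSummary(10, np.array([0] * 8 + [3]))) < 0
    # n = 4 with one site at derived count 3: H = 0.5 - 1.5 = -1
    assert sw.fay_wu_h(stats.SfsSummary(4, np.array([0, 0, 1]))) == pytest.approx(-1.0)


def test_dh_sign_matches_h_and_undefined_cases():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(4, 25))
        xi = rng.integers(0, 4, size=n - 1)
        sfs = stats.SfsSummary(n, xi)
        if sfs.S == 0:
            assert math.isnan(sw.normalized_dh(sfs))
            continue
        h = sw.fay_wu_h(sfs)
        dh = sw.normalized_dh(sfs)
        assert math.copysign(1, h) == math.copysign(1, dh) or h == 0


def test_dh_standardization_on_neutral_replicates():
    """The variance normalization must leave neutral DH with spread ~1.

    An error in the variance formula would show up as a systematic
    inflation or deflation of the spread; mean-zero alone would not
    catch it.
    """
    vals = [
        sw.normalized_dh(stats.SfsSummary(20, xi))
        for xi in sw.neutral_coalescent_sfs(20, 5.0, 400, seed=17)
        if xi.sum() >= 1
    ]
    sd = float(np.std(vals))
    assert 0.6 < sd < 1.3


def test_theta_pi_two_route_consistency():
    """SFS-route pi equals matrix-route mean pairwise difference."""
    rng = np.random.default_rng(5)
    for _ in range(30):
        m = random_poly_matrix(rng, 8, 6)
        sfs = sw.unfolded_sfs(_matrix(m))
        t = sw.theta_estimators(sfs)
        assert t.theta_pi == pytest.approx(bf_mean_pairwise(m), abs=1e-12)


# ---------------------------------------------------------------------------
# DIND
# ---------------------------------------------------------------------------


def _dind_case(rng, n_rows=8, n_cols=20, n_flank=4, min_flank=2):
    m = random_poly_matrix(rng, n_rows, n_cols)
    pos = np.sort(rng.choice(10_000, size=n_cols, replace=False)) + 1
    focal = int(rng.integers(n_cols))
    return m, pos, focal


def test_dind_matches_bruteforce_oracle():
    rng = np.random.default_rng(21)
    checked = 0
    for _ in range(200):
        m, pos, focal = _dind_case(rng)
        counts = m.sum(axis=0)
        if not (0 < counts[focal] < m.shape[0]):
            continue
        res = stats.dind(_matrix(m, pos), focal, n_flank=4, min_flank=2)
        oracle = bf_dind(m, pos, focal, n_flank=4, min_flank=2)
        if oracle is None:
            assert not res.available
            continue
        ipi_a, ipi_d = oracle
        assert res.ipi_a == pytest.approx(ipi_a, abs=1e-12)
        assert res.ipi_d == pytest.approx(ipi_d, abs=1e-12)
        if ipi_d == 0:
            assert res.sentinel
        else:
            assert res.value == pytest.approx(ipi_a / ipi_d, abs=1e-12)
        checked += 1
    assert checked > 100


def test_dind_symmetric_carriers_give_unity():
    # ancestral and derived carrier groups with identical flanking rows
    block = np.array([[0, 1, 0, 1], [1, 0, 1, 0]], dtype=np.int8)
    ent = np.zeros((4, 9), dtype=np.int8)
    ent[:, [0, 1, 2, 3]] = np.vstack([block, block])
    ent[2:, 4] = 1  # focal
    ent[:, [5, 6, 7, 8]] = np.vstack([block, block])
    res = stats.dind(_matrix(ent), 4, n_flank=4, min_flank=2)
    assert res.value == pytest.approx(1.0)


def test_dind_identical_derived_carriers_is_sentinel():
    ent = np.zeros((6, 9), dtype=np.int8)
    rng = np.random.default_rng(2)
    ent[3:, :] = random_poly_matrix(rng, 3, 9)  # diverse ancestral carriers
    ent[:3, :] = 0
    ent[:3, 4] = 1  # derived carriers identical everywhere
    ent[3:, 4] = 0
    for j in (0, 1, 2, 3, 5, 6, 7, 8):  # keep flanks polymorphic
        if ent[3:, j].sum() == 0:
            ent[3, j] = 1
    res = stats.dind(_matrix(ent), 4, n_flank=4, min_flank=2)
    assert res.sentinel and res.ipi_d == 0.0


def test_dind_invariant_under_row_permutation():
    rng = np.random.default_rng(31)
    m, pos, _ = _dind_case(rng, n_rows=8, n_cols=16)
    counts = m.sum(axis=0)
    focal = int(np.flatnonzero((counts > 0) & (counts < 8))[3])
    base = stats.dind(_matrix(m, pos), focal, n_flank=3, min_flank=2)
    for _ in range(5):
        perm = rng.permutation(8)
        # permute sample pairs' chromosomes consistently (rows are free here)
        res = stats.dind(_matrix(m[perm], pos), focal, n_flank=3, min_flank=2)
        assert res.ipi_a == pytest.approx(base.ipi_a, abs=1e-12)
        assert res.ipi_d == pytest.approx(base.ipi_d, abs=1e-12)


def test_dind_monomorphic_focal_rejected():
    ent = np.zeros((4, 5), dtype=np.int8)
    ent[:, 1] = 1
    ent[0, [0, 2, 3, 4]] = 1
    with pytest.raises(ValueError):
        stats.dind(_matrix(ent), 1)


def test_dind_flank_shortage_not_available():
    ent = random_poly_matrix(np.random.default_rng(4), 6, 5)
    res = stats.dind(_matrix(ent), 0, n_flank=20, min_flank=10)
    assert not res.available and "flanking" in res.reason


# ---------------------------------------------------------------------------
# LD r^2
# ---------------------------------------------------------------------------


def test_ld_r2_perfect_and_symmetry():
    a = np.array([0, 0, 1, 1, 0, 1], dtype=np.int8)
    assert stats.ld_r2(a, a) == pytest.approx(1.0)
    assert stats.ld_r2(a, 1 - a) == pytest.approx(1.0)
    rng = np.random.default_rng(9)
    for _ in range(20):
        x = random_poly_matrix(rng, 10, 2)
        assert stats.ld_r2(x[:, 0], x[:, 1]) == pytest.approx(
            stats.ld_r2(x[:, 1], x[:, 0]), abs=1e-15
        )


def test_ld_r2_closed_form_counts():
    # counts AB=4, Ab=1, aB=1, ab=4 over 10 chromosomes
    a = np.array([1] * 5 + [0] * 5, dtype=np.int8)
    b = np.array([1] * 4 + [0, 1] + [0] * 4, dtype=np.int8)
    expected = bf_ld_r2(a, b)
    assert stats.ld_r2(a, b) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx((0.4 - 0.25) ** 2 / 0.25**2, abs=1e-12)


def test_ld_r2_monomorphic_nan():
    assert math.isnan(stats.ld_r2(np.zeros(6, dtype=np.int8), np.array([0, 1] * 3)))
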