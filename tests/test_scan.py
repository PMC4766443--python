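"""Frequency binning, empirical ranks, zero rule, windows, LD filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

import sweepscan as sw
from sweepscan import scan as sc
from sweepscan.datatypes import GeneRegion, HaplotypeMatrix, PopulationPanel, ValidationError

from conftest import random_poly_matrix


# ---------------------------------------------------------------------------
# frequency classes
# ---------------------------------------------------------------------------


def test_assign_freq_class_boundaries():
    assert sw.assign_freq_class(0.5, 50, upper=0.5) == 50
    assert sw.assign_freq_class(0.005, 100, upper=1.0) == 1
    assert sw.assign_freq_class(0.01, 100, upper=1.0) == 1  # upper edge inclusive
    assert sw.assign_freq_class(1.0, 100, upper=1.0) == 100


def test_assign_freq_class_out_of_range():
    with pytest.raises(ValidationError):
        sw.assign_freq_class(0.0, 50, upper=0.5)
    with pytest.raises(ValidationError):
        sw.assign_freq_class(0.51, 50, upper=0.5)


def test_assign_freq_class_floor_oracle():
    rng = np.random.default_rng(0)
    freqs = rng.uniform(1e-6, 1.0, size=1000)
    got = sw.assign_freq_class(freqs, 100, upper=1.0)
    width = 1.0 / 100
    away_from_edges = np.abs(freqs / width - np.round(freqs / width)) > 1e-6
    expected = np.floor(freqs[away_from_edges] / width).astype(int) + 1
    np.testing.assert_array_equal(got[away_from_edges], np.minimum(expected, 100))


# ---------------------------------------------------------------------------
# empirical rank
# ---------------------------------------------------------------------------


def test_empirical_rank_extremes_and_median():
    dist = np.sort(np.array([0.1, 0.4, 0.2, 0.9, 0.5]))
    assert sw.empirical_rank(1.5, dist) == 1.0
    assert sw.empirical_rank(0.0, dist) == 0.0
    # value equal to the class median of an odd-count distribution:
    # count-based oracle says 3 of 5 values are <= it
    assert sw.empirical_rank(0.4, dist) == pytest.approx(3 / 5)


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(st.floats(-10, 10), min_size=1, max_size=50),
    st.floats(-12, 12),
    st.floats(-12, 12),
)
def test_empirical_rank_monotone(dist, a, b):
    d = np.sort(np.asarray(dist))
    lo, hi = min(a, b), max(a, b)
    assert sw.empirical_rank(lo, d) <= sw.empirical_rank(hi, d)


def test_empirical_rank_random_ties_uniform_within_block():
    """Randomized tie ranks stay inside the tie block and calibrate."""
    dist = np.sort(np.array([1.0] * 80 + [0.0] * 20))
    rng = np.random.default_rng(12)
    ranks = np.array([sw.empirical_rank(1.0, dist, ties="random", rng=rng) for _ in range(4000)])
    assert ranks.min() >= 0.2 - 1e-9 and ranks.max() <= 1.0
    # P(rank >= 0.99) for a value drawn from the null itself must be ~1%
    assert np.mean(ranks >= 0.99) == pytest.approx(0.01 / 0.8, abs=0.01)


def test_build_control_distributions_and_merge():
    values = np.array([0.1, 0.2, 0.9])
    freqs = np.array([0.05, 0.05, 0.225])  # classes 1 and 5 of 10 occupied
    null = sw.build_control_distributions(values, freqs, n_classes=10, freq_upper=0.5)
    assert null.class_distribution(1).tolist() == [0.1, 0.2]
    assert null.class_distribution(5).tolist() == [0.9]
    # empty class 3 served by the nearest non-empty class; the tie
    # between classes 1 and 5 for class 3 goes to the lower class
    assert null.lookup_[3] == 1
    assert null.lookup_[4] == 5
    with pytest.raises(ValidationError):
        sw.build_control_distributions(np.array([]), np.array([]), n_classes=10)


def test_control_distribution_quantiles_match_reference():
    rng = np.random.default_rng(1)
    values = rng.normal(size=10_000)
    freqs = rng.uniform(1e-6, 1, size=10_000)
    null = sw.build_control_distributions(values, freqs, n_classes=20)
    cls = sw.assign_freq_class(freqs, 20)
    for c in (1, 7, 20):
        expected = np.quantile(values[cls == c], [0.25, 0.5, 0.99])
        got = np.quantile(null.class_distribution(c), [0.25, 0.5, 0.99])
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_ranker_sklearn_protocol():
    est = sw.EmpiricalNullRanker(n_classes=10, freq_upper=0.5, ties="upper")
    assert est.get_params()["n_classes"] == 10
    est2 = clone(est).set_params(n_classes=5)
    X = np.column_stack([np.linspace(-1, 1, 50), np.linspace(0.01, 0.49, 50)])
    ranks = est2.fit(X).transform(X)
    assert ranks.shape == (50, 1)
    assert np.all((ranks >= 0) & (ranks <= 1))


def test_ranker_serialization_round_trip():
    rng = np.random.default_rng(3)
    X = np.column_stack([rng.normal(size=200), rng.uniform(1e-3, 1, size=200)])
    null = sw.EmpiricalNullRanker(n_classes=10, ties="upper").fit(X)
    back = sw.EmpiricalNullRanker.from_dict(null.to_dict())
    for c in range(1, 11):
        np.testing.assert_array_equal(null.class_distribution(c), back.class_distribution(c))


# ---------------------------------------------------------------------------
# zero rule
# ---------------------------------------------------------------------------


def test_zero_rule_examples():
    out = sw.apply_dind_zero_rule([3.7, 1.0, np.nan], [False, False, True])
    assert out.tolist() == [3.7, 1.0, 23.7]
    vals = np.array([0.5, 2.0])
    assert sw.apply_dind_zero_rule(vals, [False, False]).tolist() == [0.5, 2.0]
    two = sw.apply_dind_zero_rule([np.nan, 1.5, np.nan], [True, False, True])
    assert two[0] == two[2] == 21.5
    only = sw.apply_dind_zero_rule([np.nan, np.nan], [True, True])
    assert only.tolist() == [20.0, 20.0]


def test_zero_rule_sentinels_rank_top():
    rng = np.random.default_rng(5)
    values = rng.uniform(0, 5, size=200)
    sent = rng.random(200) < 0.1
    values[sent] = np.nan
    freqs = rng.uniform(1e-3, 1, size=200)
    rule = sc.DindZeroRule(10).fit(values, sent, freqs)
    final = rule.finalize(values, sent, freqs)
    null = sw.build_control_distributions(final, freqs, n_classes=10, ties="upper")
    ranks = null.rank(final[sent], freqs[sent])
    assert np.all(ranks == 1.0)
    # strictly above every non-sentinel value in the same class
    cls = sw.assign_freq_class(freqs, 10)
    for c in np.unique(cls[sent]):
        non = final[(cls == c) & ~sent]
        if non.size:
            assert final[(cls == c) & sent].min() > non.max()


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def test_sliding_windows_counts():
    r = GeneRegion("c", 0, 10_000)
    assert len(sw.sliding_windows(r, 5000, 500)) == 11
    assert sw.sliding_windows(GeneRegion("c", 0, 5000), 5000, 500) == [(0, 5000)]
    with pytest.warns(UserWarning):
        assert sw.sliding_windows(GeneRegion("c", 0, 4999), 5000, 500) == []


def _pop_matrix(entries, positions):
    ids = [f"s{i}" for i in range(entries.shape[0] // 2)]
    panel = PopulationPanel({i: "p" for i in ids})
    return HaplotypeMatrix(entries, positions, ids, panel)


def test_window_dh_scan_flags_and_na():
    rng = np.random.default_rng(6)
    ent = random_poly_matrix(rng, 10, 30)
    pos = np.sort(rng.choice(np.arange(5001, 10_000), size=30, replace=False))
    m = _pop_matrix(ent, pos)
    region = GeneRegion("c", 0, 10_000)
    rows = np.arange(10)
    # first window [0, 5000) holds no sites -> not available
    out = sw.window_dh_scan(m, region, rows, control_dh=None, size=5000, step=5000, min_snps=5)
    assert not out.loc[0, "available"] and math.isnan(out.loc[0, "dh"])
    # a DH below every control value is flagged
    out2 = sw.window_dh_scan(
        m, region, rows, control_dh=np.array([10.0, 11.0, 12.0]), size=5000, step=5000
    )
    avail = out2[out2["available"]]
    assert avail["below_threshold"].all()


def test_window_flagging_shift_invariant():
    rng = np.random.default_rng(7)
    ent = random_poly_matrix(rng, 8, 40)
    pos = np.sort(rng.choice(np.arange(1, 20_000), size=40, replace=False))
    null = np.array([-1.0, 0.0, 1.0])
    base = sw.window_dh_scan(
        _pop_matrix(ent, pos), GeneRegion("c", 0, 20_000), np.arange(8), null
    )
    shift = 7_000
    shifted = sw.window_dh_scan(
        _pop_matrix(ent, pos + shift),
        GeneRegion("c", shift, 20_000 + shift),
        np.arange(8),
        null,
    )
    assert shifted["below_threshold"].tolist() == base["below_threshold"].tolist()
    assert (shifted["start"] - base["start"]).unique().tolist() == [shift]


# ---------------------------------------------------------------------------
# joint criterion and LD filter
# ---------------------------------------------------------------------------


def _calls_frame(rows):
    return pd.DataFrame(
        rows, columns=["region", "chrom", "pos", "site", "pop", "fst_rank", "dind_rank"]
    )


def test_call_selection_targets_rules():
    df = _calls_frame(
        [
            ("g", "c", 100, 0, "YRI", 0.995, 0.992),  # flagged
            ("g", "c", 200, 1, "YRI", 0.995, np.nan),  # missing rank -> skipped
            ("g", "c", 300, 2, "YRI", 0.99, 0.99),  # boundary, inclusive
            ("g", "c", 400, 3, "YRI", 0.995, 0.42),
            ("g", "c", 400, 3, "CEU", 0.42, 0.995),  # split across populations
        ]
    )
    out = sw.call_selection_targets(df, 0.99)
    assert out["joint_flag"].tolist() == [True, False, True, False, False]


def test_ld_cluster_filter_rules():
    # region with 4 joint-flagged SNPs: sites 0,1,2 identical columns
    # (pairwise r^2 = 1), site 3 linked to nothing
    ent = np.zeros((8, 4), dtype=np.int8)
    ent[:4, [0, 1, 2]] = 1
    ent[[0, 5], 3] = 1
    m = _pop_matrix(ent, np.array([10, 20, 30, 40]))
    df = _calls_frame(
        [("g", "c", p, i, "p", 1.0, 1.0) for i, p in enumerate([10, 20, 30, 40])]
    )
    df["joint_flag"] = True
    out = sw.ld_cluster_filter(df, {"g": m}, r2_threshold=0.8)
    assert out["final_flag"].tolist() == [True, True, True, False]
    assert out.loc[0, "ld_cluster"] == out.loc[1, "ld_cluster"] == out.loc[2, "ld_cluster"]
    assert out.loc[3, "ld_cluster"] != out.loc[0, "ld_cluster"]


def test_ld_cluster_pair_only_removed():
    ent = np.zeros((8, 2), dtype=np.int8)
    ent[:4, [0, 1]] = 1  # two SNPs in perfect LD, nothing else
    m = _pop_matrix(ent, np.array([10, 20]))
    df = _calls_frame([("g", "c", 10, 0, "p", 1.0, 1.0), ("g", "c", 20, 1, "p", 1.0, 1.0)])
    df["joint_flag"] = True
    out = sw.ld_cluster_filter(df, {"g": m})
    assert not out["final_flag"].any()


def test_ld_cluster_matches_bruteforce_degrees():
    from sweepscan import stats

    rng = np.random.default_rng(9)
    ent = random_poly_matrix(rng, 12, 8)
    m = _pop_matrix(ent, np.arange(1, 9) * 10)
    df = _calls_frame([("g", "c", (i + 1) * 10, i, "p", 1.0, 1.0) for i in range(8)])
    df["joint_flag"] = True
    out = sw.ld_cluster_filter(df, {"g": m}, r2_threshold=0.8)
    for i in range(8):
        degree = sum(
            1
            for j in range(8)
            if j != i and (stats.ld_r2(ent[:, i], ent[:, j]) or 0) > 0.8
        )
        assert out.loc[i, "final_flag"] == (degree >= 2)


# ---------------------------------------------------------------------------
# scanner protocol
# ---------------------------------------------------------------------------


def test_scanner_requires_controls_and_fit(sweep_fixture):
    with pytest.raises(ValidationError, match="control"):
        sw.SweepScanner().fit([])
    with pytest.raises(ValidationError, match="fitted"):
        sw.SweepScanner().scan(sweep_fixture["targets"])


def test_scanner_sklearn_params_round_trip():
    est = sw.SweepScanner(rank_threshold=0.95, random_state=3)
    params = est.get_params()
    assert params["rank_threshold"] == 0.95
    est2 = clone(est)
    assert est2.get_params() == params
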