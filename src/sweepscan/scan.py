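"""Frequency-binned empirical outlier ranking and the sweep scan.

The scan's statistical engine: per-SNP F_ST and DIND values are ranked
against null distributions built from a control set of neutral-proxy
regions, binned by allele frequency (F_ST by minor-allele frequency in
50 classes, DIND by derived-allele frequency in 100 classes) because
both statistics are frequency-dependent. A SNP is a candidate selection
target when both ranks reach the threshold (default 0.99) in the same
population, and is retained only if it sits in strong LD (r^2 > 0.80)
with at least two other candidates. Normalized Fay & Wu's H (DH) in
5 kb / 500 bp sliding windows, compared with the control 1st
percentile, provides a confirmatory signature.

``EmpiricalNullRanker`` and ``SweepScanner`` follow the scikit-learn
estimator protocol: parameters in ``__init__``, fitted state in
trailing-underscore attributes, ``fit`` on the control set and
``predict``/``transform`` on targets.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

from . import stats
from .datatypes import GeneRegion, HaplotypeMatrix, RegionData, ValidationError

log = logging.getLogger(__name__)

#: value a DIND sentinel receives on top of the class maximum
ZERO_RULE_OFFSET = 20.0


# ---------------------------------------------------------------------------
# frequency classes
# ---------------------------------------------------------------------------


def assign_freq_class(freq, n_classes: int, upper: float = 1.0):
    """Equal-width frequency class over (0, upper], 1-based, upper-edge inclusive.

    Class k covers ((k-1) * w, k * w] with w = upper / n_classes; a
    frequency within 1e-9 (relative) of an internal edge maps to the
    lower class, so exact rationals like 1/100 land where the arithmetic
    says they should despite floating point.
    """
    f = np.asarray(freq, dtype=np.float64)
    width = upper / n_classes
    if np.any(f <= 0) or np.any(f / width > n_classes + 1e-9):
        raise ValidationError(f"frequency outside (0, {upper}]")
    idx = np.ceil(f / width - 1e-9).astype(np.int64)
    idx = np.clip(idx, 1, n_classes)
    return idx if idx.ndim else int(idx)


def empirical_rank(value, class_dist: np.ndarray, ties: str = "upper", rng=None):
    """Empirical percentile rank of ``value`` within sorted null values.

    ``ties``:
      ``"upper"``    rank = (# null <= value) / M — the convention that
                     makes rank 1.0 attainable and the zero rule coherent;
      ``"midpoint"`` averages the <= and < counts;
      ``"random"``   draws uniformly inside the tie block, the randomized
                     probability-integral transform: for a value
                     exchangeable with the null the rank is uniform even
                     when the null has atoms.
    """
    vals = np.asarray(class_dist, dtype=np.float64)
    if vals.size == 0:
        raise ValidationError("empirical rank against an empty class distribution")
    v = np.asarray(value, dtype=np.float64)
    m = vals.size
    le = np.searchsorted(vals, v, side="right")
    if ties == "upper":
        r = le / m
    elif ties == "midpoint":
        lt = np.searchsorted(vals, v, side="left")
        r = (le + lt) / (2.0 * m)
    elif ties == "random":
        lt = np.searchsorted(vals, v, side="left")
        rng = np.random.default_rng() if rng is None else rng
        u = rng.random(v.shape if v.ndim else None)
        r = (lt + u * (le - lt)) / m
    else:
        raise ValueError(f"unknown tie mode {ties!r}")
    return r if np.ndim(r) else float(r)


class EmpiricalNullRanker(TransformerMixin, BaseEstimator):
    """Frequency-binned empirical null for one statistic.

    ``fit`` takes ``X`` of shape (n, 2): column 0 the statistic value,
    column 1 the allele frequency used for binning. Values are grouped
    into equal-width frequency classes and sorted; an empty class is
    served by the nearest non-empty class (ties broken toward the lower
    class). ``transform`` returns the empirical percentile rank of each
    (value, frequency) pair against its class.
    """

    def __init__(
        self,
        n_classes: int = 100,
        freq_upper: float = 1.0,
        ties: str = "upper",
        random_state: int | None = None,
    ):
        self.n_classes = n_classes
        self.freq_upper = freq_upper
        self.ties = ties
        self.random_state = random_state

    # -- estimator API --------------------------------------------------
    def fit(self, X, y=None):
        values, freqs = self._split(X)
        if values.size == 0:
            raise ValidationError("cannot build a null distribution from zero control values")
        cls = assign_freq_class(freqs, self.n_classes, self.freq_upper)
        self.class_values_ = [np.empty(0)] * (self.n_classes + 1)  # 1-based
        for c in range(1, self.n_classes + 1):
            self.class_values_[c] = np.sort(values[cls == c])
        self.lookup_ = self._build_lookup()
        self.n_fit_ = values.size
        self._rng = np.random.default_rng(self.random_state)
        return self

    def transform(self, X):
        values, freqs = self._split(X)
        return self.rank(values, freqs).reshape(-1, 1)

    # -- domain API -----------------------------------------------------
    def rank(self, values, freqs) -> np.ndarray:
        values = np.asarray(values, dtype=np.float64)
        cls = np.atleast_1d(assign_freq_class(freqs, self.n_classes, self.freq_upper))
        out = np.empty(values.shape, dtype=np.float64)
        flat_v = np.atleast_1d(values)
        flat_o = out.reshape(-1)
        for i in range(flat_v.size):
            dist = self.class_values_[self.lookup_[cls[i]]]
            flat_o[i] = empirical_rank(flat_v[i], dist, ties=self.ties, rng=self._rng)
        return out

    def class_distribution(self, class_index: int) -> np.ndarray:
        """Sorted null values serving the given class (after merging)."""
        return self.class_values_[self.lookup_[class_index]]

    def merged_classes(self) -> list[int]:
        return [c for c in range(1, self.n_classes + 1) if self.lookup_[c] != c]

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "freq_upper": self.freq_upper,
            "ties": self.ties,
            "classes": {
                str(c): self.class_values_[c].tolist()
                for c in range(1, self.n_classes + 1)
                if self.class_values_[c].size
            },
        }

    @classmethod
    def from_dict(cls, d: dict, random_state: int | None = None) -> "EmpiricalNullRanker":
        obj = cls(
            n_classes=d["n_classes"],
            freq_upper=d["freq_upper"],
            ties=d.get("ties", "upper"),
            random_state=random_state,
        )
        obj.class_values_ = [np.empty(0)] * (obj.n_classes + 1)
        for c, vals in d["classes"].items():
            obj.class_values_[int(c)] = np.asarray(vals, dtype=np.float64)
        obj.lookup_ = obj._build_lookup()
        obj.n_fit_ = int(sum(v.size for v in obj.class_values_))
        obj._rng = np.random.default_rng(random_state)
        return obj

    # -- helpers --------------------------------------------------------
    @staticmethod
    def _split(X):
        if isinstance(X, tuple):
            values, freqs = X
        else:
            X = np.asarray(X, dtype=np.float64)
            values, freqs = X[:, 0], X[:, 1]
        return np.asarray(values, dtype=np.float64), np.asarray(freqs, dtype=np.float64)

    def _build_lookup(self) -> np.ndarray:
        nonempty = [c for c in range(1, self.n_classes + 1) if self.class_values_[c].size]
        if not nonempty:
            raise ValidationError("all frequency classes are empty")
        lookup = np.zeros(self.n_classes + 1, dtype=np.int64)
        arr = np.asarray(nonempty)
        for c in range(1, self.n_classes + 1):
            if self.class_values_[c].size:
                lookup[c] = c
            else:
                # nearest non-empty class, tie toward the lower class
                dist = np.abs(arr - c)
                lookup[c] = int(arr[np.argmin(dist)])  # argmin takes first == lower
        merged = [c for c in range(1, self.n_classes + 1) if lookup[c] != c]
        if merged:
            log.debug("empirical null: %d empty classes served by neighbours", len(merged))
        return lookup


def build_control_distributions(
    values, freqs, n_classes: int, freq_upper: float = 1.0, ties: str = "upper"
) -> EmpiricalNullRanker:
    """Group and sort control statistic values per frequency class."""
    return EmpiricalNullRanker(n_classes=n_classes, freq_upper=freq_upper, ties=ties).fit(
        (np.asarray(values), np.asarray(freqs))
    )


# ---------------------------------------------------------------------------
# DIND zero rule
# ---------------------------------------------------------------------------


def apply_dind_zero_rule(values, sentinel_mask) -> np.ndarray:
    """Resolve iπ_D = 0 sentinels within one DAF class.

    Every sentinel becomes max(non-sentinel values in the class) + 20;
    a class containing only sentinels resolves to 20 (the degenerate
    case must still be deterministic). Non-sentinel values pass through.
    """
    values = np.asarray(values, dtype=np.float64).copy()
    sent = np.asarray(sentinel_mask, dtype=bool)
    if sent.any():
        non = values[~sent]
        repl = float(non.max()) + ZERO_RULE_OFFSET if non.size else ZERO_RULE_OFFSET
        values[sent] = repl
    return values


class DindZeroRule:
    """Class-level sentinel replacement learned from the control set.

    Stores, per DAF class, the replacement value max(non-sentinel
    control DIND in class) + 20 (or 20 for a class with no non-sentinel
    values; nearest-class merging mirrors the null distributions).
    Target sentinels are finalized against the control classes so that
    target and control sentinels coincide in value.
    """

    def __init__(self, n_classes: int, freq_upper: float = 1.0):
        self.n_classes = n_classes
        self.freq_upper = freq_upper

    def fit(self, values, sentinel_mask, freqs) -> "DindZeroRule":
        values = np.asarray(values, dtype=np.float64)
        sent = np.asarray(sentinel_mask, dtype=bool)
        cls = np.atleast_1d(assign_freq_class(freqs, self.n_classes, self.freq_upper))
        non_max = np.full(self.n_classes + 1, np.nan)
        occupied = np.zeros(self.n_classes + 1, dtype=bool)
        for c in range(1, self.n_classes + 1):
            in_c = cls == c
            occupied[c] = bool(in_c.any())
            non = values[in_c & ~sent]
            if non.size:
                non_max[c] = non.max()
        # serve classes with no control values at all from the nearest
        # occupied class (tie toward the lower class)
        occ = np.flatnonzero(occupied)
        if occ.size == 0:
            raise ValidationError("zero rule fitted on an empty control set")
        self.replacement_ = np.empty(self.n_classes + 1)
        for c in range(1, self.n_classes + 1):
            src = c if occupied[c] else int(occ[np.argmin(np.abs(occ - c))])
            m = non_max[src]
            self.replacement_[c] = (m + ZERO_RULE_OFFSET) if np.isfinite(m) else ZERO_RULE_OFFSET
        return self

    def finalize(self, values, sentinel_mask, freqs) -> np.ndarray:
        values = np.asarray(values, dtype=np.float64).copy()
        sent = np.asarray(sentinel_mask, dtype=bool)
        if sent.any():
            cls = np.atleast_1d(assign_freq_class(freqs, self.n_classes, self.freq_upper))
            values[sent] = self.replacement_[cls[sent]]
        return values


# ---------------------------------------------------------------------------
# sliding windows / DH scan
# ---------------------------------------------------------------------------


def sliding_windows(region: GeneRegion, size: int, step: int) -> list[tuple[int, int]]:
    """Window bounds [start + k*step, start + k*step + size), 0-based half-open."""
    if step < 1:
        raise ValidationError("window step must be >= 1")
    if region.length < size:
        warnings.warn(
            f"region {region.name!r} shorter than the window size ({region.length} < {size}); "
            "no windows produced",
            stacklevel=2,
        )
        return []
    k_max = (region.length - size) // step
    return [(region.start + k * step, region.start + k * step + size) for k in range(k_max + 1)]


def window_dh_scan(
    matrix: HaplotypeMatrix,
    region: GeneRegion,
    rows: np.ndarray,
    control_dh: np.ndarray | None,
    size: int = 5000,
    step: int = 500,
    min_snps: int = 5,
    percentile: float = 1.0,
) -> pd.DataFrame:
    """Normalized Fay & Wu's H per sliding window, flagged vs the control null.

    ``control_dh`` is the pooled control-window DH distribution; the
    threshold is its empirical ``percentile`` (default 1st) computed
    with the 'lower' rule so it is an actual control value. A window is
    flagged when its DH lies strictly below that threshold. Windows with
    fewer than ``min_snps`` segregating sites are marked unavailable.
    """
    threshold = math.nan
    if control_dh is not None and len(control_dh):
        threshold = float(np.percentile(np.asarray(control_dh), percentile, method="lower"))
    recs = []
    sub = matrix.entries[rows]
    n = sub.shape[0]
    derived = (sub == 1).sum(axis=0)
    for start, end in sliding_windows(region, size, step):
        in_win = (matrix.positions > start) & (matrix.positions <= end)
        counts = derived[in_win]
        seg = counts[(counts > 0) & (counts < n)]
        S = int(seg.size)
        if S >= min_snps:
            xi = np.bincount(seg, minlength=n)[1:n]
            dh = stats.normalized_dh(stats.SfsSummary(n=n, xi=xi))
        else:
            dh = math.nan
        ok = S >= min_snps and math.isfinite(dh)
        below = bool(ok and math.isfinite(threshold) and dh < threshold)
        recs.append((region.chrom, start, end, S, dh, ok, below))
    return pd.DataFrame(
        recs, columns=["chrom", "start", "end", "S", "dh", "available", "below_threshold"]
    )


# ---------------------------------------------------------------------------
# joint criterion and LD filter
# ---------------------------------------------------------------------------


def call_selection_targets(snps: pd.DataFrame, rank_threshold: float = 0.99) -> pd.DataFrame:
    """Joint criterion: both ranks >= threshold in the same population.

    Rows lacking either rank are never flagged (skipped with a log
    line). The comparison is inclusive: rank exactly at the threshold
    counts.
    """
    df = snps.copy()
    has_both = df["fst_rank"].notna() & df["dind_rank"].notna()
    n_skipped = int((~has_both).sum())
    if n_skipped:
        log.debug("joint criterion: %d SNP-population rows lack one of the ranks", n_skipped)
    df["joint_flag"] = (
        has_both & (df["fst_rank"] >= rank_threshold) & (df["dind_rank"] >= rank_threshold)
    )
    return df


def ld_cluster_filter(
    snps: pd.DataFrame,
    matrices: dict[str, HaplotypeMatrix],
    r2_threshold: float = 0.80,
    min_partners: int = 2,
) -> pd.DataFrame:
    """Retain joint-flagged SNPs in strong LD with enough other flagged SNPs.

    Within each (region, population), flagged SNPs form a graph with an
    edge where r^2 > ``r2_threshold``; a SNP keeps its flag
    (``final_flag``) iff its degree is at least ``min_partners``.
    Connected components of that graph get cluster ids.
    """
    df = snps.copy()
    df["ld_cluster"] = ""
    df["ld_partners"] = 0
    df["final_flag"] = False
    for (region_name, pop), grp in df[df["joint_flag"]].groupby(["region", "pop"], sort=True):
        idx = grp.index.to_numpy()
        sites = grp["site"].to_numpy()
        if len(idx) == 0:
            continue
        matrix = matrices[region_name]
        rows = matrix.rows_for_population(pop)
        k = len(sites)
        r2 = np.zeros((k, k))
        cols = matrix.entries[rows][:, sites]
        for a in range(k):
            for b in range(a + 1, k):
                r2[a, b] = r2[b, a] = stats.ld_r2(cols[:, a], cols[:, b])
        adj = np.nan_to_num(r2) > r2_threshold
        degree = adj.sum(axis=1)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        df.loc[idx, "ld_partners"] = degree
        df.loc[idx, "final_flag"] = degree >= min_partners
        df.loc[idx, "ld_cluster"] = [f"{region_name}:{pop}:c{labels[i]}" for i in range(k)]
    return df


# ---------------------------------------------------------------------------
# per-SNP statistics table
# ---------------------------------------------------------------------------


def compute_region_stats(
    data: RegionData,
    populations: Sequence[str],
    n_flank: int = 20,
    min_flank: int = 10,
) -> pd.DataFrame:
    """Long-format per-(SNP, population) statistics for one region.

    ``fst`` is the maximum pairwise Weir-Cockerham F_ST over population
    pairs involving the row's population, with ``fst_maf`` the pooled
    minor-allele frequency of the maximizing pair (F_ST nulls are MAF-
    matched). ``dind_raw`` is iπ_A/iπ_D (NaN for sentinels, which carry
    ``dind_sentinel=True``); sites with unresolved ancestral state are
    excluded from DIND/DAF but keep their (label-symmetric) F_ST.
    """
    matrix = data.matrix
    region = data.region
    resolved = (
        data.table.resolved_mask()
        if data.table is not None
        else np.ones(matrix.n_sites, dtype=bool)
    )
    pops = list(populations)
    d = {}
    n = {}
    for p in pops:
        d[p], n[p] = matrix.derived_counts(matrix.rows_for_population(p))

    # pairwise F_ST and pooled-pair MAF
    pair_fst = {}
    pair_maf = {}
    for i, p in enumerate(pops):
        for q in pops[i + 1 :]:
            pair_fst[(p, q)] = stats.wc_fst_arrays(n[p], d[p], n[q], d[q])
            pooled_d = d[p] + d[q]
            pooled_n = n[p] + n[q]
            with np.errstate(invalid="ignore", divide="ignore"):
                maf = np.minimum(pooled_d, pooled_n - pooled_d) / pooled_n
            pair_maf[(p, q)] = maf

    frames = []
    for p in pops:
        rows = matrix.rows_for_population(p)
        fsts = []
        mafs = []
        for q in pops:
            if q == p:
                continue
            key = (p, q) if (p, q) in pair_fst else (q, p)
            fsts.append(pair_fst[key])
            mafs.append(pair_maf[key])
        if fsts:
            fst_stack = np.vstack(fsts)
            maf_stack = np.vstack(mafs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                best = np.nanargmax(np.where(np.isnan(fst_stack), -np.inf, fst_stack), axis=0)
            all_nan = np.isnan(fst_stack).all(axis=0)
            fst = fst_stack[best, np.arange(matrix.n_sites)]
            fst_maf = maf_stack[best, np.arange(matrix.n_sites)]
            fst[all_nan] = np.nan
            fst_maf[all_nan] = np.nan
        else:
            fst = np.full(matrix.n_sites, np.nan)
            fst_maf = np.full(matrix.n_sites, np.nan)

        daf = np.where(n[p] > 0, d[p] / np.maximum(n[p], 1), np.nan)
        daf = np.where(resolved, daf, np.nan)
        poly = resolved & (d[p] > 0) & (d[p] < n[p])

        ipi_a = np.full(matrix.n_sites, np.nan)
        ipi_d = np.full(matrix.n_sites, np.nan)
        dind_raw = np.full(matrix.n_sites, np.nan)
        sentinel = np.zeros(matrix.n_sites, dtype=bool)
        dind_ok = np.zeros(matrix.n_sites, dtype=bool)
        sub_idx = np.flatnonzero(resolved)
        if sub_idx.size:
            sub_matrix = matrix.subset_sites(sub_idx)
            for local_j, j in enumerate(sub_idx):
                if not poly[j]:
                    continue
                res = stats.dind(sub_matrix, local_j, rows, n_flank=n_flank, min_flank=min_flank)
                if not res.available:
                    continue
                dind_ok[j] = True
                ipi_a[j] = res.ipi_a
                ipi_d[j] = res.ipi_d
                sentinel[j] = res.sentinel
                dind_raw[j] = res.value

        frames.append(
            pd.DataFrame(
                {
                    "region": region.name or region.chrom,
                    "chrom": region.chrom,
                    "pos": matrix.positions,
                    "site": np.arange(matrix.n_sites),
                    "pop": p,
                    "n": n[p],
                    "derived": np.where(resolved, d[p], -1),
                    "daf": daf,
                    "fst": fst,
                    "fst_maf": fst_maf,
                    "ipi_a": ipi_a,
                    "ipi_d": ipi_d,
                    "dind_raw": dind_raw,
                    "dind_sentinel": sentinel,
                    "dind_ok": dind_ok,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# the scanner
# ---------------------------------------------------------------------------


@dataclass
class ScanReport:
    """Everything the scan produced, in memory."""

    snps: pd.DataFrame
    windows: pd.DataFrame
    populations: list[str]
    control_counts: dict = field(default_factory=dict)
    archaic: pd.DataFrame | None = None
    archaic_summary: dict | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def calls(self) -> pd.DataFrame:
        return self.snps[self.snps["final_flag"]].reset_index(drop=True)


class SweepScanner(BaseEstimator):
    """Selective-sweep scan fitted on a neutral control set.

    ``fit`` consumes control regions and learns the frequency-binned
    F_ST and DIND null distributions, the class-level DIND zero rule
    and the per-population control DH window distribution. ``predict``
    (or the richer ``scan``) applies the joint rank criterion, the LD
    cluster filter and the DH window confirmation to target regions.

    ``rank_ties`` selects the tie convention for empirical ranks. The
    default ``"random"`` draws the rank uniformly inside a tie block —
    the randomized probability-integral transform — so that under the
    null the flagging probability equals 1 - rank_threshold even where
    the statistic has mass points (DIND sentinels, sparse F_ST
    classes); with a seeded scanner the draw is reproducible. ``"upper"``
    reproduces the plain (# <=)/M convention.
    """

    def __init__(
        self,
        populations: Sequence[str] | None = None,
        rank_threshold: float = 0.99,
        r2_threshold: float = 0.80,
        dh_percentile: float = 1.0,
        fst_classes: int = 50,
        dind_classes: int = 100,
        window_size: int = 5000,
        window_step: int = 500,
        min_window_snps: int = 5,
        dind_flank: int = 20,
        dind_min_flank: int = 10,
        rank_ties: str = "random",
        random_state: int | None = None,
    ):
        self.populations = populations
        self.rank_threshold = rank_threshold
        self.r2_threshold = r2_threshold
        self.dh_percentile = dh_percentile
        self.fst_classes = fst_classes
        self.dind_classes = dind_classes
        self.window_size = window_size
        self.window_step = window_step
        self.min_window_snps = min_window_snps
        self.dind_flank = dind_flank
        self.dind_min_flank = dind_min_flank
        self.rank_ties = rank_ties
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, control_regions: Iterable, y=None) -> "SweepScanner":
        regions = [_as_region_data(r, role="control") for r in control_regions]
        if not regions:
            raise ValidationError("the scan requires at least one control region")
        self.populations_ = list(
            self.populations
            if self.populations is not None
            else regions[0].matrix.panel.populations
        )
        if len(self.populations_) < 2:
            raise ValidationError("F_ST needs at least two populations")
        seed_seq = np.random.SeedSequence(self.random_state)
        s_fst, s_dind = seed_seq.spawn(2)

        ctrl = pd.concat(
            [
                compute_region_stats(
                    r, self.populations_, self.dind_flank, self.dind_min_flank
                )
                for r in regions
            ],
            ignore_index=True,
        )
        self.control_stats_ = ctrl

        fst_ok = ctrl["fst"].notna() & (ctrl["fst_maf"] > 0)
        self.fst_null_ = EmpiricalNullRanker(
            n_classes=self.fst_classes,
            freq_upper=0.5,
            ties=self.rank_ties,
            random_state=_seed_int(s_fst),
        ).fit((ctrl.loc[fst_ok, "fst"].to_numpy(), ctrl.loc[fst_ok, "fst_maf"].to_numpy()))

        dind_ok = ctrl["dind_ok"]
        self.dind_zero_rule_ = DindZeroRule(self.dind_classes, 1.0).fit(
            ctrl.loc[dind_ok, "dind_raw"].to_numpy(),
            ctrl.loc[dind_ok, "dind_sentinel"].to_numpy(),
            ctrl.loc[dind_ok, "daf"].to_numpy(),
        )
        ctrl_final = self.dind_zero_rule_.finalize(
            ctrl.loc[dind_ok, "dind_raw"].to_numpy(),
            ctrl.loc[dind_ok, "dind_sentinel"].to_numpy(),
            ctrl.loc[dind_ok, "daf"].to_numpy(),
        )
        self.dind_null_ = EmpiricalNullRanker(
            n_classes=self.dind_classes,
            freq_upper=1.0,
            ties=self.rank_ties,
            random_state=_seed_int(s_dind),
        ).fit((ctrl_final, ctrl.loc[dind_ok, "daf"].to_numpy()))

        # control DH window distribution, per population
        self.dh_null_ = {p: [] for p in self.populations_}
        for r in regions:
            if r.region.length < self.window_size:
                continue
            for p in self.populations_:
                w = window_dh_scan(
                    r.matrix,
                    r.region,
                    r.matrix.rows_for_population(p),
                    None,
                    size=self.window_size,
                    step=self.window_step,
                    min_snps=self.min_window_snps,
                )
                self.dh_null_[p].extend(w.loc[w["available"], "dh"].tolist())
        self.dh_null_ = {p: np.sort(np.asarray(v)) for p, v in self.dh_null_.items()}
        self.dh_threshold_ = {
            p: (
                float(np.percentile(v, self.dh_percentile, method="lower"))
                if v.size
                else math.nan
            )
            for p, v in self.dh_null_.items()
        }
        self.control_counts_ = {
            "regions": len(regions),
            "fst_values": int(fst_ok.sum()),
            "dind_values": int(dind_ok.sum()),
            "dh_windows": {p: int(v.size) for p, v in self.dh_null_.items()},
        }
        log.info("scanner fitted: %s", self.control_counts_)
        return self

    # ------------------------------------------------------------------
    def scan(self, target_regions: Iterable) -> ScanReport:
        """Full scan of target regions; requires a fitted scanner."""
        if not hasattr(self, "fst_null_"):
            raise ValidationError("SweepScanner must be fitted on control regions first")
        regions = [_as_region_data(r, role="target") for r in target_regions]
        snps = pd.concat(
            [
                compute_region_stats(r, self.populations_, self.dind_flank, self.dind_min_flank)
                for r in regions
            ],
            ignore_index=True,
        )

        # ranks
        snps["fst_rank"] = np.nan
        fst_ok = snps["fst"].notna() & (snps["fst_maf"] > 0)
        if fst_ok.any():
            snps.loc[fst_ok, "fst_rank"] = self.fst_null_.rank(
                snps.loc[fst_ok, "fst"].to_numpy(), snps.loc[fst_ok, "fst_maf"].to_numpy()
            )
        snps["dind"] = np.nan
        snps["dind_rank"] = np.nan
        dind_ok = snps["dind_ok"]
        if dind_ok.any():
            finalized = self.dind_zero_rule_.finalize(
                snps.loc[dind_ok, "dind_raw"].to_numpy(),
                snps.loc[dind_ok, "dind_sentinel"].to_numpy(),
                snps.loc[dind_ok, "daf"].to_numpy(),
            )
            snps.loc[dind_ok, "dind"] = finalized
            snps.loc[dind_ok, "dind_rank"] = self.dind_null_.rank(
                finalized, snps.loc[dind_ok, "daf"].to_numpy()
            )

        snps = call_selection_targets(snps, self.rank_threshold)
        matrices = {(r.region.name or r.region.chrom): r.matrix for r in regions}
        snps = ld_cluster_filter(snps, matrices, self.r2_threshold)

        # DH windows
        window_frames = []
        for r in regions:
            for p in self.populations_:
                w = window_dh_scan(
                    r.matrix,
                    r.region,
                    r.matrix.rows_for_population(p),
                    self.dh_null_.get(p),
                    size=self.window_size,
                    step=self.window_step,
                    min_snps=self.min_window_snps,
                    percentile=self.dh_percentile,
                )
                w.insert(0, "region", r.region.name or r.region.chrom)
                w.insert(4, "pop", p)
                window_frames.append(w)
        windows = (
            pd.concat(window_frames, ignore_index=True)
            if window_frames
            else pd.DataFrame(
                columns=["region", "chrom", "start", "end", "pop", "S", "dh", "available", "below_threshold"]
            )
        )
        log.info(
            "scan: %d SNP-population rows, %d joint candidates, %d final calls, %d flagged windows",
            len(snps),
            int(snps["joint_flag"].sum()),
            int(snps["final_flag"].sum()),
            int(windows["below_threshold"].sum()) if len(windows) else 0,
        )
        return ScanReport(
            snps=snps,
            windows=windows,
            populations=self.populations_,
            control_counts=self.control_counts_,
        )

    def predict(self, target_regions: Iterable) -> pd.DataFrame:
        """Selection calls (rows with final_flag) for the target regions."""
        return self.scan(target_regions).calls


def _as_region_data(r, role: str) -> RegionData:
    if isinstance(r, RegionData):
        return r
    region, matrix = r[0], r[1]
    table = r[2] if len(r) > 2 else None
    return RegionData(region=region, matrix=matrix, table=table)


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0] % (2**31))
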