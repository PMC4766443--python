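"""End-to-end orchestration: config, stage sequencing, artifact output.

``run_scan`` executes the fixed stage order — acquire data (simulate or
load), polarize, per-SNP statistics on control and target regions,
null distributions, ranks, zero rule, joint calling, LD filter, DH
windows, archaic classification — and persists every stage's output
under the configured directory. Reruns with the same config and seed
reproduce every output file byte-identically (no timestamps are
written; all randomness flows from the single seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import archaic as archaic_mod
from . import io as sio
from .datatypes import RegionData, ValidationError
from .scan import ScanReport, SweepScanner
from .simulate import SimulationConfig, generate_control_set, simulate_wright_fisher

log = logging.getLogger(__name__)

__version__ = "0.1.0"

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything a scan run needs; exactly one data source.

    ``inputs`` points at files (vcf, panel, targets_bed, controls_bed,
    optional archaic, outgroups); ``simulation`` holds a
    :class:`SimulationConfig` field mapping plus ``n_control_regions``.
    """

    out_dir: str = "scan_out"
    seed: int = 0
    populations: list | None = None
    rank_threshold: float = 0.99
    r2_threshold: float = 0.80
    dh_percentile: float = 1.0
    fst_classes: int = 50
    dind_classes: int = 100
    window_size: int = 5000
    window_step: int = 500
    min_window_snps: int = 5
    dind_flank: int = 20
    dind_min_flank: int = 10
    rank_ties: str = "random"
    inputs: dict | None = None
    simulation: dict | None = None

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValidationError("config must provide exactly one of 'inputs' or 'simulation'")
        for name in ("rank_threshold", "r2_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.dh_percentile < 100.0:
            raise ValidationError("dh_percentile is in percent and must be in (0, 100)")
        if self.inputs is not None:
            for key in ("vcf", "panel", "targets_bed", "controls_bed"):
                if key not in self.inputs:
                    raise ValidationError(f"inputs config requires {key!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# data acquisition
# ---------------------------------------------------------------------------


def _acquire(config: RunConfig):
    """Stage 1: produce target/control RegionData lists + archaic table."""
    if config.simulation is not None:
        sim_raw = dict(config.simulation)
        n_controls = sim_raw.pop("n_control_regions", None)
        if n_controls is None:
            raise ValidationError("simulation config requires n_control_regions")
        sim_raw.setdefault("seed", config.seed)
        sim_cfg = SimulationConfig(**sim_raw)
        target = simulate_wright_fisher(sim_cfg)
        controls = generate_control_set(sim_cfg, n_controls)
        log.info(
            "stage acquire: simulated 1 target region (%d SNPs) and %d control regions",
            target.matrix.n_sites,
            len(controls),
        )
        return (
            [target.as_region_data()],
            [c.as_region_data() for c in controls],
            target.archaic,
            target.truth,
        )

    paths = config.inputs
    panel = sio.read_panel(paths["panel"])
    table, matrix = sio.read_vcf(paths["vcf"], panel)
    if paths.get("outgroups"):
        table, matrix = sio.polarize_variants(
            table, matrix, sio.read_outgroup_alleles(paths["outgroups"])
        )
    else:
        matrix = sio.polarize_from_aa(table, matrix)
    table = table.with_frequencies(matrix)

    def slice_regions(bed_path, role):
        out = []
        for region in sio.read_bed(bed_path, role=role):
            mask = region.contains_pos(matrix.positions) & (table.df["chrom"] == region.chrom).to_numpy()
            out.append(RegionData(region, matrix.subset_sites(mask), table.subset(mask)))
        return out

    targets = slice_regions(paths["targets_bed"], "target")
    controls = slice_regions(paths["controls_bed"], "control")
    if not controls:
        raise ValidationError("no control regions — the empirical null requires a control set")
    archaic_df = (
        sio.read_archaic_table(paths["archaic"])
        if paths.get("archaic")
        else pd.DataFrame(columns=["chrom", "pos", "allele1", "allele2", "individual"])
    )
    log.info(
        "stage acquire: %d target / %d control regions from %s",
        len(targets),
        len(controls),
        paths["vcf"],
    )
    return targets, controls, archaic_df, None


def _pooled_daf(targets: list[RegionData], populations: list[str]) -> dict[int, float]:
    pooled: dict[int, float] = {}
    for rd in targets:
        if rd.table is None:
            continue
        df = rd.table.df
        num = np.zeros(len(df))
        den = np.zeros(len(df))
        for p in populations:
            if f"daf_{p}" in df.columns:
                daf = df[f"daf_{p}"].to_numpy()
                n = df[f"n_{p}"].to_numpy()
                ok = np.isfinite(daf)
                num[ok] += daf[ok] * n[ok]
                den[ok] += n[ok]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        for pos, v in zip(df["pos"], vals):
            if np.isfinite(v):
                pooled[int(pos)] = float(v)
    return pooled


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def run_scan(config: RunConfig, write: bool = True) -> ScanReport:
    """Execute the full scan; persist stage outputs unless ``write=False``."""
    targets, controls, archaic_df, truth = _acquire(config)
    if not controls:
        raise ValidationError("control regions are required")

    scanner = SweepScanner(
        populations=config.populations,
        rank_threshold=config.rank_threshold,
        r2_threshold=config.r2_threshold,
        dh_percentile=config.dh_percentile,
        fst_classes=config.fst_classes,
        dind_classes=config.dind_classes,
        window_size=config.window_size,
        window_step=config.window_step,
        min_window_snps=config.min_window_snps,
        dind_flank=config.dind_flank,
        dind_min_flank=config.dind_min_flank,
        rank_ties=config.rank_ties,
        random_state=config.seed,
    )
    scanner.fit(controls)
    report = scanner.scan(targets)

    # archaic classification of the final calls
    if len(archaic_df) and len(report.calls):
        pooled = _pooled_daf(targets, report.populations)
        table_df = pd.concat([rd.table.df for rd in targets if rd.table is not None])
        classified = archaic_mod.classify_calls(report.calls, table_df, archaic_df, pooled)
        report.archaic = classified
        report.archaic_summary = archaic_mod.summarize_archaic(classified) if len(classified) else None
        log.info("stage archaic: %s", report.archaic_summary)

    report.provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "config": config.to_dict(),
    }
    if truth is not None:
        report.provenance["simulation_truth"] = truth.to_dict()

    if write:
        write_report(report, scanner, Path(config.out_dir))
    return report


def write_report(report: ScanReport, scanner: SweepScanner, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report.snps.to_csv(out_dir / "snp_stats.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    report.calls.to_csv(out_dir / "calls.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    sio.write_bed(report.calls.to_dict("records"), out_dir / "calls.bed")
    report.windows.to_csv(out_dir / "windows.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    flagged = report.windows[report.windows["below_threshold"]]
    sio.write_bed(
        [(r.chrom, r.start, r.end, f"{r.region}:{r.pop}") for r in flagged.itertuples()],
        out_dir / "flagged_windows.bed",
    )
    if report.archaic is not None:
        report.archaic.to_csv(out_dir / "archaic_calls.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    nulls = {
        "fst": scanner.fst_null_.to_dict(),
        "dind": scanner.dind_null_.to_dict(),
        "dind_zero_rule": scanner.dind_zero_rule_.replacement_[1:].tolist(),
        "dh": {p: np.asarray(v).tolist() for p, v in scanner.dh_null_.items()},
        "dh_threshold": scanner.dh_threshold_,
    }
    (out_dir / "nulls.json").write_text(json.dumps(nulls, sort_keys=True))

    summary = {
        "n_snp_rows": int(len(report.snps)),
        "n_candidates": int(report.snps["joint_flag"].sum()),
        "n_final_calls": int(report.snps["final_flag"].sum()),
        "n_windows": int(len(report.windows)),
        "n_flagged_windows": int(report.windows["below_threshold"].sum()) if len(report.windows) else 0,
        "populations": report.populations,
        "control_counts": report.control_counts,
        "archaic_summary": report.archaic_summary,
        "provenance": report.provenance,
    }
    (out_dir / "report.json").write_text(json.dumps(summary, sort_keys=True, indent=2))
    log.info("wrote scan artifacts to %s", out_dir)
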