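"""Reading and writing the standard formats, and variant polarization.

VCF is read through cyvcf2 and written as plain VCF 4.2 text (the
fields the data model stores: CHROM, POS, REF, ALT, the AA ancestral-
allele INFO tag and phased GT columns). Regions travel as BED (0-based
half-open), the sample panel as a two-column TSV, outgroup and archaic
alleles as small TSV tables.

Coding convention: a matrix fresh from :func:`read_vcf` is ref/alt
coded (0 = REF). Polarization rewrites resolved columns to
ancestral/derived coding (1 = derived); unresolved columns keep the
ref/alt coding and are excluded from derived-allele analyses.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    UNRESOLVED,
    GeneRegion,
    HaplotypeMatrix,
    PopulationPanel,
    ValidationError,
    VariantTable,
)

log = logging.getLogger(__name__)

_NUCS = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# panel / regions / small tables
# ---------------------------------------------------------------------------


def read_panel(path) -> PopulationPanel:
    """Two-column TSV (sample, population); '#' lines are comments."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"panel file {path} needs two tab-separated columns")
    return PopulationPanel(dict(zip(df[0], df[1])))


def write_panel(panel: PopulationPanel, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in panel.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


def read_bed(path, role: str = "target") -> list[GeneRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else ""
            regions.append(
                GeneRegion(parts[0], int(parts[1]), int(parts[2]), name=name, role=role)
            )
    return regions


def write_bed(records: Iterable, path) -> None:
    """Write regions or per-SNP calls as sorted BED (0-based half-open).

    Accepts :class:`GeneRegion` (already 0-based), any object or mapping
    with ``chrom``/``pos`` (a 1-based variant becomes the length-1
    interval ``pos-1 .. pos``), or ``(chrom, start, end[, name])``
    tuples already in BED coordinates.
    """
    rows: list[tuple[str, int, int, str]] = []
    for rec in records:
        if isinstance(rec, GeneRegion):
            rows.append((rec.chrom, rec.start, rec.end, rec.name))
        elif isinstance(rec, Mapping) and "pos" in rec:
            rows.append((str(rec["chrom"]), int(rec["pos"]) - 1, int(rec["pos"]), str(rec.get("name", ""))))
        elif hasattr(rec, "pos"):
            rows.append((str(rec.chrom), int(rec.pos) - 1, int(rec.pos), str(getattr(rec, "name", ""))))
        else:
            chrom, start, end, *rest = rec
            rows.append((str(chrom), int(start), int(end), str(rest[0]) if rest else ""))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fields = [chrom, str(start), str(end)] + ([name] if name else [])
            fh.write("\t".join(fields) + "\n")


def read_outgroup_alleles(path) -> dict[int, tuple[str | None, str | None, str | None]]:
    """TSV with columns chrom, pos, chimp, orang, macaque ('.' = missing)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    need = {"pos", "chimp", "orang", "macaque"}
    if not need.issubset(cols):
        raise ValidationError(f"outgroup table {path} must have columns {sorted(need)}")
    out: dict[int, tuple] = {}
    for _, row in df.iterrows():
        alleles = tuple(
            a.upper() if isinstance(a, str) and a.upper() in _NUCS else None
            for a in (row["chimp"], row["orang"], row["macaque"])
        )
        out[int(row["pos"])] = alleles
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path, panel: PopulationPanel) -> tuple[VariantTable, HaplotypeMatrix]:
    """Read phased biallelic SNPs from a VCF 4.x file.

    Multiallelic records and indels are skipped (counts logged). The AA
    INFO tag, when present and matching REF or ALT, is captured as the
    ancestral allele; anything else is recorded as unresolved. The
    returned matrix is ref/alt coded (0 = REF) — run a polarization
    step to obtain derived coding.

    Raises :class:`ValidationError` on an unphased non-missing genotype,
    naming the offending record.
    """
    from cyvcf2 import VCF  # deferred: import cost

    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    vcf = VCF(path)
    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in panel.assignments if s not in vcf_samples]
    if missing_samples:
        raise ValidationError(f"panel samples absent from VCF header: {missing_samples}")
    keep = [i for i, s in enumerate(vcf_samples) if s in panel.assignments]
    samples = [vcf_samples[i] for i in keep]

    recs: list[tuple] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.REF not in _NUCS or var.ALT[0] not in _NUCS:
            n_skipped += 1
            continue
        aa = var.INFO.get("AA")
        aa = aa.upper() if isinstance(aa, str) else UNRESOLVED
        if aa not in (var.REF, var.ALT[0]):
            aa = UNRESOLVED
        col = np.empty(2 * len(keep), dtype=np.int8)
        for out_i, i in enumerate(keep):
            a0, a1, phased = var.genotypes[i][0], var.genotypes[i][1], var.genotypes[i][2]
            if a0 >= 0 and a1 >= 0 and not phased:
                raise ValidationError(
                    f"unphased genotype for sample {vcf_samples[i]!r} at "
                    f"{var.CHROM}:{var.POS} — phased haplotypes are required"
                )
            col[2 * out_i] = a0 if a0 >= 0 else MISSING
            col[2 * out_i + 1] = a1 if a1 >= 0 else MISSING
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0], aa))
        columns.append(col)
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records in %s", n_skipped, path)

    table = VariantTable(
        pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt", "ancestral"])
        if recs
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "ancestral"])
    )
    entries = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    positions = table.pos if len(table) else np.empty(0, dtype=np.int64)
    chroms = table.df["chrom"].to_numpy(dtype=object)
    matrix = HaplotypeMatrix(entries, positions, samples, panel, chroms)
    return table, matrix


def write_vcf(table: VariantTable, matrix: HaplotypeMatrix, path, derived_coded: bool = True) -> None:
    """Write a minimal phased VCF 4.2 with the AA INFO tag.

    When ``derived_coded`` is True (the package's internal convention),
    columns whose ancestral allele is ALT are flipped back to ref/alt
    coding on output; unresolved columns are assumed to be ref/alt coded
    already.
    """
    if len(table) != matrix.n_sites:
        raise ValidationError("table and matrix site counts differ")
    ent = matrix.entries
    if derived_coded:
        flip = table.resolved_mask() & (table.df["ancestral"] == table.df["alt"]).to_numpy()
        if flip.any():
            ent = matrix.flip_columns(flip).entries
    contigs = sorted(set(table.df["chrom"])) if len(table) else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, row in enumerate(table.df.itertuples(index=False)):
            info = f"AA={row.ancestral}" if row.ancestral != UNRESOLVED else "."
            gts = []
            col = ent[:, j]
            for i in range(0, len(col), 2):
                a = "." if col[i] == MISSING else str(col[i])
                b = "." if col[i + 1] == MISSING else str(col[i + 1])
                gts.append(f"{a}|{b}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------


def polarize_variants(
    table: VariantTable,
    matrix: HaplotypeMatrix,
    outgroup_alleles: Mapping[int, Sequence[str | None]],
) -> tuple[VariantTable, HaplotypeMatrix]:
    """Assign ancestral alleles by outgroup parsimony and recode to derived.

    The nearest outgroup (chimpanzee) allele is accepted as ancestral
    iff it matches one of the two human alleles and is confirmed by at
    least one of the deeper outgroups (orangutan, macaque); every other
    configuration — conflict, an outgroup allele matching neither human
    allele, or missing data — leaves the site unresolved. This is the
    conservative deterministic reading of 4-taxon parsimony on
    (((human, chimp), orangutan), macaque): whenever the rule assigns a
    state, that state is the unique most-parsimonious allele at the
    human-chimp ancestor.

    Input matrix must be ref/alt coded; resolved columns come back
    derived-coded, unresolved columns untouched.
    """
    ancestral = []
    for row in table.df.itertuples(index=False):
        chimp, orang, mac = (outgroup_alleles.get(int(row.pos)) or (None, None, None))[:3]
        if chimp in (row.ref, row.alt) and (orang == chimp or mac == chimp):
            ancestral.append(chimp)
        else:
            ancestral.append(UNRESOLVED)
    df = table.df.copy()
    df["ancestral"] = ancestral
    new_table = VariantTable(df)
    flip = new_table.resolved_mask() & (df["ancestral"] == df["alt"]).to_numpy()
    new_matrix = matrix.flip_columns(flip) if flip.any() else matrix
    n_res = int(new_table.resolved_mask().sum())
    log.info("polarize_variants: %d/%d sites resolved", n_res, len(table))
    return new_table, new_matrix


def polarize_from_aa(table: VariantTable, matrix: HaplotypeMatrix) -> HaplotypeMatrix:
    """Recode a ref/alt matrix to derived coding using the table's AA field."""
    flip = table.resolved_mask() & (table.df["ancestral"] == table.df["alt"]).to_numpy()
    return matrix.flip_columns(flip) if flip.any() else matrix


# ---------------------------------------------------------------------------
# archaic genotype tables
# ---------------------------------------------------------------------------


def read_archaic_table(path) -> pd.DataFrame:
    """TSV with columns chrom, pos, allele1, allele2, individual."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"pos": np.int64})
    df.columns = [c.lower() for c in df.columns]
    need = {"chrom", "pos", "allele1", "allele2", "individual"}
    if not need.issubset(df.columns):
        raise ValidationError(f"archaic table {path} must have columns {sorted(need)}")
    return df


def write_archaic_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
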