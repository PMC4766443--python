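"""Comparison of selected variants against archaic-hominin genotypes.

A selective event that post-dates the split of modern humans from
Neandertals/Denisovans leaves the archaic individuals homozygous for
the ancestral allele at the selected sites. A site is called
modern-human-specific when every genotyped archaic individual is
ancestral-homozygous while more than 90% of modern human chromosomes
(pooled over the analyzed populations) carry the derived allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import UNRESOLVED, ValidationError

ANCESTRAL_HOM = "ancestral_homozygous"
CARRIES_DERIVED = "carries_derived"
MISSING_STATUS = "missing"


@dataclass(frozen=True)
class ArchaicGenotype:
    """One diploid, unphased archaic genotype at one position."""

    individual: str
    pos: int
    allele1: str | None
    allele2: str | None

    @property
    def is_missing(self) -> bool:
        return self.allele1 is None or self.allele2 is None


@dataclass(frozen=True)
class ArchaicClassification:
    """Per-individual archaic status of one variant."""

    pos: int
    status: dict  # individual -> ANCESTRAL_HOM | CARRIES_DERIVED | MISSING_STATUS
    available: bool = True

    def all_nonmissing_ancestral(self) -> bool:
        nonmissing = [s for s in self.status.values() if s != MISSING_STATUS]
        return bool(nonmissing) and all(s == ANCESTRAL_HOM for s in nonmissing)

    def any_derived(self) -> bool:
        return any(s == CARRIES_DERIVED for s in self.status.values())


def classify_archaic(
    pos: int,
    ancestral: str,
    derived: str,
    genotypes: list[ArchaicGenotype],
) -> ArchaicClassification:
    """Status of each archaic individual at a polarized variant.

    An individual is ancestral-homozygous when both alleles equal the
    ancestral allele, carries-derived when either allele equals the
    derived allele, missing otherwise (no call, or an allele matching
    neither modern state — treated as no usable call). An unresolved
    ancestral state yields a not-available classification.
    """
    if ancestral == UNRESOLVED or not ancestral:
        return ArchaicClassification(pos=pos, status={}, available=False)
    status = {}
    for g in genotypes:
        if g.pos != pos:
            raise ValidationError(f"genotype position {g.pos} does not match variant {pos}")
        if g.is_missing:
            status[g.individual] = MISSING_STATUS
        elif derived in (g.allele1, g.allele2):
            status[g.individual] = CARRIES_DERIVED
        elif g.allele1 == ancestral and g.allele2 == ancestral:
            status[g.individual] = ANCESTRAL_HOM
        else:
            status[g.individual] = MISSING_STATUS
    return ArchaicClassification(pos=pos, status=status)


def modern_human_specific(
    classification: ArchaicClassification, pooled_modern_daf: float
) -> bool | None:
    """Modern-human-specific flag.

    True iff every non-missing archaic individual is ancestral-
    homozygous and the pooled modern derived-allele frequency is
    strictly above 0.90. Returns None (not available) when the
    classification is unavailable or every archaic status is missing.
    """
    if not classification.available:
        return None
    nonmissing = [s for s in classification.status.values() if s != MISSING_STATUS]
    if not nonmissing:
        return None
    return all(s == ANCESTRAL_HOM for s in nonmissing) and pooled_modern_daf > 0.90


def genotypes_at(archaic_df: pd.DataFrame, pos: int) -> list[ArchaicGenotype]:
    """Extract per-individual genotypes at one position from an archaic table."""
    sub = archaic_df[archaic_df["pos"] == pos]
    out = []
    for row in sub.itertuples(index=False):
        a1 = row.allele1 if isinstance(row.allele1, str) and row.allele1 != "." else None
        a2 = row.allele2 if isinstance(row.allele2, str) and row.allele2 != "." else None
        out.append(ArchaicGenotype(individual=row.individual, pos=pos, allele1=a1, allele2=a2))
    return out


def classify_calls(
    calls: pd.DataFrame,
    table_df: pd.DataFrame,
    archaic_df: pd.DataFrame,
    pooled_daf: dict[int, float],
) -> pd.DataFrame:
    """Archaic classification for each called SNP (one row per unique position).

    ``table_df`` supplies ref/alt/ancestral per position; ``pooled_daf``
    the pooled modern derived-allele frequency. Output columns:
    pos, ancestral, derived, per-individual statuses (one column per
    archaic individual), all_ancestral flag, pooled_daf, mhs_flag.
    """
    individuals = sorted(archaic_df["individual"].unique()) if len(archaic_df) else []
    meta = table_df.set_index("pos")
    recs = []
    for pos in sorted(calls["pos"].unique()):
        row = meta.loc[pos]
        anc = row["ancestral"]
        der = row["alt"] if anc == row["ref"] else row["ref"]
        cls = classify_archaic(int(pos), anc, der, genotypes_at(archaic_df, int(pos)))
        daf = pooled_daf.get(int(pos), math.nan)
        mhs = modern_human_specific(cls, daf) if math.isfinite(daf) else None
        rec = {
            "pos": int(pos),
            "ancestral": anc,
            "derived": der,
            "pooled_daf": daf,
            "all_ancestral": cls.available and cls.all_nonmissing_ancestral(),
            "mhs_flag": mhs,
        }
        for ind in individuals:
            rec[f"status_{ind}"] = cls.status.get(ind, MISSING_STATUS)
        recs.append(rec)
    return pd.DataFrame(recs)


def summarize_archaic(classified: pd.DataFrame) -> dict:
    """Summary fractions over classified selection targets.

    Returns the fraction of targets at which every genotyped archaic
    individual is ancestral-homozygous, and the count of
    modern-human-specific sites. Invariant under row order.
    """
    if len(classified) == 0:
        raise ValidationError("no classified calls to summarize")
    frac = float(classified["all_ancestral"].mean())
    n_mhs = int((classified["mhs_flag"] == True).sum())  # noqa: E712 - may hold None
    return {
        "n_classified": int(len(classified)),
        "archaic_ancestral_fraction": frac,
        "n_modern_human_specific": n_mhs,
    }
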