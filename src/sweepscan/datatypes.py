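"""Core in-memory containers for the sweep scan.

All containers use the conventions of the standard formats they mirror:
VCF positions are 1-based; ``GeneRegion`` and every window computed from it
are 0-based half-open (BED). Haplotype entries are small integers with
``-1`` marking a missing call; after polarization ``1`` means the derived
allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: marker for a missing haplotype call
MISSING = -1

#: marker for an unresolved ancestral allele
UNRESOLVED = "."


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class GeneRegion:
    """A genomic interval with a scan role.

    ``start``/``end`` are 0-based half-open (BED convention). ``role`` is
    either ``"target"`` (gene of interest) or ``"control"`` (member of the
    neutral reference set used to build null distributions).
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    role: str = "target"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"region {self.name!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.role not in ("target", "control"):
            raise ValidationError(f"region role must be 'target' or 'control', got {self.role!r}")

    @classmethod
    def from_one_based(cls, chrom: str, start: int, end: int, **kw) -> "GeneRegion":
        """Build from 1-based inclusive bounds (e.g. GFF-style input)."""
        return cls(chrom, start - 1, end, **kw)

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: np.ndarray) -> np.ndarray:
        """Boolean mask of 1-based positions falling inside the region."""
        p = np.asarray(pos_1based)
        return (p > self.start) & (p <= self.end)


@dataclass(frozen=True)
class PopulationPanel:
    """Mapping of sample ids to population labels."""

    assignments: Mapping[str, str]
    populations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pops = self.populations or tuple(dict.fromkeys(self.assignments.values()))
        object.__setattr__(self, "populations", tuple(pops))
        unknown = set(self.assignments.values()) - set(self.populations)
        if unknown:
            raise ValidationError(f"panel lists populations not in the declared order: {unknown}")

    def population_of(self, sample: str) -> str:
        return self.assignments[sample]

    def samples_for(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def __len__(self) -> int:
        return len(self.assignments)


class VariantTable:
    """Per-SNP records backed by a :class:`pandas.DataFrame`.

    Required columns: ``chrom`` (str), ``pos`` (int, 1-based), ``ref``,
    ``alt`` (single nucleotides) and ``ancestral`` (nucleotide or ``"."``
    when unresolved). Per-population derived-allele frequencies live in
    ``daf_<pop>`` columns with called chromosome counts in ``n_<pop>``;
    they are filled by :meth:`with_frequencies`.
    """

    REQUIRED = ("chrom", "pos", "ref", "alt", "ancestral")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"variant table missing columns: {missing}")
        if len(df) and (df["pos"] <= 0).any():
            raise ValidationError("variant positions must be strictly positive")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def ancestral(self) -> np.ndarray:
        return self.df["ancestral"].to_numpy()

    def resolved_mask(self) -> np.ndarray:
        """Sites whose ancestral allele matches ref or alt."""
        df = self.df
        return (
            (df["ancestral"] != UNRESOLVED)
            & ((df["ancestral"] == df["ref"]) | (df["ancestral"] == df["alt"]))
        ).to_numpy()

    def with_frequencies(self, matrix: "HaplotypeMatrix") -> "VariantTable":
        """Return a copy with per-population DAF / called-count columns.

        The matrix must be derived-coded; unresolved sites get NaN DAF.
        """
        if matrix.n_sites != len(self):
            raise ValidationError("matrix and table describe different numbers of sites")
        df = self.df.copy()
        resolved = self.resolved_mask()
        for pop in matrix.panel.populations:
            rows = matrix.rows_for_population(pop)
            sub = matrix.entries[rows]
            called = (sub != MISSING).sum(axis=0)
            derived = (sub == 1).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                daf = np.where(called > 0, derived / np.maximum(called, 1), np.nan)
            daf = np.where(resolved, daf, np.nan)
            df[f"daf_{pop}"] = daf
            df[f"n_{pop}"] = called
        out = VariantTable(df)
        bad = [
            c
            for c in df.columns
            if c.startswith("daf_") and len(df) and np.nanmax(df[c].to_numpy(), initial=0) > 1 + 1e-12
        ]
        if bad:  # pragma: no cover - defensive
            raise ValidationError(f"derived allele frequency outside [0, 1] in {bad}")
        return out

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))


class HaplotypeMatrix:
    """Phased chromosomes x biallelic sites with a sample panel.

    Row ``2*i`` and ``2*i + 1`` are the two phased chromosomes of
    ``sample_ids[i]``. ``positions`` are strictly increasing 1-based bp.
    Entries are ``0``/``1`` (``1`` = derived once polarized) or
    :data:`MISSING`.
    """

    def __init__(
        self,
        entries: np.ndarray,
        positions: np.ndarray,
        sample_ids: Sequence[str],
        panel: PopulationPanel,
        chroms: np.ndarray | None = None,
    ):
        entries = np.asarray(entries, dtype=np.int8)
        positions = np.asarray(positions, dtype=np.int64)
        if entries.ndim != 2:
            raise ValidationError("entries must be a 2-D chromosomes x sites array")
        if entries.shape[1] != positions.shape[0]:
            raise ValidationError("positions length must equal the number of site columns")
        if chroms is not None:
            chroms = np.asarray(chroms, dtype=object)
            if chroms.shape != positions.shape:
                raise ValidationError("chroms must have one label per site column")
            boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1 if chroms.size else []
            blocks = np.split(positions, boundaries)
        else:
            blocks = [positions]
        for block in blocks:
            if block.size and not np.all(np.diff(block) > 0):
                raise ValidationError("positions must be strictly increasing within a chromosome")
        if positions.size and positions.min() <= 0:
            raise ValidationError("positions must be 1-based (strictly positive)")
        if entries.shape[0] != 2 * len(sample_ids):
            raise ValidationError("expected two chromosome rows per sample")
        bad = ~np.isin(entries, (0, 1, MISSING))
        if bad.any():
            raise ValidationError("haplotype entries must be 0, 1 or MISSING")
        for s in sample_ids:
            if s not in panel.assignments:
                raise ValidationError(f"sample {s!r} absent from the population panel")
        self.entries = entries
        self.positions = positions
        self.chroms = chroms
        self.sample_ids = list(sample_ids)
        self.panel = panel
        self._pop_rows: dict[str, np.ndarray] = {}

    # -- shape ---------------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_sites(self) -> int:
        return self.entries.shape[1]

    # -- panel lookups -------------------------------------------------
    def row_populations(self) -> np.ndarray:
        return np.array(
            [self.panel.population_of(self.sample_ids[i // 2]) for i in range(self.n_chromosomes)]
        )

    def rows_for_population(self, population: str) -> np.ndarray:
        if population not in self._pop_rows:
            rows = [
                i
                for i in range(self.n_chromosomes)
                if self.panel.population_of(self.sample_ids[i // 2]) == population
            ]
            self._pop_rows[population] = np.asarray(rows, dtype=np.intp)
        return self._pop_rows[population]

    # -- site selection ------------------------------------------------
    def subset_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypeMatrix(
            self.entries[:, index],
            self.positions[index],
            self.sample_ids,
            self.panel,
            None if self.chroms is None else self.chroms[index],
        )

    def slice_region(self, region: GeneRegion) -> "HaplotypeMatrix":
        mask = region.contains_pos(self.positions)
        if self.chroms is not None:
            mask &= self.chroms == region.chrom
        return self.subset_sites(mask)

    # -- allele counts -------------------------------------------------
    def derived_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(derived count, called count) per site over the given rows."""
        sub = self.entries if rows is None else self.entries[rows]
        called = (sub != MISSING).sum(axis=0)
        derived = (sub == 1).sum(axis=0)
        return derived, called

    def flip_columns(self, index: np.ndarray) -> "HaplotypeMatrix":
        """Return a copy with allele coding of the given columns inverted."""
        ent = self.entries.copy()
        cols = np.asarray(index)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        block = ent[:, cols]
        obs = block != MISSING
        block[obs] = 1 - block[obs]
        ent[:, cols] = block
        return HaplotypeMatrix(ent, self.positions, self.sample_ids, self.panel, self.chroms)


@dataclass(frozen=True)
class RegionData:
    """A region together with the haplotypes and variants inside it."""

    region: GeneRegion
    matrix: HaplotypeMatrix
    table: VariantTable | None = None
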