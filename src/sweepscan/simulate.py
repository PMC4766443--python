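"""Synthetic data generation for the sweep scan.

The centrepiece is a discrete-generation haploid forward Wright-Fisher
simulator with an island-model migration scheme, per-bp mutation on a
fixed lattice of candidate positions (infinite-sites: a mutation only
lands on a currently unoccupied site), per-bp crossover recombination,
an optional hard sweep (multiplicative fitness advantage 1 + s for
carriers of the derived allele at a focal site in one deme) and an
archaic lineage: a deme isolated at a configurable generation, evolved
without migration and sampled as a single diploid individual at the
end. Forward simulation gives direct control over sweep timing and the
archaic split at desk scale.

By default the deme haplotypes are initialized at migration-drift
equilibrium drawn from an island-model coalescent (msprime), so that
standing variation has a realistic age structure — mid-frequency
variants shared between demes rather than young and deme-private —
without the ~10N-generation forward burn-in that equilibration from
zero variation would need. ``init="empty"`` starts from a monomorphic
population instead (pure forward burn-in).

Also here: a neutral coalescent replicate generator (msprime) used as
an independent oracle for SFS statistics, and a small hand-constructed
sweep fixture with exactly known expected outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GeneRegion,
    HaplotypeMatrix,
    PopulationPanel,
    RegionData,
    ValidationError,
    VariantTable,
)

log = logging.getLogger(__name__)

_NUCS = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the forward Wright-Fisher generator.

    Sizes are haploid chromosome counts. ``mutation_rate`` and
    ``recombination_rate`` are per-bp per-generation; they are scaled
    up relative to human per-generation rates so that a 50 kb region in
    a three-deme metapopulation of 1000-chromosome demes carries
    realistic sample diversity (a few hundred segregating sites in a
    120-chromosome sample) at desk scale. ``sweep_start_gen`` and ``archaic_split_gen``
    count generations after the ``burn_in`` neutral phase.

    ``init="coalescent"`` (default) draws the starting deme haplotypes
    from an island-model coalescent at equilibrium; ``burn_in`` can
    then be 0. ``init="empty"`` starts monomorphic and relies on
    ``burn_in`` forward generations to build variation.
    """

    n_demes: int = 3
    deme_size: int = 1000
    migration_rate: float = 0.001
    seq_length: int = 50_000
    n_sites_max: int = 1536
    mutation_rate: float = 2.4e-7
    recombination_rate: float = 0.6e-7
    selection_s: float = 0.0
    sweep_deme: int = 0
    sweep_start_gen: int = 0
    sweep_final_daf: float | None = None
    focal_pos: int | None = None
    n_generations: int = 0
    burn_in: int = 0
    init: str = "coalescent"
    sample_sizes: tuple = (40, 40, 40)
    archaic_split_gen: int | None = None
    archaic_deme_size: int = 200
    max_reinjections: int = 200
    chrom: str = "chr1"
    region_name: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("migration_rate", "mutation_rate", "recombination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.deme_size < 2:
            raise ValidationError("deme_size must be >= 2")
        if len(self.sample_sizes) != self.n_demes:
            raise ValidationError("sample_sizes must list one entry per deme")
        for k in self.sample_sizes:
            if k % 2 or k < 2 or k > self.deme_size:
                raise ValidationError("sample sizes must be even and <= deme_size")
        if self.n_sites_max > self.seq_length:
            raise ValidationError("n_sites_max cannot exceed seq_length")
        if self.selection_s < 0:
            raise ValidationError("selection_s must be >= 0")
        if self.init not in ("coalescent", "empty"):
            raise ValidationError("init must be 'coalescent' or 'empty'")
        if self.init == "coalescent" and self.n_demes > 1 and self.migration_rate == 0:
            raise ValidationError(
                "coalescent initialization needs migration_rate > 0 with several demes "
                "(isolated demes never share ancestry); use init='empty'"
            )


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside every simulated dataset."""

    focal_pos: int | None
    sweep_active: bool
    deme_daf: dict = field(default_factory=dict)
    sample_daf: dict = field(default_factory=dict)
    generations_run: int = 0
    reinjections: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationResult:
    region: GeneRegion
    matrix: HaplotypeMatrix
    table: VariantTable
    archaic: pd.DataFrame
    truth: SimulationTruth

    def as_region_data(self) -> RegionData:
        return RegionData(region=self.region, matrix=self.matrix, table=self.table)


# ---------------------------------------------------------------------------
# forward simulator
# ---------------------------------------------------------------------------


def simulate_wright_fisher(config: SimulationConfig) -> SimulationResult:
    """Run the forward simulation and sample the configured chromosomes.

    Returns polarized output (the simulator knows every ancestral
    state): matrix entries are derived-coded, the variant table carries
    the AA field, and only sites segregating in the pooled modern
    sample are emitted. Raises ``RuntimeError`` when a positively
    selected focal allele is lost more than ``max_reinjections`` times.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    n_sites = cfg.n_sites_max
    if cfg.init == "coalescent":
        demes, lattice, free = _coalescent_init(cfg, rng)
    else:
        lattice = np.sort(rng.choice(L, size=n_sites, replace=False)) + 1  # 1-based bp
        free = np.ones(n_sites, dtype=bool)
        demes = [np.zeros((cfg.deme_size, n_sites), dtype=np.int8) for _ in range(cfg.n_demes)]
    archaic: np.ndarray | None = None

    total_gens = cfg.burn_in + cfg.n_generations
    t_archaic = None if cfg.archaic_split_gen is None else cfg.burn_in + cfg.archaic_split_gen
    sweeping = cfg.selection_s > 0
    t_sweep = cfg.burn_in + cfg.sweep_start_gen if sweeping else None
    if sweeping and cfg.sweep_deme >= cfg.n_demes:
        raise ValidationError("sweep_deme out of range")

    focal_idx = None
    if sweeping or cfg.focal_pos is not None:
        target_bp = cfg.focal_pos if cfg.focal_pos is not None else L // 2
        focal_idx = int(np.argmin(np.abs(lattice.astype(np.int64) - target_bp)))

    reinjections = 0
    sweep_started = False
    gen = 0
    recycle_every = 16
    if total_gens == 0 and (t_archaic is not None or sweeping):
        raise ValidationError("archaic split / sweep need at least one forward generation")

    def inject_focal() -> None:
        row = int(rng.integers(cfg.deme_size))
        demes[cfg.sweep_deme][row, focal_idx] = 1
        free[focal_idx] = False

    for gen in range(1, total_gens + 1):
        if t_archaic is not None and gen - 1 == t_archaic and archaic is None:
            rows = rng.choice(cfg.deme_size, size=min(cfg.archaic_deme_size, cfg.deme_size), replace=False)
            archaic = demes[0][rows].copy()
        if t_sweep is not None and gen - 1 == t_sweep and not sweep_started:
            sweep_started = True
            if int(sum(int(d[:, focal_idx].sum()) for d in demes)) == 0:
                inject_focal()

        selection_on = sweep_started and sweeping
        new_demes = [
            _reproduce_deme(
                d, demes, rng, cfg, L, lattice,
                selection_on=selection_on, focal_idx=focal_idx,
            )
            for d in range(cfg.n_demes)
        ]
        demes = new_demes
        if archaic is not None:
            archaic = _reproduce_isolated(archaic, rng, cfg, L, lattice)

        _mutate(demes, archaic, free, rng, cfg, L)

        if selection_on:
            total_focal = int(sum(int(d[:, focal_idx].sum()) for d in demes))
            if total_focal == 0:
                reinjections += 1
                if reinjections > cfg.max_reinjections:
                    raise RuntimeError(
                        f"focal allele lost {reinjections} times under selection "
                        f"(s={cfg.selection_s}, deme {cfg.sweep_deme}); raise "
                        "max_reinjections or n_generations"
                    )
                inject_focal()
            elif cfg.sweep_final_daf is not None:
                daf = demes[cfg.sweep_deme][:, focal_idx].mean()
                if daf >= cfg.sweep_final_daf:
                    break

        if gen % recycle_every == 0:
            counts = sum(d.sum(axis=0, dtype=np.int64) for d in demes)
            if archaic is not None:
                counts = counts + archaic.sum(axis=0, dtype=np.int64)
            free[:] = counts == 0
            if focal_idx is not None and sweep_started:
                free[focal_idx] = False

    return _emit(cfg, rng, demes, archaic, lattice, focal_idx, sweep_started, gen, reinjections)


def _coalescent_init(cfg: SimulationConfig, rng) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Equilibrium starting state from an island-model coalescent.

    Draws one haplotype per population chromosome (ploidy 1, so the
    coalescent time scale matches the haploid Wright-Fisher forward
    dynamics), keeps strictly biallelic derived/ancestral sites and
    embeds them in the mutation lattice, reserving the remaining
    candidate positions for forward-phase mutations.
    """
    import msprime

    demog = msprime.Demography()
    for d in range(cfg.n_demes):
        demog.add_population(name=f"pop{d}", initial_size=cfg.deme_size)
    if cfg.n_demes > 1:
        demog.set_symmetric_migration_rate(
            [f"pop{d}" for d in range(cfg.n_demes)], cfg.migration_rate
        )
    ts = msprime.sim_ancestry(
        samples={f"pop{d}": cfg.deme_size for d in range(cfg.n_demes)},
        ploidy=1,
        demography=demog,
        sequence_length=cfg.seq_length,
        recombination_rate=cfg.recombination_rate,
        discrete_genome=True,
        random_seed=int(rng.integers(1, 2**31)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=True,
        random_seed=int(rng.integers(1, 2**31)),
    )
    keep_pos: list[int] = []
    cols: list[np.ndarray] = []
    for var in ts.variants():
        g = var.genotypes
        if len(var.alleles) == 2 and var.site.ancestral_state == "0" and g.max() <= 1:
            c = int(g.sum())
            if 0 < c < g.size:
                keep_pos.append(int(var.site.position) + 1)  # 1-based bp
                cols.append(g.astype(np.int8))
    occupied = np.asarray(keep_pos, dtype=np.int64)
    budget = cfg.n_sites_max - occupied.size
    if budget < 0:
        log.warning(
            "coalescent init produced %d segregating sites (> n_sites_max=%d); "
            "no free lattice slots remain for forward mutations",
            occupied.size,
            cfg.n_sites_max,
        )
        budget = 0
    complement = np.setdiff1d(np.arange(1, cfg.seq_length + 1, dtype=np.int64), occupied)
    extra = rng.choice(complement, size=min(budget, complement.size), replace=False)
    lattice = np.sort(np.concatenate([occupied, extra]))
    free = np.ones(lattice.size, dtype=bool)
    occ_idx = np.searchsorted(lattice, occupied)
    free[occ_idx] = False

    mat = np.zeros((cfg.n_demes * cfg.deme_size, lattice.size), dtype=np.int8)
    if cols:
        mat[:, occ_idx] = np.stack(cols, axis=1)
    demes = [
        mat[d * cfg.deme_size : (d + 1) * cfg.deme_size].copy() for d in range(cfg.n_demes)
    ]
    log.debug("coalescent init: %d standing sites, %d free slots", occupied.size, int(free.sum()))
    return demes, lattice, free


def _reproduce_deme(d, demes, rng, cfg, L, lattice, selection_on, focal_idx):
    N = cfg.deme_size
    src = np.full(N, d, dtype=np.int64)
    if cfg.migration_rate > 0 and cfg.n_demes > 1:
        mig = rng.random(N) < cfg.migration_rate
        k = int(mig.sum())
        if k:
            other = rng.integers(0, cfg.n_demes - 1, size=k)
            other[other >= d] += 1
            src[mig] = other

    child = np.empty_like(demes[d])
    n_cross = rng.poisson(cfg.recombination_rate * L, size=N)
    for s in np.unique(src):
        sel = np.flatnonzero(src == s)
        p1 = _draw_parents(demes[s], rng, len(sel), selection_on and s == cfg.sweep_deme, focal_idx, cfg.selection_s)
        child[sel] = demes[s][p1]
        rec = sel[n_cross[sel] > 0]
        for i in rec:
            p2 = _draw_parents(demes[s], rng, 1, selection_on and s == cfg.sweep_deme, focal_idx, cfg.selection_s)[0]
            bp = np.sort(rng.integers(1, L + 1, size=n_cross[i]))
            odd = (np.searchsorted(bp, lattice, side="left") % 2).astype(bool)
            child[i] = np.where(odd, demes[s][p2], child[i])
    return child


def _reproduce_isolated(pop, rng, cfg, L, lattice):
    N = pop.shape[0]
    p1 = rng.integers(0, N, size=N)
    child = pop[p1]
    n_cross = rng.poisson(cfg.recombination_rate * L, size=N)
    for i in np.flatnonzero(n_cross > 0):
        p2 = int(rng.integers(N))
        bp = np.sort(rng.integers(1, L + 1, size=n_cross[i]))
        odd = (np.searchsorted(bp, lattice, side="left") % 2).astype(bool)
        child[i] = np.where(odd, pop[p2], child[i])
    return child


def _draw_parents(pop, rng, count, weighted, focal_idx, s):
    N = pop.shape[0]
    if not weighted:
        return rng.integers(0, N, size=count)
    w = 1.0 + s * pop[:, focal_idx]
    cdf = np.cumsum(w)
    return np.searchsorted(cdf, rng.random(count) * cdf[-1], side="right")


def _mutate(demes, archaic, free, rng, cfg, L):
    total = cfg.n_demes * cfg.deme_size + (archaic.shape[0] if archaic is not None else 0)
    n_events = rng.poisson(total * L * cfg.mutation_rate)
    if n_events == 0:
        return
    free_idx = np.flatnonzero(free)
    if free_idx.size < n_events:
        n_events = free_idx.size  # lattice exhausted this generation; keep going
        if n_events == 0:
            log.log(
                logging.DEBUG,
                "mutation lattice exhausted this generation; consider raising n_sites_max",
            )
            return
    sites = rng.choice(free_idx, size=n_events, replace=False)
    chroms = rng.integers(0, total, size=n_events)
    for site, c in zip(sites, chroms):
        d, row = divmod(int(c), cfg.deme_size)
        if d < cfg.n_demes:
            demes[d][row, site] = 1
        else:
            archaic[int(c) - cfg.n_demes * cfg.deme_size, site] = 1
        free[site] = False


def _emit(cfg, rng, demes, archaic, lattice, focal_idx, sweep_started, gen, reinjections):
    pops = [f"pop{d}" for d in range(cfg.n_demes)]
    sample_rows = []
    sample_ids = []
    assignments = {}
    for d in range(cfg.n_demes):
        k = cfg.sample_sizes[d]
        rows = np.sort(rng.choice(cfg.deme_size, size=k, replace=False))
        sample_rows.append(demes[d][rows])
        for j in range(k // 2):
            sid = f"{pops[d]}_s{j:03d}"
            sample_ids.append(sid)
            assignments[sid] = pops[d]
    pooled = np.concatenate(sample_rows, axis=0)

    counts = pooled.sum(axis=0, dtype=np.int64)
    keep = (counts > 0) & (counts < pooled.shape[0])
    keep_idx = np.flatnonzero(keep)
    positions = lattice[keep_idx].astype(np.int64)
    entries = pooled[:, keep_idx]

    # nucleotide dressing: random ancestral base, distinct derived base,
    # REF assigned to ancestral or derived with equal probability so a
    # polarization step is actually exercised downstream
    anc_base = _NUCS[rng.integers(0, 4, size=keep_idx.size)]
    der_base = _NUCS[(rng.integers(0, 4, size=keep_idx.size) + rng.integers(1, 4, size=keep_idx.size)) % 4]
    der_base = np.where(der_base == anc_base, _NUCS[(np.searchsorted(_NUCS, anc_base) + 1) % 4], der_base)
    ref_is_anc = rng.random(keep_idx.size) < 0.5
    ref = np.where(ref_is_anc, anc_base, der_base)
    alt = np.where(ref_is_anc, der_base, anc_base)

    panel = PopulationPanel(assignments, tuple(pops))
    matrix = HaplotypeMatrix(entries, positions, sample_ids, panel)
    table = VariantTable(
        pd.DataFrame(
            {"chrom": cfg.chrom, "pos": positions, "ref": ref, "alt": alt, "ancestral": anc_base}
        )
    ).with_frequencies(matrix)

    if archaic is not None:
        a_rows = rng.choice(archaic.shape[0], size=2, replace=False)
        a = archaic[a_rows][:, keep_idx]
        arch_df = pd.DataFrame(
            {
                "chrom": cfg.chrom,
                "pos": positions,
                "allele1": np.where(a[0] == 1, der_base, anc_base),
                "allele2": np.where(a[1] == 1, der_base, anc_base),
                "individual": "archaic1",
            }
        )
    else:
        arch_df = pd.DataFrame(columns=["chrom", "pos", "allele1", "allele2", "individual"])

    focal_pos = int(lattice[focal_idx]) if focal_idx is not None else None
    truth = SimulationTruth(
        focal_pos=focal_pos,
        sweep_active=bool(sweep_started and cfg.selection_s > 0),
        deme_daf={
            pops[d]: float(demes[d][:, focal_idx].mean()) if focal_idx is not None else float("nan")
            for d in range(cfg.n_demes)
        },
        sample_daf={
            pops[d]: float(sample_rows[d][:, focal_idx].mean()) if focal_idx is not None else float("nan")
            for d in range(cfg.n_demes)
        },
        generations_run=gen,
        reinjections=reinjections,
        seed=cfg.seed,
    )
    region = GeneRegion(cfg.chrom, 0, cfg.seq_length, name=cfg.region_name, role="target")
    return SimulationResult(region=region, matrix=matrix, table=table, archaic=arch_df, truth=truth)


# ---------------------------------------------------------------------------
# control set
# ---------------------------------------------------------------------------


def generate_control_set(config: SimulationConfig, n_regions: int) -> list[SimulationResult]:
    """Independent neutral replicates sharing the target demography.

    Selection is forced off; each region gets its own deterministic
    substream seed derived from ``config.seed`` and a distinct
    chromosome label, so the regions are independent but reproducible.
    """
    if n_regions < 1:
        raise ValidationError("n_regions must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_regions)
    out = []
    for i, child in enumerate(children):
        sub = dataclasses.replace(
            config,
            selection_s=0.0,
            sweep_final_daf=None,
            archaic_split_gen=None,
            chrom=f"ctrl{i:04d}",
            region_name=f"ctrl{i:04d}",
            seed=int(child.generate_state(1, dtype=np.uint32)[0] % (2**31)),
        )
        res = simulate_wright_fisher(sub)
        res.truth.sweep_active = False
        res.region = dataclasses.replace(res.region, role="control")
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# neutral coalescent oracle (msprime)
# ---------------------------------------------------------------------------


def neutral_coalescent_sfs(n: int, theta: float, num_replicates: int, seed: int):
    """Yield unfolded SFS vectors (length n - 1) under the standard
    neutral coalescent with scaled mutation rate ``theta`` per region.

    Uses msprime with ploidy 1 and Ne = 1, so theta = 2 * Ne * mu_total
    means mu_total = theta / 2 on a unit-length continuous genome
    (infinite sites). Serves as the independent Monte-Carlo oracle for
    the SFS statistics; it is not the package's generator.
    """
    import msprime

    anc = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=1.0,
        sequence_length=1.0,
        discrete_genome=False,
        num_replicates=num_replicates,
        random_seed=max(1, seed % (2**31)),
    )
    rng = np.random.default_rng(seed)
    for ts in anc:
        ts = __import__("msprime").sim_mutations(
            ts,
            rate=theta / 2.0,
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
        )
        counts = np.zeros(n + 1, dtype=np.int64)
        for var in ts.variants():
            c = int(var.genotypes.sum())
            counts[c] += 1
        yield counts[1:n]


# ---------------------------------------------------------------------------
# hand-constructed sweep fixture
# ---------------------------------------------------------------------------

#: positions (1-based) of the fixture's target-region sites
_FIX_POS = np.array(
    [300, 500, 1200, 1900, 2600, 3300, 4000, 4400, 4700, 5000, 5300, 5600,
     6000, 6700, 7400, 8100, 8800, 9500]
)
_FIX_FOCAL_POS = 5000
_FIX_SWEEP_POS = (4400, 4700, 5000, 5300, 5600)
_FIX_FIXED_DIFF_POS = 300

# diversity patterns for the three non-swept pop1 chromosomes across the
# twelve neutral sites (columns n1..n12)
_FIX_DIVERSE = np.array(
    [
        [1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1],
        [0, 1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 1],
        [0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1, 0],
    ],
    dtype=np.int8,
)
_FIX_POP2 = np.array(
    [
        [1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1],
        [0, 1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 1],
        [0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1, 0],
        [1, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0, 1],
        [0, 1, 1, 0, 1, 0, 0, 1, 1, 0, 1, 0],
        [1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0],
    ],
    dtype=np.int8,
)


def make_sweep_fixture() -> dict:
    """Small hand-constructed two-population dataset with a perfect sweep.

    Target region ``chrA`` (10 kb, 18 sites, 24 chromosomes): in pop1,
    nine identical "swept" chromosomes carry the derived allele at the
    focal site (pos 5000) and four hitchhikers, so iπ_D = 0 at all five
    (the zero-rule sentinel); three diverse chromosomes carry the
    ancestral allele. Site pos 300 is a fixed difference between pop1
    and pop2 (F_ST exactly 1). A deterministic control region ``chrB``
    provides the null distributions, with designed occupancy of the
    frequency classes the target statistics fall into.

    Returns a dict with ``targets``/``controls`` (RegionData lists),
    ``panel``, ``archaic`` (genotype table, both archaic individuals
    ancestral-homozygous at the swept sites) and ``expected`` values
    derivable by hand: iπ_A at the focal site, the pairwise F_ST of a
    9/12-vs-0/12 site (36/11 / 4.5 = 8/11), and the five swept
    positions that must come out as final selection calls.
    """
    n_sites = len(_FIX_POS)
    neutral_cols = [1, 2, 3, 4, 5, 6, 12, 13, 14, 15, 16, 17]
    sweep_cols = [7, 8, 10, 11]
    focal_col = 9

    target = np.zeros((24, n_sites), dtype=np.int8)
    # pop1 rows 0..8: swept haplotype
    target[0:9, focal_col] = 1
    target[0:9, sweep_cols] = 1
    target[0:9, 0] = 1
    # pop1 rows 9..11: diverse ancestral carriers (share the fixed difference)
    target[9:12, 0] = 1
    target[9:12, neutral_cols] = _FIX_DIVERSE
    # pop2 rows 12..23
    target[12:24, neutral_cols] = np.vstack([_FIX_POP2, _FIX_POP2])

    samples = [f"pop1_s{i}" for i in range(6)] + [f"pop2_s{i}" for i in range(6)]
    panel = PopulationPanel({s: s.split("_")[0] for s in samples}, ("pop1", "pop2"))
    target_region = GeneRegion("chrA", 0, 10_000, name="sweep_gene", role="target")
    target_matrix = HaplotypeMatrix(target, _FIX_POS, samples, panel)
    target_table = VariantTable(
        pd.DataFrame(
            {"chrom": "chrA", "pos": _FIX_POS, "ref": "A", "alt": "G", "ancestral": "A"}
        )
    ).with_frequencies(target_matrix)

    control_matrix, control_positions = _fixture_control()
    control_region = GeneRegion("chrB", 0, 10_000, name="ctrl_gene", role="control")
    control_hm = HaplotypeMatrix(control_matrix, control_positions, samples, panel)
    control_table = VariantTable(
        pd.DataFrame(
            {"chrom": "chrB", "pos": control_positions, "ref": "A", "alt": "G", "ancestral": "A"}
        )
    ).with_frequencies(control_hm)

    classified_pos = list(_FIX_SWEEP_POS) + [_FIX_FIXED_DIFF_POS]
    archaic = pd.DataFrame(
        [
            {"chrom": "chrA", "pos": p, "allele1": "A", "allele2": "A", "individual": ind}
            for ind in ("Denisova", "Altai")
            for p in classified_pos
        ]
    )

    expected = {
        "focal_pos": _FIX_FOCAL_POS,
        "sweep_positions": list(_FIX_SWEEP_POS),
        "fixed_diff_pos": _FIX_FIXED_DIFF_POS,
        "fst_fixed_diff": 1.0,
        "fst_sweep_site": 8.0 / 11.0,  # WC ANOVA on 12 chroms 9 derived vs 12 chroms 0
        "focal_ipi_a": 4.0,  # three diverse carriers, pairwise 4 differences each
        "focal_ipi_d": 0.0,
        "focal_daf": 0.75,
        "final_call_pop": "pop1",
    }
    return {
        "targets": [RegionData(target_region, target_matrix, target_table)],
        "controls": [RegionData(control_region, control_hm, control_table)],
        "panel": panel,
        "archaic": archaic,
        "expected": expected,
    }


def write_sweep_fixture(directory) -> dict:
    """Materialize the sweep fixture as the pipeline's input files.

    Writes a two-chromosome VCF (target region chrA + control region
    chrB), panel TSV, target/control BEDs and the archaic genotype
    table; returns the path mapping suitable for a run config's
    ``inputs`` block plus the fixture's ``expected`` values.
    """
    from pathlib import Path

    from . import io as sio
    from .datatypes import HaplotypeMatrix, VariantTable

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fx = make_sweep_fixture()
    t = fx["targets"][0]
    c = fx["controls"][0]
    cols = ["chrom", "pos", "ref", "alt", "ancestral"]
    table = VariantTable(
        pd.concat([t.table.df[cols], c.table.df[cols]], ignore_index=True)
    )
    matrix = HaplotypeMatrix(
        np.concatenate([t.matrix.entries, c.matrix.entries], axis=1),
        np.concatenate([t.matrix.positions, c.matrix.positions]),
        t.matrix.sample_ids,
        fx["panel"],
        np.array(["chrA"] * t.matrix.n_sites + ["chrB"] * c.matrix.n_sites, dtype=object),
    )
    sio.write_vcf(table, matrix, directory / "fixture.vcf")
    sio.write_panel(fx["panel"], directory / "panel.tsv")
    sio.write_bed([t.region], directory / "targets.bed")
    sio.write_bed([c.region], directory / "controls.bed")
    sio.write_archaic_table(fx["archaic"], directory / "archaic.tsv")
    return {
        "inputs": {
            "vcf": str(directory / "fixture.vcf"),
            "panel": str(directory / "panel.tsv"),
            "targets_bed": str(directory / "targets.bed"),
            "controls_bed": str(directory / "controls.bed"),
            "archaic": str(directory / "archaic.tsv"),
        },
        "expected": fx["expected"],
    }


#: scan settings matched to the fixture's size (fewer sites than a real
#: region: 10 frequency classes, 5+5 DIND flanks, 3-SNP windows)
FIXTURE_SCAN_PARAMS = dict(
    populations=["pop1", "pop2"],
    fst_classes=10,
    dind_classes=10,
    min_window_snps=3,
    dind_flank=5,
    dind_min_flank=5,
)


def _fixture_control() -> tuple[np.ndarray, np.ndarray]:
    """Deterministic diverse control matrix with designed class occupancy."""
    positions = np.arange(250, 250 + 20 * 500, 500, dtype=np.int64)  # 20 sites
    rng = np.random.default_rng(20240101)
    ctrl = (rng.random((24, 20)) < 0.4).astype(np.int8)
    # col 9: F_ST null for MAF class (0.35, 0.40]: 5/12 vs 4/12, modest F_ST
    ctrl[:, 9] = 0
    ctrl[[0, 2, 4, 6, 8], 9] = 1
    ctrl[[12, 13, 14, 15], 9] = 1
    # col 10: DIND null for DAF class (0.7, 0.8]: 9/12 diverse carriers in pop1
    ctrl[:, 10] = 0
    ctrl[0:9, 10] = 1
    ctrl[12:21, 10] = 1
    # col 11: F_ST null for MAF class (0.45, 0.5]: balanced 6/12 vs 6/12
    ctrl[:, 11] = 0
    ctrl[[0, 1, 2, 3, 4, 5], 11] = 1
    ctrl[[12, 14, 16, 18, 20, 22], 11] = 1
    # cols 3 and 15: differentiated sites (0/12 vs 7/12 and 1/12 vs 7/12)
    # so the MAF classes holding the target's neutral sites contain
    # control F_ST values above background drift noise
    ctrl[:, 3] = 0
    ctrl[[13, 15, 16, 17, 19, 21, 23], 3] = 1
    ctrl[:, 15] = 0
    ctrl[4, 15] = 1
    ctrl[[12, 14, 16, 18, 20, 22, 23], 15] = 1
    # keep every site polymorphic in the pooled sample
    sums = ctrl.sum(axis=0)
    for j in np.flatnonzero((sums == 0) | (sums == 24)):
        ctrl[0, j] = 1 - ctrl[0, j]
    return ctrl, positions
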