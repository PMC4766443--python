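# Methods

`sweepscan` detects recent positive selection in phased population
genomic data by empirical outlier ranking. This note records the model,
the estimators, the numerical conventions, and the design choices made
where more than one defensible option existed — together with what the
synthetic data generator does and does not emulate, and therefore what
the test suite does and does not demonstrate about real data.

## The scan

A *hard selective sweep* drives a new beneficial allele to high
frequency, dragging its haplotype background with it. The scan looks
for three signatures, each compared against an empirical null built
from a control set of neutral-proxy regions analysed identically:

1. **Population differentiation.** Per-SNP Weir & Cockerham (1984)
   F_ST between population pairs. Because F_ST is frequency-dependent,
   control values are binned into 50 equal-width minor-allele-frequency
   (MAF) classes over (0, 0.5], and each target SNP is ranked within
   its class.
2. **Derived intra-allelic nucleotide diversity (DIND).** At a focal
   SNP, iπ_A and iπ_D are the mean pairwise differences over a fixed
   flank of 40 surrounding variants (the 20 nearest polymorphic sites
   upstream and 20 downstream), computed separately among carriers of
   the ancestral and the derived allele. DIND = iπ_A/iπ_D: a recently
   swept derived allele sits on one haplotype, so iπ_D ≈ 0 and DIND is
   large at high derived-allele frequency (DAF). Control values are
   binned into 100 DAF classes over (0, 1].
3. **High-frequency-derived excess.** Normalized Fay & Wu's H (DH) in
   5 kb windows sliding by 500 bp; windows below the control set's 1st
   DH percentile are flagged as confirmatory evidence.

A SNP is a *candidate selection target* when both its F_ST rank and its
DIND rank reach 0.99 in the same population (inclusive comparison), and
is *retained* only when it shows r² > 0.80 with at least two other
candidates in that population — isolated outliers are treated as noise.
Retained candidates are finally compared with archaic-hominin
genotypes: a site is *modern-human-specific* when every genotyped
archaic individual is homozygous for the ancestral allele while the
pooled modern DAF exceeds 0.90 (strict inequality; pooling weights
every chromosome equally).

## Estimators

With n chromosomes and unfolded SFS counts ξ_i (i = 1..n−1):

- θ_π = Σ ξ_i·i(n−i)/C(n,2), θ_H = Σ ξ_i·i²/C(n,2),
  θ_L = Σ ξ_i·i/(n−1), θ_W = S/a_n with a_n = Σ_{i<n} 1/i.
  The identity θ_π + θ_H = 2θ_L holds exactly and is tested.
- Fay & Wu's H = θ_π − θ_H. The normalized form is
  DH = (θ_π − θ_L)/√Var, with the neutral-model variance

      Var = (n−2)/(6(n−1))·θ
          + [18n²(3n+2)·b_{n+1} − (88n³+9n²−13n+6)] / (9n(n−1)²)·θ²,

  b_n = Σ_{i<n} 1/i², θ estimated by θ_W and θ² by S(S−1)/(a_n²+b_n).
  The implementation is validated against a Monte-Carlo neutral
  coalescent oracle (msprime): mean DH ≈ 0 and spread ≈ 1 over
  replicates. The plug-in θ estimates leave a small positive mean
  offset (~+0.07 at n = 20, θ = 5), a known finite-sample effect.
- F_ST uses the haploid (allele-count) ANOVA form of Weir & Cockerham,
  appropriate for phased chromosomes:
  θ̂ = (MSP − MSG)/(MSP + (n_c − 1)·MSG). Negative estimates are kept
  unclipped so that empirical ranking remains monotone. Sites
  monomorphic in the pooled pair are undefined (NA).
- r² = D²/(p_A(1−p_A)p_B(1−p_B)) from phased haplotype counts.

Every estimator is checked against brute-force enumeration on small
instances to 1e-12.

## Conventions and edge rules

- **Coordinates.** VCF positions are 1-based; regions, windows and all
  BED output are 0-based half-open.
- **Polarization.** The chimpanzee allele is accepted as ancestral iff
  it matches one human allele and is confirmed by orangutan or
  macaque; anything else is unresolved. Wherever this conservative
  rule assigns a state it agrees with exhaustive 4-taxon parsimony
  (tested); it abstains in some cases parsimony would resolve.
  Unresolved sites keep ref/alt coding and are excluded from
  DAF-based analyses (DIND, DH, archaic) but retain their
  label-symmetric F_ST.
- **Missing data.** Pairwise deletion per site; the SFS (and hence DH)
  requires complete data and is computed on the no-missing simulator
  output or complete subsets.
- **DIND edges.** Near region boundaries the flank shrinks down to a
  configurable minimum (default 10 per side), below which the SNP is
  not a DIND candidate. Carrier groups of fewer than two chromosomes
  have mean pairwise diversity 0, so a singleton derived allele is an
  iπ_D = 0 sentinel. No physical-distance cap is imposed on flanks.
- **Zero rule.** Within each DAF class, iπ_D = 0 sentinels take the
  value max(non-sentinel values in the class) + 20 — computed on the
  control set and applied identically to control and target sentinels
  so they tie exactly. A class with no non-sentinel values resolves to
  20. Sentinels therefore sit strictly above every regular value in
  their class.
- **Frequency classes.** Equal-width, 1-based, upper-edge-inclusive;
  frequencies within 1e-9 (relative) of an internal edge map to the
  lower class so exact rationals bin as the arithmetic says. Empty
  classes are served by the nearest non-empty class, ties toward the
  lower class.
- **F_ST per population.** F_ST is pairwise but the joint criterion is
  per-population; a SNP's F_ST in population P is the maximum pairwise
  value over pairs containing P, MAF-matched by the pooled frequency
  of the maximizing pair. This is the most inclusive deterministic
  assignment; the control set is built with the same rule, so the
  ranking stays calibrated.
- **Rank ties.** The plain empirical rank (# control ≤ value)/M is
  available (`ties="upper"`), but the scanner defaults to randomized
  tie resolution: the rank is drawn uniformly inside the tie block
  (the randomized probability-integral transform). This matters
  because both statistics have atoms — DIND sentinels share one exact
  value per class, and sparse MAF classes hold few distinct F_ST
  configurations. With "upper" ranks, every member of a top-heavy tie
  block ranks 1.0 and the null calibration of the 0.99 threshold
  breaks (singleton-derived SNPs alone are ~20% of sites); with
  randomized ranks the flagging probability under the null equals
  1 − threshold for any null distribution. The draw is seeded by the
  run seed, so results are reproducible bit-for-bit.
- **DH windows.** Windows need ≥ 5 segregating sites (configurable),
  else NA. The 1st percentile threshold uses the 'lower' empirical
  quantile, i.e. an actual control value; flagging is strict `<`.
  DH is computed per population; the control DH distribution is kept
  per population as well (the demes of the generator are exchangeable,
  so this costs nothing and stays correct for asymmetric panels).
- **DIND null pooling.** Control DIND values from all analysed
  populations enter one distribution per DAF class, mirroring the
  single control distribution the scan's significance is defined
  against and keeping high-DAF classes occupied.

## The synthetic-data generator

The generator is a discrete-generation haploid Wright-Fisher forward
simulator over a fixed lattice of candidate positions: island-model
migration (each offspring draws its parent from another deme with the
migration probability), per-bp mutation assigned to unoccupied lattice
sites (infinite-sites; sites whose derived allele is lost are
recycled), per-offspring Poisson crossover recombination, an optional
hard sweep (parental sampling weight 1 + s for derived-allele carriers
at the focal site in the sweep deme, with re-injection on loss), and an
archaic lineage — a deme isolated at a configured generation, evolved
without migration, and sampled as one diploid individual at the end.

Starting haplotypes are drawn at migration-drift equilibrium from an
island-model coalescent (msprime, ploidy 1 so the time scales match)
rather than grown forward from a monomorphic state: equilibration from
zero variation needs ~10N generations, and truncating it leaves
mid-frequency variants young and deme-private, which distorts the
F_ST null upward. `init="empty"` retains the pure forward path.

Defaults (one scaled study condition, fixed once):

| parameter | default | rationale |
|---|---|---|
| demes × size | 3 × 1000 haploid | three-population design, desk scale |
| migration | 0.001 /chrom/gen | Nm = 1, strong but realistic structure |
| region length | 50 kb | ~10× the DH window |
| mutation | 2.4e-7 /bp/gen | ~400 segregating sites in a 120-chromosome sample, enough DIND flank density |
| recombination | 0.6e-7 /bp/gen | preserves swept haplotypes across a 5 kb window while decorrelating flanks |
| samples | 40 chromosomes/deme | 1000-Genomes-like panel size |
| sweep | s = 0.05, run to deme DAF ≥ 0.8 | partial hard sweep |

Rates are scaled up relative to per-generation human rates in exchange
for the small population sizes, preserving the population-scaled
compound parameters that the statistics actually see.

**What the generator emulates:** frequency-matched null ranking,
hitchhiking structure, within-deme SFS distortion from migration,
sweep-age/archaic-split ordering, missing-free phased genotypes with
VCF/BED/TSV plumbing identical to real inputs. **What it does not:**
variable recombination and mutation landscapes, background selection,
demographic history (growth, bottlenecks, admixture), sequencing and
phasing error, ascertainment bias, and an archaic lineage that is much
older than the sweeps — here the archaic splits at the start of the
forward phase, so it shares more standing variation with moderns than
a deeply diverged genome would, and the archaic-ancestral fraction
among selection targets is correspondingly conservative. Passing tests
therefore demonstrate the statistical machinery, not robustness to
real-data artefacts.

## Measured behavior and known limitations

- The joint F_ST+DIND criterion recovers the majority of simulated
  partial hard sweeps at the default conditions, and the null
  calibration of both ranks is exact by construction (verified to
  within three binomial standard errors on ~10⁵ SNP-population pairs).
- DH-window confirmation has maximum power for sweeps near completion.
  For sweeps stopped at deme DAF 0.8 under Nm = 1 structure, focal
  windows reach normalized DH of −2 to −4 while the within-deme
  control 1st percentile sits near −3.5 (neutral migration-drift
  already produces high-frequency-derived excess), so roughly half of
  such sweeps are DH-confirmed; detection approaches certainty as the
  sweep approaches fixation. This mirrors DH's documented role as a
  confirmatory, not primary, signature.
- Under the same strong structure, neutral within-deme haplotypes
  occasionally drift high enough to form LD-linked clusters of joint
  outliers; the measured rate of neutral replicates with at least one
  final (LD-filtered) call is a few percent. The LD filter removes the
  large majority of isolated false positives but cannot remove
  genuinely sweep-like drift clusters — no outlier method can without
  an explicit demographic null.
- Ranks are empirical percentiles; no analytical p-values or
  multiple-testing correction are computed, deliberately.
- The scan assumes phased, polarized, biallelic SNPs; phasing and
  imputation are out of scope, and multiallelic sites are dropped.
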