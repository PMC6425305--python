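# Methods

## Model and procedure

The analysis treats each SNP's pair of association p-values `(p1, p2)` as
a draw from a four-class mixture: null for both traits, specific to one
trait, or shared. Enrichment of small `p1` among SNPs with small `p2` is
evidence of polygenic overlap regardless of effect direction, which is
what distinguishes this framework from genetic-correlation methods: a
trait pair can show strong conditional enrichment while the genome-wide
correlation of signed effects is essentially zero, because shared variants
act with mixed signs.

The pipeline stages are:

1. **Harmonization.** Both tables are intersected on SNP id and aligned to
   a single effect allele; swapped alleles flip the sign of `z2`,
   strand-ambiguous (A/T, C/G) and irreconcilable pairs are dropped. When
   a reported z disagrees with its p-value by more than `|Δz| > 0.05` the
   p-value wins and z is recomputed keeping the reported sign — p-values
   are the primary statistic of the method, signs only annotate direction.
2. **Region exclusion.** SNPs inside configured long-range-LD /
   known-association regions (defaults: MHC chr6:25652429–33368333 and
   APOE chr19:44909039–45912650, both ends inclusive) are removed along
   with every SNP linked to them at r² > 0.1, because their LD structure
   and outsized effects would bias the enrichment estimates.
3. **Genomic control.** λ = median(z²)/median(χ²₁) is estimated from
   LD-independent (r² < 0.1) intergenic SNPs — a set depleted of true
   associations — and all z-scores are divided by √λ (p recomputed).
   The division is applied unconditionally; a switch can clamp λ at 1 so
   the correction never inflates the statistics, but the default mirrors
   the unconditional division of the underlying procedure.
4. **Random pruning.** Estimating empirical CDFs on all SNPs would let
   large LD blocks dominate. Instead one SNP per LD cluster (r² > 0.1) is
   chosen at random — a random maximal independent set: visit SNPs in
   random order, keep any undecided SNP, discard its linked neighbours —
   and the procedure is repeated 200 times. Every empirical CDF used
   downstream is the average of the per-iteration CDFs. Iteration k draws
   its RNG stream from (seed, k), so the ensemble is reproducible and
   order-independent. Identical masks are stored once with a multiplicity
   weight; all averages are weighted, which is arithmetically identical to
   storing every mask (on an LD-free panel the ensemble collapses to a
   single full-panel mask).
5. **Conditional QQ curves.** For each conditioning stratum
   {p2 ≤ t}, t ∈ {1, 0.1, 0.01, 0.001}, the averaged exceedance
   G(q) = P(−log₁₀p₁ ≥ q | stratum) is reported as −log₁₀G on a nominal
   grid (0–10, step 0.1). Nested leftward shift of stricter strata is the
   visual signature of enrichment.
6. **condFDR / conjFDR.** The stratified averaged ECDF
   F̂(p1 | p2 ≤ t) is tabulated on a 2-D grid (−log₁₀p₁ 0–20, conditioning
   −log₁₀p₂ 0–10, step 0.1 on both axes) and
   condFDR(p1|p2) = min(1, π₀ · p1 / F̂) with π₀ = 1, F̂ evaluated by
   bilinear interpolation at (−log₁₀p1, −log₁₀p2), out-of-grid queries
   clamped to the boundary. conjFDR is the per-SNP maximum of the two
   conditional FDRs. Thresholds: condFDR < 0.01, conjFDR < 0.05, strict.
7. **Discovery.** Called SNPs are clumped into independent loci as
   connected components of the r² > 0.1 subgraph induced on the call set;
   the lead SNP minimises (FDR, p, position). Loci are annotated with the
   nearest gene (inside a gene body → "intronic", otherwise
   upstream/downstream by strand, ties to the smaller start coordinate),
   the direction of effect in both traits from the harmonized signed
   z-scores, and a flag marking variants already genome-wide significant
   (p < 5×10⁻⁸) in the original scan, which disqualifies them as novel.
   LDlink and PubMed novelty checks are external manual steps; the locus
   table carries placeholder columns for them.

## Numerical choices

- **Lookup counting is exact.** Per pruning mask the stratified ECDF is
  computed by a 2-D histogram on grid-node indices followed by reverse
  cumulative sums; a nudge of 1e-9 in −log₁₀ units makes values lying on
  a grid node count as ≤ that node's p-value despite floating round-trip
  error. On a single mask the table equals direct threshold counting
  exactly, which the tests verify against a brute-force oracle at 1e-12.
- **Sparse-cell fallback.** A lookup cell whose (ensemble-averaged)
  numerator count falls below `min_stratum_count` (default 100) inherits
  the value of the nearest less-stringent conditioning stratum,
  cascading to the unconditional stratum if needed. This removes the
  unstable ratios deep in the tail where a stratum contains a handful of
  SNPs. Strata that are entirely empty in one mask likewise inherit the
  next coarser stratum for that mask.
- **Monotonicity.** After averaging and fallback an isotonic-regression
  pass enforces that F̂ is non-increasing along the −log₁₀p₁ axis (it is
  a no-op on rows that are already monotone, so oracle equivalence is
  preserved). The derived quantity p₁/F̂ is monotone in p₁ for the true
  (concave) mixture CDF; for the empirical estimate it can dip between
  data points by the local ECDF granularity. This is left as is — forcing
  per-cell decay bounds would modify the table away from the raw counts —
  and the tests assert monotonicity up to that granularity.
- **p floor.** p-values are floored at 1e-300 so −log₁₀p stays finite.
- **Degenerate inputs.** An empty base stratum, a panel of fewer than two
  SNPs, fewer than `min_snps` (default 100) SNPs for λ estimation, and
  λ ≤ 0 all raise typed errors rather than returning values.
- **Tie-breaks.** Clump leads break FDR ties by smaller p then smaller
  position; nearest-gene ties go to the smaller start coordinate;
  duplicate SNP ids on input keep the record with the larger sample size;
  duplicate LD pairs keep the larger r².

## The synthetic-data generator

The generator emulates exactly the structure the estimator consumes, not
a population-genetic process. Per SNP a class label is drawn from
(null, shared, spec1, spec2) with configured fractions; causal classes
receive z-scale offsets δ ~ N(0, effect_sd²) in the affected trait(s).
For shared SNPs the sign of δ₂ is set to agree with δ₁ with probability
`sign_concordance` (a Bernoulli flip of the independently drawn
magnitude); at 0.5 the shared component contributes zero expected
cross-trait covariance while every shared SNP still carries genuine
effects in both traits — the mixed-direction regime. LD is
block-diagonal and compound-symmetric: within a block of size b all pairs
have the configured r², implemented as
z = Rδ + ε, ε ~ N(0, R), with R the block correlation matrix at
r = √r², so null blocks are exchangeable correlated standard normals and
causal effects spread to their LD partners. Gene intervals are generated
so a configured fraction of SNPs falls strictly outside all intervals
("intergenic"). Defaults: 10,000 SNPs, 2 chromosomes, no LD, 30%
intergenic, effect SD 3, concordance 0.5 — the acceptance simulations use
100,000 independent SNPs with 0.5%/0.5%/0.5% shared/specific fractions
and effect SD 3.

What it does **not** emulate: MAF-dependent architectures, realistic LD
decay or haplotype structure, sample overlap between studies,
population stratification, or case-control liability scaling. Passing
simulation tests therefore demonstrates the statistical machinery
(stratification, averaging, FDR calibration under exchangeable LD), not
robustness to those real-data features.

## Calibration behaviour

On the 100,000-SNP independent-SNP design the conjunctional calls are
strongly conservative (truth-based FDP far below the 0.05 threshold —
the max rule requires both directions to clear their bound). The
conditional calls at 0.01 average a truth-based FDP slightly above
nominal (~0.013–0.015 across seeds): the estimator evaluates each SNP in
the stratum selected by its own conditioning p-value, and aggregating
calls across nested strata breaks the exact Benjamini–Hochberg-style
guarantee that holds within any single stratum. This mild
anticonservativity is inherent to the naive conditional-FDR estimator
(an exact direct-count variant without the grid measures ~0.025 on the
same design; the coarse conditioning grid and the sparse-cell fallback
are conservative relative to it). π₀ = 1 bounds the null fraction but
does not absorb the stratum-selection effect.

## Problem sizes

The shipped tests run the full estimator at 100,000 SNPs × 20 seeds for
the calibration checks and 20,000-SNP panels for QQ-behaviour checks;
the end-to-end pipeline tests use 5,000–20,000 SNP panels with 20
pruning iterations. These sizes give Monte-Carlo error comfortably below
the asserted tolerances while keeping the suite quick; all of them are
plain parameters of the simulation configs and scale up unchanged.

## Known limitations

- π₀ is fixed, not estimated; condFDR is an upper-bound-style estimate.
- The lookup's conditioning axis treats p2 through its −log₁₀ grid cell;
  extremely fine conditioning structure between grid nodes is smoothed.
- Clumping uses LD connectivity only (a kb-window rule is not applied by
  default), so chained LD can merge physically distant SNPs into one
  locus.
- The generator's compound-symmetric blocks make "one SNP per LD block"
  unambiguous; on real panels with chained LD the random-maximal-
  independent-set rule is one of several defensible readings of that
  instruction.
- With LD present, truth labels understate effective discoveries: a
  null-labelled SNP in LD with a shared causal SNP carries real signal in
  both traits, so label-based FDP overstates the error rate on LD panels.
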