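# Methods

## Model

The methylation pattern of an *n*-CpG segment on a single DNA molecule is a
binary random vector **X** = [X₁, …, Xₙ] with marginals Xᵢ ~ Bern(pᵢ) —
pᵢ the per-site methylation probability (MP) — and correlation matrix **R**
with entries r_ij = cor(Xᵢ, Xⱼ), the spatial (co-methylation) correlation.
Each off-diagonal r_ij is constrained by the Fréchet bounds on the joint
success cell: P(Xᵢ=1, Xⱼ=1) ∈ [max(0, pᵢ+pⱼ−1), min(pᵢ, pⱼ)], mapped to the
correlation scale by `pairwise_correlation_bounds`.  Two named structures
are built in: exchangeable (r_ij = r) and AR(1) (r_ij = r^|i−j|).

The methylation entropy (ME) of the segment is the Shannon entropy, in
bits, of the joint distribution {q₀, …, q_{2ⁿ−1}} over the 2ⁿ patterns,

    S = − Σᵢ qᵢ log₂ qᵢ,   0·log 0 := 0,

indexed so that the **last** CpG site is the least-significant bit
(q₁ ↔ [0,…,0,1]).  For independent sites S reduces to a sum of per-site
binary entropies; for homogeneous methylation it is n·H(p).

### Latent-Gaussian thresholding

For correlated sites with n > 2 the joint distribution is not determined in
closed form by (p, R); the package constructs it by dichotomizing a latent
multivariate normal: Xᵢ = 1 iff Zᵢ ≤ zᵢ with zᵢ = Φ⁻¹(pᵢ) and
Z ~ MVN(0, Σ).  Each Σ_ij solves the tetrachoric-type equation
Φ₂(zᵢ, zⱼ; Σ_ij) = r_ij·√(pᵢ(1−pᵢ)pⱼ(1−pⱼ)) + pᵢpⱼ by Brent root finding on
[−1, 1] (the left side is monotone in Σ_ij); the residual tolerance is
1e−8.  A pairwise-assembled Σ that fails positive semi-definiteness is
projected to the nearest correlation matrix (statsmodels `corr_nearest`),
flagged, and refused when any entry moves by more than 0.01; the
exchangeable and AR(1) structures used throughout never need repair.

Pattern probabilities are multivariate-normal rectangle probabilities.
Three evaluation paths, in decreasing order of specialization:

* **n = 2**: exact closed form, q₁₁ = p₁p₂ + r·√(p₁(1−p₁)p₂(1−p₂)) etc.
* **Equicorrelated Σ with ρ ≥ 0** (homogeneous exchangeable models): the
  1-factor representation Zᵢ = √ρ·W + √(1−ρ)·εᵢ makes sites conditionally
  independent given W; one composite Gauss–Legendre quadrature over W
  (48 nodes per panel, panel edges bracketing the conditional-probability
  transition regions so accuracy survives ρ → 1) yields all 2ⁿ pattern
  probabilities at once, to ~1e−10.
* **General Σ, n ∈ {3, 4}**: recursive 1-D conditioning — integrate the
  first coordinate over its rectangle with Gauss–Legendre (64 nodes,
  truncated at ±8.5) and evaluate the conditional rectangle, bottoming out
  in the exact bivariate CDF computed through Owen's T function (machine
  precision).  Validated against scipy's Genz MVN CDF at abseps 1e−8 to
  ~6e−9; scipy's implementation is kept as a test oracle only because at
  this accuracy it costs ~0.3 s per 4-d evaluation.

All paths exceed the package-wide normalization check |Σqᵢ − 1| ≤ 1e−6,
after which q is clipped at 0 and renormalized.  Degenerate sites
(pᵢ ∈ {0, 1}) are allowed in the distribution (held constant; their
correlations must be 0) but rejected where a correlation must be solved,
since it is undefined at zero variance.  Perfect latent comonotonicity
(ρ = 1) is handled exactly through the nested-pattern representation.

Sampling thresholds i.i.d. MVN draws (eigendecomposition square root, so
singular Σ is fine) at z; a single `numpy.random.Generator` is threaded
explicitly through every stochastic operation — no global RNG state.

## Statistics

For a segment fully covered by m reads (an m×n binary matrix x):

* **OME** Ŝ = −Σ (Oᵢ/m) log₂(Oᵢ/m), the plug-in entropy of the observed
  pattern counts Oᵢ.  The plug-in estimator is biased downward at small m
  (patterns missing from the sample can only reduce entropy); the package
  implements exactly this estimator, and the consistency tests assert a
  shrinking gap with m rather than unbiasedness.
* **ML / MML**: per-site column means x̄ⱼ and their grand mean.
* Logarithms are base 2 throughout, so entropies are in bits and bounded
  by min(n, log₂ m) for the OME.

## Testing for spatial correlation

Goodness of fit of the observed pattern counts to the independence null
H₀: r_ij = 0 ∀ i≠j, with expected counts Eᵢ = m·qᵢ from the product form at
the plug-in marginals: χ² = Σ (Oᵢ−Eᵢ)²/Eᵢ on 2ᵏ − 1 − k degrees of freedom,
where k counts sites with 0 < x̄ⱼ < 1 (one df lost per estimated MP).
Degenerate sites are dropped — they carry no correlation information and
make the df formula ill-defined — and a segment with k < 2 is reported
untestable rather than erroring, which keeps real-data segments with
constant sites in the workflow.  No minimum-expected-count rule and no
continuity correction are applied, even at m = 20 with 16 cells; the
smallest expected count is recorded in the result for diagnostics.  After
dropping degenerate sites every Eᵢ is strictly positive.

The structured variant tests H₀: "exchangeable (or AR(1)) correlation at a
*specified* r" by swapping the product-form null for the latent-Gaussian
distribution at (x̄, structure, r).  Because r is fixed by the hypothesis
rather than estimated, the degrees of freedom stay 2ᵏ − 1 − k; this is the
package's choice where the convention is genuinely open.  AR(1) distances
use the original site indexing even when degenerate sites were dropped.
An r infeasible for the estimated marginals yields an untestable result
carrying the reason.

## Bipolar methylated loci and two-sample comparisons

A segment is a bipolar methylated locus when (i) its MML lies strictly
inside (0.2, 0.8) and (ii) its OME falls below the theoretical ME of a
strongly co-methylated segment — homogeneous exchangeable correlation at
r_threshold (default 0.6) — evaluated at the segment's MML.  These two
conditions alone define the flag; the spatial-test p-value is attached as
metadata, with a strict mode additionally requiring rejection at 0.05.
Raising r_threshold lowers the entropy curve and can only remove loci.

DMRs between two samples of the same segment: methylated/unmethylated call
counts pooled over all n sites and m reads form a 2×2 table tested by
Pearson chi-square (1 df, no continuity correction); a zero margin gives
p = 1, flagged degenerate.  Pooling calls is this package's reading of a
"standard chi-square test on the MMLs"; it treats calls within a read as
exchangeable evidence.  No multiple-testing correction is applied by
default (per-segment 0.05), with Bonferroni available to callers.

Association between bipolar and DMR flags on a common segment list uses
Fisher's exact test (two-sided, probability-mass definition with relative
tolerance 1e−7 against floating ties) and the *conditional-MLE* odds
ratio — the sample cross-product ratio of the reference table
[[161,30],[527,248]] is 2.5255 while the conditional MLE is 2.523,
matching the convention of standard Fisher-test implementations.  Both are
delegated to scipy (`fisher_exact`, `contingency.odds_ratio`); a
brute-force hypergeometric enumeration over all tables with the observed
margins serves as the independent oracle in the tests.

## Segment extraction

Input is a per-read TSV (read_id, chrom, comma-separated ascending 1-based
CpG positions, 0/1 state string).  Coordinates are 0-based internally;
output intervals are 0-based half-open and span both bases of the terminal
CpG dinucleotide.  Windows of n = 4 consecutive distinct CpG coordinates
slide with step 1 by default ("all 4-CpG segments" read as all windows;
a disjoint step-n mode is exposed because the published segment counts
cannot distinguish the two without the raw data).  A read joins a window
only if it covers every site — no imputation — and a window is emitted at
depth ≥ 20 by default.  Extraction is order-independent: reads are sorted
into a canonical order, so shuffled input produces identical matrices.
Duplicate read identifiers are treated as distinct reads.

## Simulation studies

* **Calibration/power of the spatial test.**  Cells (n, m) ∈ {2,3,4} ×
  {20,…,100}.  Null: each replicate draws a fresh nonhomogeneous MP vector
  from Unif(0.3, 0.7) and independent Bernoulli reads; 10,000 replicates.
  Alternative: reads from the correlated sampler at exchangeable or AR(1)
  r ∈ {0.3, 0.4}; 1,000 replicates.  An MP draw infeasible for the target
  r is re-drawn (up to 100 times; impossible for these ranges, since the
  tightest pairwise bound, at (0.3, 0.7), is 0.4286 > 0.4).  Untestable
  replicates count as non-rejections.
* **OME vs. MML.**  500 segments, n = 4; one homogeneous p ~ Unif(0, 1)
  per segment; exchangeable r ~ Unif(0, 1) for 90% of segments, r = 0 for
  10%.  Reads are redrawn independently at each depth m ∈ {20,…,100} (the
  simpler contract where reuse across depths is unspecified).  Segments
  with p drawn near 0 or 1 can be untestable (k < 2); they are reported
  non-significant.
* **Seeding.**  A master seed plus the cell coordinates feed a
  `numpy.random.SeedSequence`, so any cell is reproducible in isolation
  and cells are mutually independent; each result table carries its
  config in `DataFrame.attrs`.

### Two-sample synthetic data

The generator plants cell-type-specific methylation: "signal" segments
methylate each site at 0.98 in sample A and 0.02 in sample B (independent
noise within a sample), so pooling the samples yields an MML near 0.5 with
reads concentrated on the all-1/all-0 patterns (population entropy
≈ 1 + 4·H(0.02) ≈ 1.57 bits, well below the r = 0.6 threshold curve's
≈ 2.95 bits at MML 0.5); "null" segments methylate independently at
p = 0.5 in both samples (entropy ≈ 4 bits, never bipolar).  Defaults: 40
signal + 40 null segments, 100 reads per sample per segment, 4 CpG sites
10 bp apart, segments 500 bp apart so windows never straddle segments.
What this does *not* emulate: within-sample co-methylation at intermediate
correlation, read-depth variation, partially covering reads, strand
effects, or sequencing error; recovering the planted structure therefore
validates the pipeline's plumbing and decision rules, not its behavior on
the full complexity of real bisulfite data.

## Numerical and design choices

* Bivariate normal CDF via Owen's T with explicit branches for zero and
  infinite arguments and |ρ| = 1; validated against scipy to 2e−16.
* Brent solves use xtol 1e−13; feasibility checks allow 1e−9 slack so
  boundary correlations (e.g. r at its Fréchet bound) resolve to ρ = ±1
  instead of erroring.
* Entropy curves default to the p-grid 0.005…0.995 (step 0.005), avoiding
  log 0 at the ends; `me_exchangeable` memoizes on (n, p, r) rounded to
  12 decimals, since segment classification re-evaluates the same
  threshold curve repeatedly.
* Chi-square tail probabilities through `scipy.special.chdtrc` (cheap
  enough for 150,000 calls in the calibration study).
* The BED score is round(1000·(1 − OME/n)), so fully bipolar segments
  (OME → 0 impossible at MML 0.5; OME = 1 bit gives 750) score high.

## Problem sizes

Default study conditions run the full published grids: 150,000 null
replicates for the calibration table, 60,000 for the four power tables,
and 2,500 segment×depth draws for the scatter study — together a few
minutes on one core.  The acceptance script runs the scatter study at the
single depth m = 80 it reports.

## Known limitations

* Negative exchangeable correlations beyond pairwise feasibility are out
  of scope (all studies use r ≥ 0); the general-Σ path accepts negative
  pairwise correlations where feasible.
* The general rectangle path is implemented for the small n this method
  uses (n ≤ 4 beyond the specialized paths); larger segments would want a
  proper Genz quasi-Monte-Carlo integrator.
* The plug-in OME is not bias-corrected (no Miller–Madow variant), by
  design: the detection rules are calibrated against the same plug-in
  quantity the published workflow uses.
* Strand collapsing and alignment are upstream of the input format; the
  caller must provide forward-strand CpG cytosine positions.
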