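# Methods

## The model

`epichi` tests for main effects and epistatic interactions of arbitrary
order among biallelic SNPs in a case-control sample. The quantitative-genetic
backbone is the Mather–Jinks (F-infinity) parameterisation: at a single
locus with genotype classes `AA`, `Aa`, `aa` the genotypic values are

    G_AA = mu + a,    G_Aa = mu + d,    G_aa = mu - a,

so `a` is half the homozygote difference and `d` the heterozygote's
deviation from the homozygote midpoint. For `n` loci the 3^n genotypic
values decompose into 3^n effects — the overall mean, per-locus `a` and `d`
main effects, and every interaction product (`i_aa`, `i_ad`, …,
`i_dd...d`) — through the n-fold Kronecker product of the one-locus 3×3
design matrix

    L = [[1, 1, 0],
         [1, 0, 1],
         [1, -1, 0]]    (rows AA, Aa, aa; columns mu, a, d).

Because the solver is built as the Kronecker power of the analytic inverse
of `L` (entries ±1/2 and 1), both maps are exact up to floating rounding:
`design @ solver` is the identity to < 1e-12 for all supported locus counts
(capped at 8, i.e. 6561 genotype classes, purely to bound the dense-matrix
memory). Genotypes and effects share a base-3 flat index with locus 1 most
significant; dataset dosages (copies of the designated allele) map as
2→`AA`, 1→`Aa`, 0→`aa`. All statistics are invariant to which allele is
designated, which is tested.

This is deliberately the *unweighted* metric — effects are not
orthogonalised against allele frequencies. Frequency-weighted (NOIA-style)
parameterisations are out of scope.

## The test

For one effect the solver row assigns each genotype class a signed
coefficient. Classes with positive coefficients form the "plus" group,
negative the "minus" group, and cases and controls are tallied into a 2×2
(case/control × plus/minus) table using the coefficients *rescaled so the
largest magnitude is 1* as weights. The rescaling matters: for additive-only
effects it makes the table an ordinary integer count table whose Pearson
statistic is asymptotically chi-square with 1 df (this equivalence is tested
against an independent textbook implementation), while raw solver
coefficients would shrink the statistic by (1/2)^order and detach it from
any standard calibration. The statistic is the uncorrected Pearson

    X^2 = N (ad - bc)^2 / (r1 r2 c1 c2),

compared against an effect-specific critical value; ties count as
significant. No continuity correction is applied, because the thresholds are
calibrated rather than nominal.

Loci that enter an effect through their mean component are marginalised
(weight 1 for every class at that locus), so a pairwise or main-effect
statistic computed inside a wider analysis equals the statistic on the
marginal counts — the alternative reading (using the mean solver row, which
is (1/2, 0, 1/2) and would *drop heterozygotes*) breaks that consistency
and is not used.

### Thresholds

Additive-only effects use the 1-df 5% point, 3.84. Effects with dominance
components have fractional weights (±1/2 per dominance component at a
homozygote class), which deflates the null distribution below a full 1-df
chi-square; their critical values are smaller. The shipped lookup, keyed by
(order, dominance count), is

| order | dominance | threshold |
|-------|-----------|-----------|
| 1     | 0         | 3.84      |
| 1     | 1         | 2.60      |
| 2     | 0         | 3.84      |
| 2     | 1         | 3.20      |
| 2     | 2         | 2.50      |
| 3     | 0         | 3.84      |
| 3     | 1         | 3.20      |
| 3     | 2         | 2.60      |
| 3     | 3         | 2.14      |

The derivation behind the fractional-df values is not reproduced here;
instead `calibrate_threshold_mc` re-derives any threshold empirically as the
0.95 null quantile under a configurable null (default: independent loci in
HWE, MAF 0.5, 500 cases / 500 controls, 5000 replicates). Under that default
the calibrated quantiles come out at roughly 3.85, 3.2, 2.6 and 2.2 for
dominance counts 0–3 — the same strict ordering and, to Monte-Carlo error,
the same values as the lookup. Effects of order > 3 always go through
Monte-Carlo calibration (cached by order and dominance count, which by the
exchangeability of the default null fully determine the distribution).
`permutation_threshold` offers a dataset-conditional alternative by label
shuffling; conditioning on the observed margins makes its quantile
discrete, so it can sit a few tenths below the unconditional Monte-Carlo
value on moderate samples.

### p-values

Significance is decided only by the threshold. Two descriptive upper-tail
probabilities are attached to each statistic: `p_raw`, the plain 1-df
chi-square tail (exact for additive-only effects, conservative for
dominance-containing ones), and `p_calibrated`, the 1-df tail of
`chi2 * 3.84 / threshold` — a convenience rescaling that maps the effect's
own critical value onto the 5% point. Neither feeds the significance flag.

## Scanning

`scan(dataset, k)` tests all 3^k − 1 effects for every k-subset of SNPs.
Missingness is handled per subset (complete-case within the subset), so
each subset uses the maximal available samples; `n_used` is reported per
record. Degenerate strata (a zero table margin, e.g. a monomorphic SNP or
an empty arm) yield `chi2 = 0` with a `degenerate` flag instead of an
error. Bonferroni and Benjamini–Hochberg columns over `p_raw` are opt-in
annotations and never alter the threshold-based flag, since the method's
error control lives in the per-effect thresholds.

For interpretation, `group_effect_table` applies the solver separately to
the case and control count vectors, giving each group's counts in effect
coordinates; the case-minus-control difference localises which component
separates the groups, and `genotype_components` renders any genotype's
count as its signed sum of components.

## The simulator

The generator emulates the sampling scheme of a retrospective case-control
study of a small candidate-gene SNP panel:

* **Genotype frequencies.** Bennett's decomposition builds haplotype
  frequencies from per-locus allele frequencies plus pairwise D and
  three-way D_ABC coefficients (closed form up to three loci; any 2^n
  haplotype vector can be supplied directly beyond that), validated for
  feasibility. Random mating at the haplotype level expands these to
  multilocus genotype frequencies.
* **Penetrance.** Effects are specified sparsely on the linear penetrance
  scale and composed through the design matrix; any composed penetrance
  outside [0, 1] raises an error rather than being clipped, so infeasible
  effect sizes are impossible to simulate silently.
* **Sampling.** Case genotype-class probabilities are proportional to
  frequency × penetrance, controls to frequency × (1 − penetrance); counts
  are two independent multinomials.

Default study conditions follow the simulation design the test was
characterised under: MAF 0.5 at every locus, HWE, independent loci for the
"independent" scenario and pairwise D = 0.05 with D_ABC = 0.01 (feasible at
MAF 0.5) for the "associated" scenario; sample sizes 200, 400 and 1000 per
arm; the four representative three-way forms aaa, aad, add, ddd; a baseline
penetrance of 0.3. The published characterisation does not state its effect
magnitudes, so `calibrate_effect_size` bisects a form's magnitude until
empirical power at a reference design lands in a target band (common random
numbers make the power curve monotone in the magnitude, so bisection is
valid); the headline reproduction calibrates aaa power at 200 v 200 into
0.51–0.61, which lands near a magnitude of 0.12 and yields ≥ 0.99 power at
1000 v 1000. In a power study each form's false positive rate is measured
in companion simulations with that one form's magnitude zeroed and all
other planted forms kept, matching a "this effect absent, all else equal"
null.

What the generator does *not* emulate: genotyping error, missingness
mechanisms, covariate or population structure, haplotype-level effects, and
more than three loci in the closed-form LD path. Passing simulation tests
therefore demonstrate the statistical behaviour of the test under clean
retrospective sampling, not robustness to real-data artefacts.

Randomness: every sampler takes a single seed; the power study derives
per-cell substreams from the master seed by counter (`SeedSequence`
spawn keys), so individual cells are reproducible in isolation and
parallelisable.

## Numerical and design choices

* The solver is never obtained by numeric inversion — always the Kronecker
  power of the analytic 3×3 inverse — so effect estimates are exact dyadic
  rationals up to float rounding.
* Monte-Carlo thresholds use the default linear-interpolation empirical
  quantile; `alpha >= 1` short-circuits to 0 (the statistic is
  nonnegative). Calibration enforces ≥ 1000 replicates.
* Degenerate 2×2 margins return `chi2 = 0` with a flag rather than NaN.
* Complete-case handling is per SNP subset; the undeposited study data this
  workflow mirrors had no stated missing-data rule, and per-subset
  complete-case matches common association-scan practice.
* VCF input designates ALT as the counted allele; tabular input counts
  whatever allele the dosage column encodes. Because every statistic is
  invariant to allele relabeling (tested), no frequency-based
  reorientation is performed.
* Replicate counts in the shipped tests (1000–5000 null replicates,
  2000-replicate rejection-rate checks, ten pooled replicate panels for the
  scan null-control check) were sized so that Monte-Carlo standard errors
  are small against the asserted tolerances while the whole suite runs in a
  few seconds.

## Known limitations

* The fractional-df thresholds (3.20 / 2.60 / 2.50 / 2.14) are shipped as
  published constants; their original derivation's null model is not
  documented, so Monte-Carlo calibration under a different null (unequal
  arms, extreme MAF) may legitimately disagree with them. Both the printed
  and the calibrated values are available; significance uses the printed
  ones by default.
* The Pearson statistic on weighted tables is anti-conservative for very
  small per-group counts (it is a large-sample statistic); with ~25 samples
  per arm in the tested cells the null rejection rate of the additive-only
  test runs a fraction of a point above 5%.
* Exhaustive scanning is O(C(m, k) · 3^k); the package targets candidate
  panels (tens of SNPs), not genome-wide data.
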