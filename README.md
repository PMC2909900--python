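# epichi

Detection of main effects and epistatic interactions of arbitrary order
among biallelic SNPs in case-control studies.

Complex-disease risk rarely traces to single variants: alleles at different
loci interact, and interactions above second order are largely invisible to
the pairwise scans most association toolkits offer. `epichi` implements a
quantitative-genetic chi-square framework that dissects the joint
distribution of multilocus genotypes in cases and controls into an overall
mean, per-locus additive (`a`) and dominance (`d`) main effects, and
epistatic components of every order (`i_aa`, `i_ad`, …, `i_ddd`), and tests
each component separately. It is aimed at candidate-gene and small-panel
association studies — tens of SNPs, hundreds to thousands of cases and
controls — and at methodologists studying the power and error behaviour of
interaction tests.

## The model and test

Under the Mather–Jinks (F-infinity) metric, the 3^n genotypic values of an
n-locus system decompose linearly into 3^n genetic effects through the
n-fold Kronecker product of the one-locus design

    G_AA = mu + a,   G_Aa = mu + d,   G_aa = mu - a.

Each effect's solver row splits the genotype classes into a *plus* and a
*minus* group with relative weights in {±(1/2)^k}. Cases and controls are
tallied into a weighted 2×2 (case/control × plus/minus) contingency table
and its uncorrected Pearson statistic

    X² = N (ad − bc)² / (r₁ r₂ c₁ c₂)

is compared with an effect-specific critical value: 3.84 (the 1-df 5%
point) for additive-only effects, and calibrated values 3.20 / 2.60 / 2.50 /
2.14 for dominance-containing effects, whose fractional weights deflate the
null distribution below a full degree of freedom. Thresholds for any
pattern can be re-derived by Monte-Carlo null calibration or permutation.
On top of the test sit exhaustive k-SNP subset scans, group-wise effect
decompositions for interpreting hits, and a retrospective-sampling
simulator (allele frequencies, pairwise and three-way linkage
disequilibrium, penetrance-scale effect specs) for power and
false-positive-rate studies. See `docs/methods.md` for the full account.

## Worked example

Simulate 400 cases and 400 controls from three independent SNPs (MAF 0.5,
HWE) whose penetrance carries a pure additive×additive×additive
interaction of magnitude 0.25 on a baseline of 0.3, then fit the
three-locus model:

```python
from epichi import (MultilocusEpistasis, EffectLabel, EffectSpec,
                    build_population, hwe_genotype_freqs, sample_case_control)

model = build_population(
    EffectSpec(n=3, baseline=0.3,
               effects={EffectLabel.from_pattern("aaa"): 0.25}),
    freqs=hwe_genotype_freqs(3, maf=0.5))
counts = sample_case_control(model, n_case=400, n_ctl=400, seed=11)
res = MultilocusEpistasis.from_counts(
    counts, snp_ids=["rs101", "rs102", "rs103"]).fit()
print(res.summary())
```

The summary lists all 26 testable effects; the tail of the output reads

    i_aaa(A,B,C)         43.107   3.84    *    0.0000    0.0000
    i_aad(A,B,C)          2.633   3.20         0.1047    0.0755
    i_ada(A,B,C)          0.248   3.20         0.6184    0.5853
    ...
    i_ddd(A,B,C)          0.003   2.14         0.9540    0.9384

The planted three-way interaction is recovered decisively
(`i_aaa(A,B,C)`: X² = 43.1 against its threshold 3.84, 1-df p ≈ 5e-11). Two
of the 25 null effects (`i_aa(A,C)`, X² = 5.85; `i_ad(B,C)`, X² = 4.38)
also cross their thresholds — the expected order of false positives when 25
effects are each tested at the ~5% level. The columns are the statistic,
the effect-specific threshold, the significance flag, the plain 1-df
upper-tail `p_raw`, and `p_calibrated` (the 1-df tail after rescaling the
statistic by 3.84/threshold); significance is decided only by the
threshold.

Datasets load from delimited dosage tables (`read_genotype_table`) or
biallelic VCF plus a phenotype sidecar (`read_vcf`), and
`scan(dataset, k)` runs every k-subset. The same operations are available
from the shell:

    epichi simulate --effects aaa=0.2 --n-case 200 --n-ctl 200 -o panel.tsv
    epichi scan panel.tsv -k 3 -o records.tsv
    epichi calibrate ddd --reps 5000
    epichi power --sizes 200,400,1000 --reps 1000 -o power.tsv

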