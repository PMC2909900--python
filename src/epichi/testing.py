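"""Per-effect plus/minus chi-square tests for case-control genotype counts.

Each genetic effect splits the 3**n genotype classes into a "plus" and a
"minus" group with relative weights taken from the effect's row of the
solver matrix.  Cases and controls are tallied into a weighted 2x2
contingency table (cases/controls x plus/minus) and a Pearson chi-square
statistic is compared against an effect-specific critical threshold.

Additive-only effects have all weights in {0, +1, -1}, so their table is an
ordinary count table and the statistic is asymptotically 1-df chi-square:
their threshold is the familiar 3.84.  Dominance-containing effects carry
fractional weights, which deflate the null distribution to "less than one
degree of freedom"; their thresholds are smaller (3.20, 2.60, 2.50, 2.14 for
the patterns up to three loci) and can be re-derived empirically by Monte
Carlo (:func:`calibrate_threshold_mc`) or by permutation
(:func:`permutation_threshold`) for any pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .effects import (
    EffectLabel,
    LocusComponent,
    build_decomposition,
    effect_label,
)

__all__ = [
    "CaseControlCounts",
    "WeightedTable",
    "TestResult",
    "ThresholdTable",
    "PRINTED_THRESHOLDS",
    "plus_minus_weights",
    "build_table",
    "pearson_chi2",
    "threshold_for",
    "calibrate_threshold_mc",
    "permutation_threshold",
    "test_effect",
    "test_all",
]

#: Critical chi-square thresholds by (order, dominance count), as printed for
#: main effects and for two- and three-way epistasis.  Additive-only effects
#: sit at the nominal 1-df 5% point, 3.84; adding dominance components lowers
#: the null quantile (fractional degrees of freedom).
PRINTED_THRESHOLDS: dict[tuple[int, int], float] = {
    (1, 0): 3.84, (1, 1): 2.60,
    (2, 0): 3.84, (2, 1): 3.20, (2, 2): 2.50,
    (3, 0): 3.84, (3, 1): 3.20, (3, 2): 2.60, (3, 3): 2.14,
}

#: The 1-df 5% critical value used to rescale calibrated p-values.
_CHI2_1DF_95 = 3.84


@dataclass(frozen=True)
class CaseControlCounts:
    """Genotype-class counts for cases and controls over 3**n classes."""

    n: int
    case_counts: np.ndarray
    control_counts: np.ndarray

    def __post_init__(self) -> None:
        size = 3 ** self.n
        cc = np.asarray(self.case_counts, dtype=np.int64)
        ct = np.asarray(self.control_counts, dtype=np.int64)
        if cc.shape != (size,) or ct.shape != (size,):
            raise ValueError(f"count vectors must have length {size}")
        if (cc < 0).any() or (ct < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "case_counts", cc)
        object.__setattr__(self, "control_counts", ct)

    @property
    def n_cases(self) -> int:
        return int(self.case_counts.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_counts.sum())

    @property
    def degenerate(self) -> bool:
        """True when either arm has no genotyped samples."""
        return self.n_cases == 0 or self.n_controls == 0


@dataclass(frozen=True)
class WeightedTable:
    """Weighted 2x2 contingency table (cases/controls x plus/minus)."""

    case_plus: float
    case_minus: float
    control_plus: float
    control_minus: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.case_plus, self.case_minus],
                         [self.control_plus, self.control_minus]])


@dataclass(frozen=True)
class TestResult:
    """Outcome of one per-effect test."""

    effect: EffectLabel
    chi2: float
    threshold: float
    significant: bool
    p_raw: float
    p_calibrated: float
    degenerate: bool = False
    table: WeightedTable | None = field(default=None, compare=False)


# Per-locus weight rows: the normalized solver rows for additive and
# dominance components.  A MEAN component marginalises the locus out, i.e.
# every class at that locus enters with weight 1, so that (for example) a
# pairwise statistic computed inside a three-locus analysis equals the plain
# two-locus statistic on the marginal counts.
_COMPONENT_WEIGHTS = {
    LocusComponent.MEAN: np.array([1.0, 1.0, 1.0]),
    LocusComponent.ADDITIVE: np.array([1.0, 0.0, -1.0]),
    LocusComponent.DOMINANT: np.array([-0.5, 1.0, -0.5]),
}


def plus_minus_weights(effect: EffectLabel, n: int | None = None) -> np.ndarray:
    """Signed weight vector over the 3**n genotype classes for one effect.

    Weights are the effect's solver-row coefficients rescaled so the largest
    magnitude is 1 (entries are 0 or +/-(1/2)**k with k the number of
    dominance components a class passes through); positive weights define the
    "plus" group, negative the "minus" group.  Loci with a MEAN component are
    marginalised (weight 1 for every class).

    Raises
    ------
    ValueError
        For the overall-mean label (no test exists for mu) or an ``n``
        inconsistent with the label.
    """
    if effect.is_mean:
        raise ValueError("the overall mean mu has no plus/minus test")
    if n is not None and n != effect.n:
        raise ValueError(f"effect spans {effect.n} loci, expected {n}")
    w = np.array([1.0])
    for comp in effect.components:
        w = np.kron(w, _COMPONENT_WEIGHTS[comp])
    return w


def build_table(counts: CaseControlCounts, effect: EffectLabel) -> WeightedTable:
    """Weighted plus/minus sums of case and control counts for one effect."""
    if effect.n != counts.n:
        raise ValueError(f"effect spans {effect.n} loci, counts have {counts.n}")
    w = plus_minus_weights(effect)
    wp = np.clip(w, 0.0, None)
    wm = np.clip(-w, 0.0, None)
    return WeightedTable(
        case_plus=float(wp @ counts.case_counts),
        case_minus=float(wm @ counts.case_counts),
        control_plus=float(wp @ counts.control_counts),
        control_minus=float(wm @ counts.control_counts),
    )


def pearson_chi2(table: WeightedTable) -> tuple[float, bool]:
    """Pearson statistic N(ad-bc)^2 / (r1 r2 c1 c2), no continuity correction.

    Returns ``(chi2, degenerate)``; a zero row or column margin yields
    ``(0.0, True)`` rather than an error so scans over monomorphic or empty
    strata keep going.
    """
    a, b = table.case_plus, table.case_minus
    c, d = table.control_plus, table.control_minus
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom <= 0.0:
        return 0.0, True
    n_tot = a + b + c + d
    return float(n_tot * (a * d - b * c) ** 2 / denom), False


@dataclass
class ThresholdTable:
    """Critical-value lookup by effect pattern, with Monte-Carlo fallback.

    The printed per-pattern values cover orders 1-3; higher-order patterns
    are calibrated on demand under a configurable null (independent loci in
    Hardy-Weinberg equilibrium, MAF 0.5, 500 cases / 500 controls by default)
    and cached by (order, dominance count) — by symmetry of the default null
    the threshold depends on the pattern only through those two numbers.
    """

    maf: float = 0.5
    n_case: int = 500
    n_ctl: int = 500
    reps: int = 5000
    alpha: float = 0.05
    seed: int = 20100818
    _cache: dict[tuple[int, int], float] = field(default_factory=dict)

    def threshold_for(self, effect: EffectLabel) -> float:
        key = (effect.order, effect.dominance_count)
        if key in PRINTED_THRESHOLDS:
            return PRINTED_THRESHOLDS[key]
        if key not in self._cache:
            # collapse MEAN loci: the marginalised test only sees the
            # participating loci, so calibrate in the reduced system
            reduced = EffectLabel(tuple(
                c for c in effect.components if c is not LocusComponent.MEAN))
            p, q = self.maf, 1.0 - self.maf
            locus = np.array([p * p, 2 * p * q, q * q])  # class order AA,Aa,aa
            freqs = np.array([1.0])
            for _ in range(reduced.n):
                freqs = np.kron(freqs, locus)
            self._cache[key] = calibrate_threshold_mc(
                reduced, freqs, self.n_case, self.n_ctl,
                reps=self.reps, alpha=self.alpha,
                seed=self.seed + 7919 * (3 * key[0] + key[1]))
        return self._cache[key]

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for (order, dom), val in sorted({**PRINTED_THRESHOLDS,
                                             **self._cache}.items()):
                fh.write(f"order={order}\tdominance={dom}\tthreshold={val:.4f}\n")


_DEFAULT_THRESHOLDS = ThresholdTable()


def threshold_for(effect: EffectLabel,
                  thresholds: ThresholdTable | None = None) -> float:
    """Critical value for one effect (printed for orders <= 3, MC beyond)."""
    return (thresholds or _DEFAULT_THRESHOLDS).threshold_for(effect)


def _stats_from_count_matrices(case_mat: np.ndarray, ctl_mat: np.ndarray,
                               w: np.ndarray) -> np.ndarray:
    """Vectorised plus/minus chi-square over (reps, 3**n) count matrices."""
    wp = np.clip(w, 0.0, None)
    wm = np.clip(-w, 0.0, None)
    a = case_mat @ wp
    b = case_mat @ wm
    c = ctl_mat @ wp
    d = ctl_mat @ wm
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    n_tot = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, n_tot * (a * d - b * c) ** 2 / denom, 0.0)
    return out


def calibrate_threshold_mc(effect: EffectLabel,
                           genotype_freqs: np.ndarray,
                           n_case: int,
                           n_ctl: int,
                           reps: int = 5000,
                           alpha: float = 0.05,
                           seed: int = 0) -> float:
    """Monte-Carlo null critical value for one effect.

    Cases and controls are drawn from the same multinomial genotype
    distribution (no association), the plus/minus statistic is computed for
    each replicate, and the empirical ``1 - alpha`` quantile is returned.

    Parameters
    ----------
    genotype_freqs
        Null genotype-class distribution over the 3**effect.n classes.
    reps
        Number of null replicates; at least 1000 for a usable 5% quantile.
    """
    if reps < 1000:
        raise ValueError("need at least 1000 replicates to calibrate a threshold")
    freqs = np.asarray(genotype_freqs, dtype=float)
    if freqs.shape != (3 ** effect.n,):
        raise ValueError(f"genotype_freqs must have length {3 ** effect.n}")
    if (freqs < 0).any() or not np.isclose(freqs.sum(), 1.0, atol=1e-8):
        raise ValueError("genotype_freqs must be a probability vector")
    if alpha >= 1.0:
        return 0.0
    rng = np.random.default_rng(seed)
    case_mat = rng.multinomial(n_case, freqs, size=reps)
    ctl_mat = rng.multinomial(n_ctl, freqs, size=reps)
    stat = _stats_from_count_matrices(case_mat, ctl_mat,
                                      plus_minus_weights(effect))
    return float(np.quantile(stat, 1.0 - alpha))


def permutation_threshold(dataset, snp_subset, effect: EffectLabel,
                          reps: int = 1000, alpha: float = 0.05,
                          seed: int = 0) -> float:
    """Empirical critical value from case/control label permutations.

    Phenotype labels are shuffled among the complete-case samples at the
    subset, the genotype classes are re-tallied, and the ``1 - alpha``
    quantile of the permuted statistics is returned.
    """
    from .scan import _complete_case_classes  # local import to avoid cycle

    flat, pheno = _complete_case_classes(dataset, snp_subset)
    k = len(snp_subset)
    if pheno.sum() < 2 or (pheno == 0).sum() < 2:
        raise ValueError("need at least two cases and two controls to permute")
    if alpha >= 1.0:
        return 0.0
    rng = np.random.default_rng(seed)
    size = 3 ** k
    stats_out = np.empty(reps)
    onehot = np.zeros((flat.size, size), dtype=np.int64)
    onehot[np.arange(flat.size), flat] = 1
    w = plus_minus_weights(effect)
    for r in range(reps):
        perm = rng.permutation(pheno)
        case_counts = onehot[perm == 1].sum(axis=0)
        ctl_counts = onehot[perm == 0].sum(axis=0)
        stats_out[r] = _stats_from_count_matrices(
            case_counts[None, :], ctl_counts[None, :], w)[0]
    return float(np.quantile(stats_out, 1.0 - alpha))


def test_effect(counts: CaseControlCounts, effect: EffectLabel,
                thresholds: ThresholdTable | None = None) -> TestResult:
    """Run the plus/minus chi-square test for one effect.

    Two upper-tail p-values accompany the statistic: ``p_raw`` from the plain
    1-df chi-square (exact for additive-only effects, conservative
    otherwise), and ``p_calibrated`` from rescaling the statistic by
    3.84/threshold before the 1-df tail — a convenience mapping of the
    effect's calibrated critical value back onto the 5% point.  Significance
    is decided only by ``chi2 >= threshold`` (ties significant), never by a
    p-value.
    """
    table = build_table(counts, effect)
    chi2, degenerate = pearson_chi2(table)
    thr = threshold_for(effect, thresholds)
    significant = bool(not degenerate and chi2 >= thr)
    p_raw = float(stats.chi2.sf(chi2, df=1))
    p_cal = float(stats.chi2.sf(chi2 * _CHI2_1DF_95 / thr, df=1))
    return TestResult(effect=effect, chi2=chi2, threshold=thr,
                      significant=significant, p_raw=p_raw,
                      p_calibrated=p_cal, degenerate=degenerate, table=table)


def test_all(counts: CaseControlCounts,
             thresholds: ThresholdTable | None = None) -> list[TestResult]:
    """Test every non-mean effect (3**n - 1 of them) in flat-index order."""
    decomp = build_decomposition(counts.n)
    return [test_effect(counts, effect_label(i, counts.n), thresholds)
            for i in range(1, decomp.size)]
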