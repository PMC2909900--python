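"""Model/Results interface for multilocus epistasis testing.

:class:`MultilocusEpistasis` wraps a case-control genotype-class count
vector pair for a chosen set of loci; :meth:`~MultilocusEpistasis.fit` runs
every per-effect plus/minus chi-square test and returns an
:class:`EpistasisResults` carrying the statistics, thresholds, significance
flags and p-values, with a text ``summary()`` and the group-wise effect
decomposition used to interpret significant interactions.

Example
-------
>>> import numpy as np
>>> from epichi import MultilocusEpistasis
>>> rng = np.random.default_rng(0)
>>> case = rng.multinomial(200, np.full(9, 1 / 9))
>>> ctl = rng.multinomial(200, np.full(9, 1 / 9))
>>> res = MultilocusEpistasis(case, ctl, snp_ids=["s1", "s2"]).fit()
>>> res.frame.shape[0]   # 3**2 - 1 testable effects
8
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .effects import EffectLabel, _infer_n
from .io import GenotypeDataset
from .testing import (
    CaseControlCounts,
    TestResult,
    ThresholdTable,
    test_all,
    test_effect,
)
from .scan import GroupEffectDecomposition, count_genotypes, group_effect_table

__all__ = ["MultilocusEpistasis", "EpistasisResults"]


class MultilocusEpistasis:
    """Epistasis model for one set of loci in a case-control study.

    Parameters
    ----------
    case_counts, control_counts
        Genotype-class count vectors of length 3**n (flat base-3 genotype
        index, locus 1 most significant, class order AA/Aa/aa per locus).
    snp_ids
        Optional locus names for reports.
    thresholds
        Optional custom :class:`~epichi.testing.ThresholdTable`.
    """

    def __init__(self, case_counts, control_counts, snp_ids=None,
                 thresholds: ThresholdTable | None = None):
        case_counts = np.asarray(case_counts)
        n = _infer_n(case_counts.size)
        self.counts = CaseControlCounts(n=n, case_counts=case_counts,
                                        control_counts=control_counts)
        if snp_ids is not None and len(snp_ids) != n:
            raise ValueError(f"expected {n} SNP ids, got {len(snp_ids)}")
        self.snp_ids = list(snp_ids) if snp_ids is not None \
            else [f"locus{i + 1}" for i in range(n)]
        self.thresholds = thresholds

    @classmethod
    def from_counts(cls, counts: CaseControlCounts, snp_ids=None,
                    thresholds: ThresholdTable | None = None
                    ) -> "MultilocusEpistasis":
        return cls(counts.case_counts, counts.control_counts,
                   snp_ids=snp_ids, thresholds=thresholds)

    @classmethod
    def from_dataset(cls, dataset: GenotypeDataset, snp_subset=None,
                     thresholds: ThresholdTable | None = None
                     ) -> "MultilocusEpistasis":
        """Build from an individual-level dataset (complete-case counting)."""
        subset = list(snp_subset) if snp_subset is not None else dataset.snp_ids
        return cls.from_counts(count_genotypes(dataset, subset),
                               snp_ids=subset, thresholds=thresholds)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, snps=None,
                       phenotype_col: str = "phenotype",
                       thresholds: ThresholdTable | None = None
                       ) -> "MultilocusEpistasis":
        """Build from a samples-x-SNPs dosage DataFrame with a phenotype column."""
        if phenotype_col not in df.columns:
            raise ValueError(f"phenotype column {phenotype_col!r} not found")
        snp_cols = list(snps) if snps is not None \
            else [c for c in df.columns if c != phenotype_col]
        geno = df[snp_cols].to_numpy(dtype=float)
        geno = np.where(np.isnan(geno), -1, geno).astype(np.int8)
        ds = GenotypeDataset(
            sample_ids=[str(i) for i in df.index],
            snp_ids=snp_cols,
            phenotype=df[phenotype_col].to_numpy(dtype=np.int8),
            genotypes=geno,
        )
        return cls.from_dataset(ds, snp_cols, thresholds=thresholds)

    @property
    def n_loci(self) -> int:
        return self.counts.n

    def fit(self) -> "EpistasisResults":
        """Run all 3**n - 1 per-effect tests."""
        return EpistasisResults(self, test_all(self.counts, self.thresholds))

    def test(self, effect: str | EffectLabel) -> TestResult:
        """Run the test for a single effect (pattern string or label)."""
        label = effect if isinstance(effect, EffectLabel) \
            else EffectLabel.from_pattern(effect)
        return test_effect(self.counts, label, self.thresholds)


class EpistasisResults:
    """Fitted per-effect test results with reporting helpers."""

    def __init__(self, model: MultilocusEpistasis, results: list[TestResult]):
        self.model = model
        self.results = results
        self.frame = pd.DataFrame({
            "effect": [r.effect.name for r in results],
            "pattern": [r.effect.pattern for r in results],
            "order": [r.effect.order for r in results],
            "dominance": [r.effect.dominance_count for r in results],
            "chi2": [r.chi2 for r in results],
            "threshold": [r.threshold for r in results],
            "significant": [r.significant for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_calibrated": [r.p_calibrated for r in results],
            "degenerate": [r.degenerate for r in results],
        })

    @property
    def significant_effects(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]

    def group_effects(self) -> GroupEffectDecomposition:
        """Case/control count vectors expressed in effect coordinates."""
        return group_effect_table(self.model.counts)

    def summary(self) -> str:
        """Human-readable per-effect table, main effects first."""
        m = self.model
        lines = [
            "Multilocus epistasis test",
            f"  loci     : {', '.join(m.snp_ids)} (n={m.n_loci})",
            f"  samples  : {m.counts.n_cases} cases / "
            f"{m.counts.n_controls} controls",
            "",
            f"  {'effect':<18}{'chi2':>9}{'thr':>7}{'sig':>5}"
            f"{'p_raw':>10}{'p_cal':>10}",
        ]
        for r in sorted(self.results,
                        key=lambda r: (r.effect.order, r.effect.dominance_count)):
            mark = "*" if r.significant else ("." if r.degenerate else "")
            lines.append(
                f"  {r.effect.name:<18}{r.chi2:>9.3f}{r.threshold:>7.2f}"
                f"{mark:>5}{r.p_raw:>10.4f}{r.p_calibrated:>10.4f}")
        lines.append("")
        lines.append("  * significant at the effect-specific threshold; "
                     ". degenerate table")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        n_sig = int(self.frame["significant"].sum())
        return (f"<EpistasisResults n_loci={self.model.n_loci} "
                f"effects={len(self.results)} significant={n_sig}>")
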