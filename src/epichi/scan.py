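"""Exhaustive k-SNP epistasis scans over a case-control dataset.

For every subset of ``k`` SNPs the complete-case samples are tallied into
3**k genotype classes (dosage 2 -> class ``AA``), every non-mean effect is
tested, and one record per (subset, effect) is emitted.  Missing genotypes
are handled per subset, so each subset uses the maximal available data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import build_decomposition, effect_label, genotype_label
from .io import MISSING, GenotypeDataset
from .testing import CaseControlCounts, ThresholdTable, test_all

__all__ = [
    "count_genotypes",
    "scan",
    "group_effect_table",
    "GroupEffectDecomposition",
]


def _complete_case_classes(dataset: GenotypeDataset, snp_subset):
    """Flat genotype-class index and phenotype for complete-case samples."""
    if not snp_subset:
        raise ValueError("snp_subset must name at least one SNP")
    cols = [dataset.snp_index(s) for s in snp_subset]
    sub = dataset.genotypes[:, cols]
    complete = (sub != MISSING).all(axis=1)
    classes = 2 - sub[complete].astype(np.int64)  # dosage 2 -> class 0 (AA)
    k = len(cols)
    weights = 3 ** np.arange(k - 1, -1, -1)
    flat = classes @ weights
    return flat, dataset.phenotype[complete]


def count_genotypes(dataset: GenotypeDataset, snp_subset) -> CaseControlCounts:
    """Tally complete-case genotype-class counts for a SNP subset.

    Samples missing any genotype in the subset are excluded.  Zero cases or
    zero controls among the complete-case samples is allowed; the resulting
    counts carry the ``degenerate`` flag and downstream tests report
    chi2 = 0 rather than raising.
    """
    flat, pheno = _complete_case_classes(dataset, snp_subset)
    size = 3 ** len(snp_subset)
    case_counts = np.bincount(flat[pheno == 1], minlength=size)
    control_counts = np.bincount(flat[pheno == 0], minlength=size)
    return CaseControlCounts(n=len(snp_subset), case_counts=case_counts,
                             control_counts=control_counts)


def scan(dataset: GenotypeDataset, k: int,
         thresholds: ThresholdTable | None = None,
         corrections: tuple[str, ...] = ()) -> pd.DataFrame:
    """Test all 3**k - 1 effects for every k-subset of SNPs.

    Parameters
    ----------
    dataset
        Loaded case-control genotypes.
    k
        Subset size (1 <= k <= number of SNPs).
    thresholds
        Optional custom :class:`~epichi.testing.ThresholdTable`.
    corrections
        Optional multiple-testing annotations over ``p_raw`` across all
        records: any of ``"bonferroni"``, ``"bh"``.  They add columns only;
        the threshold-based ``significant`` flag is never altered.

    Returns
    -------
    pandas.DataFrame
        One row per (subset, effect): subset, effect, order, dominance,
        chi2, threshold, significant, p_raw, p_calibrated, degenerate,
        n_used.
    """
    if not 1 <= k <= dataset.n_snps:
        raise ValueError(f"k must be in [1, {dataset.n_snps}], got {k}")
    unknown = set(corrections) - {"bonferroni", "bh"}
    if unknown:
        raise ValueError(f"unknown corrections: {sorted(unknown)}")
    rows = []
    for subset in itertools.combinations(dataset.snp_ids, k):
        counts = count_genotypes(dataset, subset)
        n_used = counts.n_cases + counts.n_controls
        for res in test_all(counts, thresholds):
            rows.append({
                "subset": ",".join(subset),
                "effect": res.effect.name,
                "pattern": res.effect.pattern,
                "order": res.effect.order,
                "dominance": res.effect.dominance_count,
                "chi2": res.chi2,
                "threshold": res.threshold,
                "significant": res.significant,
                "p_raw": res.p_raw,
                "p_calibrated": res.p_calibrated,
                "degenerate": res.degenerate or counts.degenerate,
                "n_used": n_used,
            })
    df = pd.DataFrame(rows)
    m = len(df)
    if "bonferroni" in corrections:
        df["p_bonferroni"] = np.minimum(df["p_raw"] * m, 1.0)
    if "bh" in corrections:
        order = np.argsort(df["p_raw"].to_numpy())
        ranked = df["p_raw"].to_numpy()[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        bh = np.empty(m)
        bh[order] = np.minimum(ranked, 1.0)
        df["p_bh"] = bh
    return df


@dataclass(frozen=True)
class GroupEffectDecomposition:
    """Effect-scale view of case and control genotype-class counts.

    Applying the effect solver to the raw count vectors expresses each
    group's counts in effect coordinates; the case-minus-control difference
    per effect shows which components separate the groups, and any single
    genotype's count can be read back as a signed sum of the components that
    build it.
    """

    n: int
    case_effects: np.ndarray
    control_effects: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.case_effects - self.control_effects

    def frame(self) -> pd.DataFrame:
        labels = build_decomposition(self.n).effect_labels()
        return pd.DataFrame({
            "effect": [lab.name for lab in labels],
            "pattern": [lab.pattern for lab in labels],
            "cases": self.case_effects,
            "controls": self.control_effects,
            "difference": self.difference,
        })

    def genotype_components(self, genotype_flat_index: int) -> pd.DataFrame:
        """Signed per-effect contributions to one genotype's group counts.

        Row ``e`` holds sign * effect-value terms whose sum over effects
        reproduces the genotype's case (resp. control) count.
        """
        decomp = build_decomposition(self.n)
        row = decomp.design[genotype_flat_index]
        labels = decomp.effect_labels()
        active = row != 0
        return pd.DataFrame({
            "genotype": genotype_label(genotype_flat_index, self.n),
            "effect": [lab.name for lab, a in zip(labels, active) if a],
            "sign": row[active].astype(int),
            "cases": (row * self.case_effects)[active],
            "controls": (row * self.control_effects)[active],
            "difference": (row * self.difference)[active],
        })


def group_effect_table(counts: CaseControlCounts) -> GroupEffectDecomposition:
    """Decompose case and control count vectors into effect components."""
    solver = build_decomposition(counts.n).solver
    return GroupEffectDecomposition(
        n=counts.n,
        case_effects=solver @ counts.case_counts,
        control_effects=solver @ counts.control_counts,
    )
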