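"""Synthetic case-control genotype data with controllable epistasis and LD.

The population model is specified in two layers:

* **Genotype frequencies** — from per-locus allele frequencies plus pairwise
  and three-way linkage-disequilibrium coefficients (Bennett's haplotype
  decomposition, closed form up to three loci), expanded to multilocus
  genotype frequencies under random mating; or supplied directly.
* **Penetrance** — the probability of disease per multilocus genotype,
  built on the linear scale by composing a sparse effect specification
  (baseline mu plus chosen main/epistatic magnitudes).  Infeasible
  combinations (penetrance outside [0, 1]) are rejected, never clipped.

Case-control data are drawn retrospectively: case genotype-class
probabilities are proportional to frequency x penetrance, control
probabilities to frequency x (1 - penetrance).  On top of the sampler sit a
power / false-positive-rate study driver and an effect-size calibrator
(bisection to a target power band), both fully vectorised and reproducible
from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .effects import EffectLabel, compose, effect_index, genotype_label
from .io import GenotypeDataset, write_genotype_table
from .testing import (
    CaseControlCounts,
    ThresholdTable,
    _stats_from_count_matrices,
    plus_minus_weights,
    threshold_for,
)

__all__ = [
    "LDSpec",
    "PopulationModel",
    "EffectSpec",
    "PowerStudyResult",
    "InfeasibleModelError",
    "haplotype_freqs",
    "hwe_genotype_freqs",
    "genotype_freqs",
    "penetrance_from_effects",
    "build_population",
    "sample_case_control",
    "sample_individuals",
    "power_study",
    "calibrate_effect_size",
    "write_synthetic_dataset",
]


class InfeasibleModelError(ValueError):
    """A simulation configuration implies an impossible probability."""


@dataclass(frozen=True)
class LDSpec:
    """Allele frequencies plus linkage-disequilibrium coefficients.

    ``allele_freqs[l]`` is the population frequency of the capital allele at
    locus ``l``.  ``pairwise_D`` holds D for each locus pair in
    lexicographic order ((A,B), (A,C), (B,C) for three loci) and
    ``threeway_D`` is the three-locus coefficient; all default to zero
    (linkage equilibrium).  Closed-form haplotype frequencies are available
    for up to three loci.
    """

    allele_freqs: tuple[float, ...]
    pairwise_D: tuple[float, ...] = ()
    threeway_D: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.allele_freqs)
        if not 1 <= n <= 3:
            raise ValueError("closed-form LD path supports 1-3 loci")
        if any(not 0.0 < p < 1.0 for p in self.allele_freqs):
            raise ValueError("allele frequencies must be in (0, 1)")
        n_pairs = n * (n - 1) // 2
        pw = tuple(self.pairwise_D) or (0.0,) * n_pairs
        if len(pw) != n_pairs:
            raise ValueError(f"need {n_pairs} pairwise D values for {n} loci")
        object.__setattr__(self, "pairwise_D", pw)
        if n < 3 and self.threeway_D != 0.0:
            raise ValueError("threeway_D requires three loci")

    @property
    def n(self) -> int:
        return len(self.allele_freqs)


@dataclass(frozen=True)
class PopulationModel:
    """Genotype-class frequencies plus per-genotype penetrance."""

    genotype_freqs: np.ndarray
    penetrance: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.genotype_freqs, dtype=float)
        pen = np.asarray(self.penetrance, dtype=float)
        if f.shape != pen.shape or f.ndim != 1:
            raise ValueError("frequencies and penetrance must be equal-length vectors")
        if (f < -1e-12).any() or not np.isclose(f.sum(), 1.0, atol=1e-8):
            raise ValueError("genotype frequencies must be a probability vector")
        if (pen < 0).any() or (pen > 1).any():
            raise InfeasibleModelError("penetrances must lie in [0, 1]")
        object.__setattr__(self, "genotype_freqs", f)
        object.__setattr__(self, "penetrance", pen)

    @property
    def n(self) -> int:
        size = self.genotype_freqs.size
        n = round(np.log(size) / np.log(3))
        return n

    @property
    def prevalence(self) -> float:
        return float(self.genotype_freqs @ self.penetrance)

    def case_control_distributions(self) -> tuple[np.ndarray, np.ndarray]:
        """Retrospective genotype-class distributions for cases and controls."""
        case_w = self.genotype_freqs * self.penetrance
        ctl_w = self.genotype_freqs * (1.0 - self.penetrance)
        if case_w.sum() <= 0 or ctl_w.sum() <= 0:
            raise InfeasibleModelError(
                "penetrance is degenerate: one arm has probability zero")
        return case_w / case_w.sum(), ctl_w / ctl_w.sum()


@dataclass(frozen=True)
class EffectSpec:
    """Sparse effect specification on the linear penetrance scale."""

    n: int
    baseline: float
    effects: dict[EffectLabel, float] = field(default_factory=dict)

    def effect_vector(self) -> np.ndarray:
        e = np.zeros(3 ** self.n)
        e[0] = self.baseline
        for label, mag in self.effects.items():
            if label.n != self.n:
                raise ValueError(f"effect {label} spans {label.n} loci, spec has {self.n}")
            e[effect_index(label)] = mag
        return e


def haplotype_freqs(ld: LDSpec) -> np.ndarray:
    """All 2**n haplotype frequencies from Bennett's decomposition.

    Haplotypes are indexed with locus 1 most significant and bit 0 meaning
    the capital allele (so index 0 is the all-capital haplotype).  With sign
    ``s_l = +1`` for the capital allele and ``-1`` otherwise, the frequency
    of a three-locus haplotype is::

        f = p1 p2 p3 + s1 s2 D_AB p3 + s1 s3 D_AC p2 + s2 s3 D_BC p1
            + s1 s2 s3 D_ABC

    where each ``p_l`` is the frequency of the allele actually carried at
    locus ``l``.  Any implied frequency outside [0, 1] raises
    :class:`InfeasibleModelError` naming the offending haplotype.
    """
    n = ld.n
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    freqs = np.empty(2 ** n)
    for idx, alleles in enumerate(product((0, 1), repeat=n)):
        # allele 0 = capital
        s = np.array([1.0 if a == 0 else -1.0 for a in alleles])
        p = np.array([ld.allele_freqs[l] if a == 0 else 1.0 - ld.allele_freqs[l]
                      for l, a in enumerate(alleles)])
        f = p.prod()
        for (i, j), D in zip(pairs, ld.pairwise_D):
            others = [l for l in range(n) if l not in (i, j)]
            f += s[i] * s[j] * D * np.prod(p[others]) if others else s[i] * s[j] * D
        if n == 3:
            f += s.prod() * ld.threeway_D
        if f < -1e-12 or f > 1.0 + 1e-12:
            name = "".join("ABC"[l] if a == 0 else "abc"[l]
                           for l, a in enumerate(alleles))
            raise InfeasibleModelError(
                f"LD specification implies haplotype {name} frequency {f:.4f}")
        freqs[idx] = min(max(f, 0.0), 1.0)
    assert np.isclose(freqs.sum(), 1.0, atol=1e-9)
    return freqs


def hwe_genotype_freqs(n: int, maf: float = 0.5) -> np.ndarray:
    """Joint genotype frequencies for n independent HWE loci.

    ``maf`` is the capital-allele frequency at every locus; per-locus class
    frequencies are (p**2, 2pq, q**2) in AA/Aa/aa order.
    """
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must be in (0, 1)")
    p, q = maf, 1.0 - maf
    locus = np.array([p * p, 2 * p * q, q * q])
    out = np.array([1.0])
    for _ in range(n):
        out = np.kron(out, locus)
    return out


def genotype_freqs(haplotypes: np.ndarray) -> np.ndarray:
    """Random-mating expansion of haplotype frequencies to genotype classes.

    A genotype's frequency is the sum of ``f(h1) f(h2)`` over ordered
    haplotype pairs whose per-locus capital-allele dosages give that class
    (Hardy-Weinberg at the haplotype level).  Accepts any 2**n vector, not
    just the closed-form three-locus path.
    """
    h = np.asarray(haplotypes, dtype=float)
    n = round(np.log2(h.size))
    if 2 ** n != h.size:
        raise ValueError("haplotype vector length must be a power of 2")
    if (h < 0).any() or not np.isclose(h.sum(), 1.0, atol=1e-8):
        raise ValueError("haplotype frequencies must be a probability vector")
    geno = np.zeros(3 ** n)
    weights = 3 ** np.arange(n - 1, -1, -1)
    bit = [(np.arange(2 ** n) >> (n - 1 - l)) & 1 for l in range(n)]
    for h1 in range(2 ** n):
        for h2 in range(2 ** n):
            # allele bit 0 = capital; class = number of non-capital alleles
            classes = np.array([bit[l][h1] + bit[l][h2] for l in range(n)])
            geno[classes @ weights] += h[h1] * h[h2]
    return geno


def penetrance_from_effects(spec: EffectSpec) -> np.ndarray:
    """Compose a sparse effect spec into a penetrance vector.

    Raises :class:`InfeasibleModelError` when any composed penetrance falls
    outside [0, 1] — magnitudes are never silently clipped.
    """
    pen = compose(spec.effect_vector(), spec.n)
    if (pen < -1e-12).any() or (pen > 1.0 + 1e-12).any():
        bad = int(np.argmax((pen < 0) | (pen > 1)))
        raise InfeasibleModelError(
            f"effects compose to penetrance {pen[bad]:.4f} at genotype "
            f"{genotype_label(bad, spec.n)}")
    return np.clip(pen, 0.0, 1.0)


def build_population(spec: EffectSpec, ld: LDSpec | None = None,
                     freqs: np.ndarray | None = None) -> PopulationModel:
    """Assemble a :class:`PopulationModel` from effects and LD (or frequencies)."""
    if freqs is None:
        if ld is None:
            ld = LDSpec(allele_freqs=(0.5,) * spec.n)
        if ld.n != spec.n:
            raise ValueError("LD spec and effect spec disagree on locus count")
        freqs = genotype_freqs(haplotype_freqs(ld))
    return PopulationModel(genotype_freqs=freqs,
                           penetrance=penetrance_from_effects(spec))


def sample_case_control(model: PopulationModel, n_case: int, n_ctl: int,
                        seed: int | np.random.Generator = 0) -> CaseControlCounts:
    """Draw genotype-class counts for one retrospective case-control sample."""
    case_p, ctl_p = model.case_control_distributions()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return CaseControlCounts(
        n=model.n,
        case_counts=rng.multinomial(n_case, case_p),
        control_counts=rng.multinomial(n_ctl, ctl_p),
    )


def sample_individuals(model: PopulationModel, n_case: int, n_ctl: int,
                       seed: int | np.random.Generator = 0,
                       snp_ids=None) -> GenotypeDataset:
    """Draw an individual-level dataset (dosage matrix) from the model."""
    case_p, ctl_p = model.case_control_distributions()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = model.n
    flat = np.concatenate([
        rng.choice(3 ** n, size=n_case, p=case_p),
        rng.choice(3 ** n, size=n_ctl, p=ctl_p),
    ])
    phenotype = np.concatenate([np.ones(n_case, dtype=np.int8),
                                np.zeros(n_ctl, dtype=np.int8)])
    # flat class -> per-locus dosage (class 0 = AA = dosage 2)
    geno = np.empty((flat.size, n), dtype=np.int8)
    x = flat.copy()
    for l in range(n - 1, -1, -1):
        geno[:, l] = 2 - (x % 3)
        x //= 3
    if snp_ids is None:
        snp_ids = [f"snp{l + 1}" for l in range(n)]
    sample_ids = [f"case{i + 1}" for i in range(n_case)] + \
                 [f"ctl{i + 1}" for i in range(n_ctl)]
    return GenotypeDataset(sample_ids=sample_ids, snp_ids=list(snp_ids),
                           phenotype=phenotype, genotypes=geno)


def write_synthetic_dataset(model: PopulationModel, n_case: int, n_ctl: int,
                            seed: int, path, snp_ids=None) -> GenotypeDataset:
    """Sample an individual-level dataset and write it as a genotype table."""
    ds = sample_individuals(model, n_case, n_ctl, seed=seed, snp_ids=snp_ids)
    write_genotype_table(ds, path)
    return ds


# ---------------------------------------------------------------------------
# power / false-positive-rate studies

#: The four representative three-way forms, by dominance count.
REPRESENTATIVE_FORMS: tuple[str, ...] = ("aaa", "aad", "add", "ddd")

#: Default "associated SNPs" scenario: modest pairwise and three-way LD,
#: feasible at MAF 0.5.
DEFAULT_ASSOCIATED_LD = dict(pairwise_D=(0.05, 0.05, 0.05), threeway_D=0.01)


def _rejection_rate(model: PopulationModel, effect: EffectLabel,
                    n_case: int, n_ctl: int, reps: int,
                    rng: np.random.Generator,
                    thresholds: ThresholdTable | None = None) -> float:
    """Fraction of replicate samples whose statistic meets the threshold."""
    case_p, ctl_p = model.case_control_distributions()
    case_mat = rng.multinomial(n_case, case_p, size=reps)
    ctl_mat = rng.multinomial(n_ctl, ctl_p, size=reps)
    stat = _stats_from_count_matrices(case_mat, ctl_mat,
                                      plus_minus_weights(effect))
    return float((stat >= threshold_for(effect, thresholds)).mean())


@dataclass(frozen=True)
class PowerStudyResult:
    """Power and FPR per effect form, scenario and sample size."""

    table: pd.DataFrame
    reps: int
    seed: int
    sample_sizes: tuple[int, ...]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def power_study(forms=REPRESENTATIVE_FORMS,
                magnitudes: dict[str, float] | float = 0.15,
                sample_sizes=(200, 400, 1000),
                baseline: float = 0.3,
                maf: float = 0.5,
                scenarios=("independent", "associated"),
                associated_ld: dict | None = None,
                reps: int = 1000,
                seed: int = 0,
                thresholds: ThresholdTable | None = None) -> PowerStudyResult:
    """Estimate power and FPR for three-locus epistasis forms.

    For each scenario all configured forms are planted jointly (on the
    linear penetrance scale, baseline ``baseline``); a form's **power** is
    its test's rejection rate over ``reps`` replicates of that population,
    and its **FPR** is its rejection rate over companion replicates in which
    that one form's magnitude is set to zero with everything else equal.

    Per-(scenario, size, form) replicate streams are spawned from the master
    seed by counter, so any cell is reproducible in isolation.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    forms = tuple(forms)
    if isinstance(magnitudes, (int, float)):
        magnitudes = {f: float(magnitudes) for f in forms}
    n = len(forms[0].replace("*", ""))
    labels = {f: EffectLabel.from_pattern(f) for f in forms}

    def make_ld(scenario: str) -> LDSpec:
        if scenario == "independent":
            return LDSpec(allele_freqs=(maf,) * n)
        params = associated_ld if associated_ld is not None else DEFAULT_ASSOCIATED_LD
        return LDSpec(allele_freqs=(maf,) * n, **params)

    rows = []
    stream = 0
    for scenario in scenarios:
        freqs = genotype_freqs(haplotype_freqs(make_ld(scenario)))
        for size in sample_sizes:
            for form in forms:
                alt_spec = EffectSpec(n=n, baseline=baseline,
                                      effects={labels[f]: magnitudes[f]
                                               for f in forms})
                null_effects = {labels[f]: magnitudes[f]
                                for f in forms if f != form}
                null_spec = EffectSpec(n=n, baseline=baseline,
                                       effects=null_effects)
                alt_model = build_population(alt_spec, freqs=freqs)
                null_model = build_population(null_spec, freqs=freqs)
                rng_alt = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))
                rng_null = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(stream + 1,)))
                stream += 2
                power = _rejection_rate(alt_model, labels[form], size, size,
                                        reps, rng_alt, thresholds)
                fpr = _rejection_rate(null_model, labels[form], size, size,
                                      reps, rng_null, thresholds)
                rows.append({"scenario": scenario, "n_per_arm": size,
                             "form": form, "magnitude": magnitudes[form],
                             "power": 100.0 * power, "fpr": 100.0 * fpr})
    return PowerStudyResult(table=pd.DataFrame(rows), reps=reps, seed=seed,
                            sample_sizes=tuple(sample_sizes))


def calibrate_effect_size(form: str | EffectLabel,
                          n_per_arm: int,
                          target_power_range: tuple[float, float],
                          reps: int = 1000,
                          seed: int = 0,
                          baseline: float = 0.3,
                          maf: float = 0.5,
                          max_iter: int = 40,
                          thresholds: ThresholdTable | None = None
                          ) -> tuple[float, float]:
    """Bisect the penetrance-scale magnitude of one form to a power band.

    Returns ``(magnitude, achieved_power)`` with the empirical power at
    ``n_per_arm`` cases and controls inside ``target_power_range``.  Common
    random numbers (the same replicate stream at every magnitude) make the
    power curve monotone in the magnitude, so plain bisection converges.

    Raises :class:`InfeasibleModelError` when the target band is not
    reachable within the feasible penetrance range.
    """
    label = form if isinstance(form, EffectLabel) else EffectLabel.from_pattern(form)
    lo_t, hi_t = target_power_range
    if not 0.0 < lo_t < hi_t < 1.0:
        raise ValueError("target power range must satisfy 0 < lo < hi < 1")
    n = label.n
    freqs = genotype_freqs(haplotype_freqs(LDSpec(allele_freqs=(maf,) * n)))
    feasible_max = min(baseline, 1.0 - baseline) * 0.999

    def power_at(mag: float) -> float:
        spec = EffectSpec(n=n, baseline=baseline, effects={label: mag})
        model = build_population(spec, freqs=freqs)
        rng = np.random.default_rng(seed)
        return _rejection_rate(model, label, n_per_arm, n_per_arm, reps, rng,
                               thresholds)

    if power_at(feasible_max) < lo_t:
        raise InfeasibleModelError(
            f"target power {lo_t:.2f} unreachable: power at the feasibility "
            f"bound ({feasible_max:.3f}) is {power_at(feasible_max):.3f}")
    lo, hi = 0.0, feasible_max
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = power_at(mid)
        if lo_t <= p <= hi_t:
            return mid, p
        if p < lo_t:
            lo = mid
        else:
            hi = mid
    raise InfeasibleModelError(
        "bisection did not land in the target power band; widen the band or "
        "increase reps")
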