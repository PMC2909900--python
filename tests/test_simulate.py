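"""Population model, retrospective sampler, and power-study machinery."""

import numpy as np
import pytest

from epichi import (
    EffectLabel,
    EffectSpec,
    InfeasibleModelError,
    LDSpec,
    build_population,
    calibrate_effect_size,
    count_genotypes,
    decompose,
    effect_index,
    genotype_freqs,
    genotype_index,
    haplotype_freqs,
    hwe_genotype_freqs,
    penetrance_from_effects,
    power_study,
    read_genotype_table,
    sample_case_control,
    threshold_for,
    write_synthetic_dataset,
)
from epichi.simulate import PopulationModel, _rejection_rate
from epichi.testing import _stats_from_count_matrices, plus_minus_weights
from epichi.effects import effect_label


class TestHaplotypes:
    def test_independence_gives_uniform_haplotypes(self):
        h = haplotype_freqs(LDSpec(allele_freqs=(0.5, 0.5, 0.5)))
        np.testing.assert_allclose(h, np.full(8, 1 / 8))

    def test_perfect_coupling(self):
        h = haplotype_freqs(LDSpec(allele_freqs=(0.5, 0.5), pairwise_D=(0.25,)))
        np.testing.assert_allclose(h, [0.5, 0.0, 0.0, 0.5])

    def test_infeasible_ld_names_haplotype(self):
        with pytest.raises(InfeasibleModelError, match="haplotype"):
            haplotype_freqs(LDSpec(allele_freqs=(0.5, 0.5), pairwise_D=(0.3,)))

    def test_three_way_coefficient_shifts_frequencies(self):
        ld = LDSpec(allele_freqs=(0.5, 0.5, 0.5),
                    pairwise_D=(0.05, 0.05, 0.05), threeway_D=0.01)
        h = haplotype_freqs(ld)
        assert np.isclose(h.sum(), 1.0)
        # ABC haplotype: 1/8 + 3 * 0.05/2 + 0.01
        assert h[0] == pytest.approx(0.125 + 3 * 0.025 + 0.01)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            LDSpec(allele_freqs=(0.5, 0.5), pairwise_D=(0.1, 0.1))
        with pytest.raises(ValueError):
            LDSpec(allele_freqs=(0.0, 0.5))
        with pytest.raises(ValueError):
            LDSpec(allele_freqs=(0.5, 0.5), threeway_D=0.01)


class TestGenotypeFreqs:
    def test_independent_loci_factorise(self):
        g = genotype_freqs(haplotype_freqs(LDSpec(allele_freqs=(0.5, 0.5))))
        locus = np.array([0.25, 0.5, 0.25])
        np.testing.assert_allclose(g, np.kron(locus, locus))
        np.testing.assert_allclose(g, hwe_genotype_freqs(2, 0.5))

    def test_fixed_haplotype_gives_single_genotype(self):
        g = genotype_freqs(np.array([1.0, 0.0, 0.0, 0.0]))
        expected = np.zeros(9)
        expected[genotype_index("AABB")] = 1.0
        np.testing.assert_allclose(g, expected)

    def test_coupling_enumeration(self):
        g = genotype_freqs(np.array([0.5, 0.0, 0.0, 0.5]))
        expected = np.zeros(9)
        expected[genotype_index("AABB")] = 0.25
        expected[genotype_index("AaBb")] = 0.5
        expected[genotype_index("aabb")] = 0.25
        np.testing.assert_allclose(g, expected)


class TestPenetrance:
    def test_baseline_only_is_constant(self):
        pen = penetrance_from_effects(EffectSpec(n=2, baseline=0.1))
        np.testing.assert_allclose(pen, 0.1)

    def test_ddd_pattern(self):
        spec = EffectSpec(n=3, baseline=0.5,
                          effects={EffectLabel.from_pattern("ddd"): 0.4})
        pen = penetrance_from_effects(spec)
        assert pen[genotype_index("AaBbCc")] == pytest.approx(0.9)
        # d-columns vanish at homozygous loci: most classes sit at baseline
        assert pen[genotype_index("AABBCC")] == pytest.approx(0.5)

    def test_infeasible_effects_rejected_not_clipped(self):
        spec = EffectSpec(n=1, baseline=0.1,
                          effects={EffectLabel.from_pattern("a"): 0.2})
        with pytest.raises(InfeasibleModelError, match="penetrance"):
            penetrance_from_effects(spec)


class TestSampler:
    def test_null_case_distribution_equals_frequencies(self):
        freqs = hwe_genotype_freqs(2, 0.5)
        model = build_population(EffectSpec(n=2, baseline=0.2), freqs=freqs)
        case_p, ctl_p = model.case_control_distributions()
        np.testing.assert_allclose(case_p, freqs)
        np.testing.assert_allclose(ctl_p, freqs)

    def test_full_penetrance_class_collects_all_cases(self):
        pen = np.zeros(3)
        pen[0] = 1.0
        model = PopulationModel(genotype_freqs=np.array([0.25, 0.5, 0.25]),
                                penetrance=pen)
        counts = sample_case_control(model, 50, 50, seed=0)
        assert counts.case_counts[0] == 50
        assert counts.control_counts[0] == 0

    def test_degenerate_penetrance_rejected(self):
        model = PopulationModel(genotype_freqs=np.array([0.25, 0.5, 0.25]),
                                penetrance=np.ones(3))
        with pytest.raises(InfeasibleModelError):
            sample_case_control(model, 10, 10, seed=0)

    def test_expected_counts_within_three_se(self):
        freqs = hwe_genotype_freqs(1, 0.5)
        label = EffectLabel.from_pattern("a")
        model = build_population(
            EffectSpec(n=1, baseline=0.3, effects={label: 0.1}), freqs=freqs)
        case_p, _ = model.case_control_distributions()
        n = 20000
        counts = sample_case_control(model, n, n, seed=1)
        for j in range(3):
            se = np.sqrt(n * case_p[j] * (1 - case_p[j]))
            assert abs(counts.case_counts[j] - n * case_p[j]) < 3 * se

    def test_seeded_reproducibility(self):
        model = build_population(EffectSpec(n=2, baseline=0.3),
                                 freqs=hwe_genotype_freqs(2, 0.5))
        a = sample_case_control(model, 100, 100, seed=9)
        b = sample_case_control(model, 100, 100, seed=9)
        np.testing.assert_array_equal(a.case_counts, b.case_counts)
        np.testing.assert_array_equal(a.control_counts, b.control_counts)


class TestNullCalibration:
    def test_null_rejection_near_nominal(self):
        """Additive-only effects reject ~5% of null replicates; effects with
        dominance components stay below 8% at their printed thresholds."""
        freqs = hwe_genotype_freqs(3, 0.5)
        reps = 2000
        rng = np.random.default_rng(123)
        case_mat = rng.multinomial(500, freqs, size=reps)
        ctl_mat = rng.multinomial(500, freqs, size=reps)
        se3 = 3 * np.sqrt(0.05 * 0.95 / reps)
        for i in range(1, 27):
            lab = effect_label(i, 3)
            stat = _stats_from_count_matrices(case_mat, ctl_mat,
                                              plus_minus_weights(lab))
            rate = (stat >= threshold_for(lab)).mean()
            if lab.dominance_count == 0:
                assert abs(rate - 0.05) < se3, f"{lab.pattern}: {rate:.3f}"
            else:
                assert rate <= 0.08, f"{lab.pattern}: {rate:.3f}"

    def test_ld_does_not_shift_null_rejection(self):
        """Associated vs independent SNPs with the same margins give null
        rejection rates within 3 Monte-Carlo SEs of each other."""
        label = EffectLabel.from_pattern("aaa")
        reps = 2000
        rates = []
        for ld in (LDSpec(allele_freqs=(0.5,) * 3),
                   LDSpec(allele_freqs=(0.5,) * 3,
                          pairwise_D=(0.05,) * 3, threeway_D=0.01)):
            freqs = genotype_freqs(haplotype_freqs(ld))
            model = PopulationModel(genotype_freqs=freqs,
                                    penetrance=np.full(27, 0.3))
            rates.append(_rejection_rate(model, label, 500, 500, reps,
                                         np.random.default_rng(7)))
        se = np.sqrt(2 * 0.05 * 0.95 / reps)
        assert abs(rates[0] - rates[1]) < 3 * se


class TestPowerStudy:
    def test_shape_and_determinism(self):
        res = power_study(magnitudes=0.15, sample_sizes=(200,), reps=200,
                          seed=4)
        assert len(res.table) == 2 * 1 * 4  # scenarios x sizes x forms
        res2 = power_study(magnitudes=0.15, sample_sizes=(200,), reps=200,
                           seed=4)
        assert res.table.equals(res2.table)

    def test_zero_magnitude_power_matches_null_level(self):
        res = power_study(forms=("aaa",), magnitudes=0.0, sample_sizes=(500,),
                          scenarios=("independent",), reps=2000, seed=8)
        assert res.table["power"].iloc[0] / 100 < 0.08

    def test_power_monotone_in_sample_size(self):
        res = power_study(forms=("aaa",), magnitudes=0.12,
                          sample_sizes=(200, 400, 1000),
                          scenarios=("independent",), reps=1000, seed=10)
        p = res.table.sort_values("n_per_arm")["power"].to_numpy() / 100
        tol = 2 * np.sqrt(0.25 / 1000)
        assert p[1] >= p[0] - tol
        assert p[2] >= p[1] - tol

    def test_fpr_near_nominal(self):
        res = power_study(forms=("aaa",), magnitudes=0.12, sample_sizes=(400,),
                          scenarios=("independent",), reps=2000, seed=12)
        assert res.table["fpr"].iloc[0] / 100 < 0.08

    def test_reps_floor(self):
        with pytest.raises(ValueError):
            power_study(reps=50)


class TestCalibrateEffectSize:
    def test_lands_in_band_and_is_deterministic(self):
        mag, power = calibrate_effect_size("aaa", 200, (0.51, 0.61),
                                           reps=1000, seed=1)
        assert 0.51 <= power <= 0.61
        assert 0.0 < mag < 0.3
        mag2, power2 = calibrate_effect_size("aaa", 200, (0.51, 0.61),
                                             reps=1000, seed=1)
        assert (mag, power) == (mag2, power2)

    def test_unreachable_target(self):
        with pytest.raises(InfeasibleModelError, match="unreachable"):
            calibrate_effect_size("aaa", 20, (0.999, 0.9995), reps=1000, seed=2)

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            calibrate_effect_size("aaa", 200, (0.6, 0.5))


class TestParameterRecovery:
    def test_case_distribution_decomposes_to_planted_effect(self):
        """Among interaction terms, the decomposition of the expected case
        distribution — divided by the genotype frequencies to return to the
        penetrance scale — peaks at the planted effect's label."""
        label = EffectLabel.from_pattern("aad")
        freqs = hwe_genotype_freqs(3, 0.5)
        model = build_population(
            EffectSpec(n=3, baseline=0.3, effects={label: 0.08}), freqs=freqs)
        case_p, _ = model.case_control_distributions()
        e = decompose(case_p / freqs)
        interactions = {i: abs(e[i]) for i in range(1, 27)
                        if effect_label(i, 3).order >= 2}
        assert max(interactions, key=interactions.get) == effect_index(label)


class TestSyntheticFiles:
    def test_round_trip_counts(self, tmp_path):
        model = build_population(
            EffectSpec(n=3, baseline=0.3,
                       effects={EffectLabel.from_pattern("aaa"): 0.2}),
            freqs=hwe_genotype_freqs(3, 0.5))
        path = tmp_path / "synth.tsv"
        ds = write_synthetic_dataset(model, 80, 120, seed=3, path=path)
        loaded = read_genotype_table(path)
        assert loaded.snp_ids == ["snp1", "snp2", "snp3"]
        direct = count_genotypes(ds, ds.snp_ids)
        reread = count_genotypes(loaded, loaded.snp_ids)
        np.testing.assert_array_equal(direct.case_counts, reread.case_counts)
        np.testing.assert_array_equal(direct.control_counts,
                                      reread.control_counts)
        assert reread.n_cases == 80 and reread.n_controls == 120

    def test_seeded_reproducibility(self, tmp_path):
        model = build_population(EffectSpec(n=2, baseline=0.3),
                                 freqs=hwe_genotype_freqs(2, 0.5))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_synthetic_dataset(model, 30, 30, seed=5, path=p1)
        write_synthetic_dataset(model, 30, 30, seed=5, path=p2)
        assert p1.read_text() == p2.read_text()
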