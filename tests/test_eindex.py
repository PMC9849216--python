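"""Ending-preference model and E-index scoring."""

import numpy as np
import pytest

import fragaxis as fx


def _brute_force_e_index(sample, controls):
    """Independent per-read oracle: plain dict counting, no sparse model."""
    u_counts: dict[tuple[str, int], int] = {}
    d_counts: dict[tuple[str, int], int] = {}
    for fs in controls:
        for rec in fs:
            key_u = (rec.chrom, rec.u_end)
            key_d = (rec.chrom, rec.d_end)
            u_counts[key_u] = u_counts.get(key_u, 0) + 1
            d_counts[key_d] = d_counts.get(key_d, 0) + 1
    total = 0
    for rec in sample:
        total += u_counts.get((rec.chrom, rec.u_end), 0)
        total += d_counts.get((rec.chrom, rec.d_end), 0)
    return total / len(sample)


def _random_sets(rng, n_sets, n_frags, span=2_000):
    sets = []
    for k in range(n_sets):
        starts = rng.integers(0, span, n_frags)
        sizes = rng.integers(50, 300, n_frags)
        sets.append(
            fx.FragmentSet(f"r{k}", "chrS", starts, starts + sizes)
        )
    return sets


class TestModelBuild:
    def test_single_fragment_counts(self):
        fs = fx.FragmentSet("c", "chrS", [10], [20])
        model = fx.build_end_model([fs])
        assert model.lookup_u("chrS", np.array([10])) == [1]
        assert model.lookup_d("chrS", np.array([19])) == [1]
        assert model.lookup_u("chrS", np.array([19])) == [0]

    def test_duplicated_pool_doubles_counts(self, control_samples):
        fs = control_samples[0].subset(np.arange(2_000))
        single = fx.build_end_model([fs])
        double = fx.build_end_model([fs, fs])
        pos = single.u_positions["chrS"]
        np.testing.assert_array_equal(
            2 * single.lookup_u("chrS", pos), double.lookup_u("chrS", pos)
        )

    def test_count_conservation(self, control_samples):
        model = fx.build_end_model(control_samples)
        n = sum(len(fs) for fs in control_samples)
        assert model.total_u() == n
        assert model.total_d() == n
        assert model.total_fragments == n

    def test_empty_pool_rejected(self):
        empty = fx.FragmentSet("e", "chrS", np.empty(0, int), np.empty(0, int))
        with pytest.raises(ValueError):
            fx.build_end_model([empty])


class TestEIndex:
    def test_direct_formula(self):
        controls = [
            fx.FragmentSet("c", "chrS", [10] * 5 + [5] * 3, [50] * 5 + [20] * 3)
        ]
        # model: U@10 x5, U@5 x3, D@49 x5, D@19 x3
        model = fx.build_end_model(controls)
        sample = fx.FragmentSet("s", "chrS", [10], [20])
        res = fx.e_index(sample, model)
        assert res.e_index == 8.0  # M_U=5 at 10, M_D=3 at 19
        assert res.n_fragments == 1

    def test_all_ends_miss_the_model(self):
        model = fx.build_end_model([fx.FragmentSet("c", "chrS", [10], [20])])
        sample = fx.FragmentSet("s", "chrS", [500], [700])
        res = fx.e_index(sample, model)
        assert res.e_index == 0.0
        assert res.missing_ends == 2

    def test_empty_sample_rejected(self):
        model = fx.build_end_model([fx.FragmentSet("c", "chrS", [10], [20])])
        empty = fx.FragmentSet("s", "chrS", np.empty(0, int), np.empty(0, int))
        with pytest.raises(ValueError):
            fx.e_index(empty, model)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        controls = _random_sets(rng, 3, 400)
        sample = _random_sets(rng, 1, 300)[0]
        model = fx.build_end_model(controls)
        assert fx.e_index(sample, model).e_index == pytest.approx(
            _brute_force_e_index(sample, controls), rel=0, abs=0
        )

    def test_doubling_pool_doubles_score(self, control_samples):
        fs = control_samples[0].subset(np.arange(3_000))
        sample = control_samples[1].subset(np.arange(2_000))
        e1 = fx.e_index(sample, fx.build_end_model([fs])).e_index
        e2 = fx.e_index(sample, fx.build_end_model([fs, fs])).e_index
        assert e2 == pytest.approx(2 * e1)

    def test_off_lattice_shift_lowers_score(self, control_samples):
        """A +3 bp shift moves ends off the preferred-site lattice."""
        model = fx.build_end_model(control_samples[:2])
        sample = control_samples[2]
        base = fx.e_index(sample, model).e_index
        shifted = fx.FragmentSet(
            "shifted", sample.chroms, sample.starts + 3, sample.ends + 3
        )
        assert fx.e_index(shifted, model).e_index < base

    def test_serialisation_round_trip(self, tmp_path, control_samples):
        model = fx.build_end_model([control_samples[0].subset(np.arange(2_000))])
        path = tmp_path / "model.tsv.gz"
        model.to_tsv(path)
        back = fx.EndingPreferenceModel.from_tsv(path)
        sample = control_samples[1].subset(np.arange(1_000))
        assert fx.e_index(sample, back).e_index == fx.e_index(sample, model).e_index
        assert back.total_fragments == model.total_fragments

    def test_control_scores_above_cancer(self, control_samples, track, landscape):
        model = fx.build_end_model(control_samples[:2])
        held_out = control_samples[2]
        cancer = fx.sample_fragments(
            track,
            landscape,
            spec=fx.SampleSpec(
                sample_id="ca", label="cancer", n_fragments=30_000,
                tumor_fraction=0.2, seed=91,
            ),
        )
        assert fx.e_index(held_out, model).e_index > fx.e_index(cancer, model).e_index


class TestEvaluateScores:
    def test_perfect_separation(self):
        out = fx.evaluate_scores(
            [10, 11, 12, 1, 2, 3],
            ["control"] * 3 + ["cancer"] * 3,
        )
        assert out["auc"] == 1.0
        assert out["z_p"] < 0.05

    def test_identical_groups_are_chance_level(self):
        out = fx.evaluate_scores(
            [5, 6, 7, 5, 6, 7], ["control"] * 3 + ["cancer"] * 3
        )
        assert out["auc"] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fx.evaluate_scores([1, 2], ["control", "control"])


class TestTumorLoad:
    def test_anti_monotone_scores(self):
        r, p = fx.tumor_load_correlation(
            [10, 8, 6, 4, 2], [0.0, 0.1, 0.2, 0.3, 0.4]
        )
        assert r < -0.99
        assert p < 0.01

    def test_constant_scores_undefined(self):
        with pytest.warns(UserWarning):
            r, _ = fx.tumor_load_correlation([5, 5, 5], [0.0, 0.2, 0.4])
        assert np.isnan(r)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fx.tumor_load_correlation([1, 2], [0.0, 0.1])

    def test_mixture_gradient_strongly_negative(
        self, control_pool, tumor_pure, control_samples
    ):
        model = fx.build_end_model(control_samples[:2])
        fractions = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        scores = []
        for i, f in enumerate(fractions):
            mix = fx.mix_samples(control_pool, tumor_pure, f, 20_000, seed=50 + i)
            scores.append(fx.e_index(mix, model).e_index)
        r, _ = fx.tumor_load_correlation(scores, fractions)
        assert r < -0.8


class TestCombineFeatures:
    def test_perfect_feature_dominates(self):
        labels = ["control"] * 6 + ["cancer"] * 6
        perfect = [10, 11, 12, 13, 14, 15, 1, 2, 3, 4, 5, 6]
        noise = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8]
        out = fx.combine_features(perfect, noise, labels)
        assert out["auc_methylation"] == 1.0
        assert out["auc_combined"] == 1.0

    def test_pure_noise_is_chance_level(self):
        rng = np.random.default_rng(5)
        labels = ["control"] * 20 + ["cancer"] * 20
        out = fx.combine_features(
            rng.normal(size=40), rng.normal(size=40), labels
        )
        assert abs(out["auc_combined"] - 0.5) < 0.3

    def test_combination_not_worse_than_best_single(self):
        rng = np.random.default_rng(8)
        n = 15
        labels = ["control"] * n + ["cancer"] * n
        md = np.r_[rng.normal(0.7, 0.03, n), rng.normal(0.62, 0.03, n)]
        ei = np.r_[rng.normal(170, 3, n), rng.normal(163, 3, n)]
        out = fx.combine_features(md, ei, labels)
        best = max(out["auc_methylation"], out["auc_e_index"])
        assert out["auc_combined"] >= best - 0.02
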