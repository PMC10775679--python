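"""Abnormal indicators, quantitative normalization, scans, permutation null."""

import numpy as np
import pandas as pd
import pytest

from rarept import (
    BiomarkerEffect,
    DiseaseSpec,
    SignatureCode,
    abnormal_indicator,
    association_scan,
    generate_cohort,
    normalize_quantitative,
    permutation_null,
)
from rarept.biomarkers import count_bonferroni_significant

from conftest import make_vocab, signature_count_scores, signature_specs


class TestAbnormalIndicator:
    def test_boundary_values_count_as_normal(self):
        assert not abnormal_indicator([2.0], "above", -2.0, 2.0)[0]
        assert not abnormal_indicator([-2.0], "below", -2.0, 2.0)[0]
        assert not abnormal_indicator([2.0], "outside", -2.0, 2.0)[0]

    def test_directions(self):
        assert abnormal_indicator([2.1], "above", -2.0, 2.0)[0]
        assert not abnormal_indicator([2.1], "below", -2.0, 2.0)[0]
        assert abnormal_indicator([-2.5], "outside", -2.0, 2.0)[0]
        assert abnormal_indicator([-2.5], "below", -2.0, 2.0)[0]
        assert not abnormal_indicator([0.0], "outside", -2.0, 2.0)[0]
        with pytest.raises(ValueError):
            abnormal_indicator([0.0], "sideways", -2.0, 2.0)


@pytest.fixture(scope="module")
def biomarker_cohort():
    vocab = make_vocab(6)
    spec = DiseaseSpec(
        phecode=vocab.codes[0], prevalence=0.05,
        biomarker_effects=(BiomarkerEffect("t0", "above", 1.0),),
    )
    return generate_cohort([spec], 4000, vocab, seed=61)


class TestNormalizeQuantitative:

    def test_in_range_population_has_mean_zero_var_one_per_sex(self, biomarker_cohort):
        z = normalize_quantitative(biomarker_cohort, "t0", "above")
        sex = biomarker_cohort.sex_array()
        ranges = biomarker_cohort.reference_ranges.set_index(["test_id", "sex"])
        values = biomarker_cohort.test_results["t0"].to_numpy()
        for s in ("F", "M"):
            low, high = ranges.loc[("t0", s), ["low", "high"]]
            in_range = (sex == s) & (values >= low) & (values <= high)
            assert z[in_range].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[in_range].var() == pytest.approx(1.0, abs=1e-9)

    def test_below_direction_negates(self, biomarker_cohort):
        za = normalize_quantitative(biomarker_cohort, "t0", "above")
        zb = normalize_quantitative(biomarker_cohort, "t0", "below")
        np.testing.assert_allclose(zb, -za)
        # most extreme low raw value becomes the largest aligned score
        assert np.argmax(zb) == np.argmin(biomarker_cohort.test_results["t0"].to_numpy())

    def test_outside_direction_is_nonnegative(self, biomarker_cohort):
        zo = normalize_quantitative(biomarker_cohort, "t0", "outside")
        assert (zo >= 0).all()


def _planted_cohort(seed, effect=2.0, n=3000, n_diseases=3):
    vocab = make_vocab(10 + n_diseases * 5)
    specs = signature_specs(
        vocab, n_diseases, prevalence=0.04, biomarker_effect=effect
    )
    cohort = generate_cohort(specs, n, vocab, seed=seed)
    return cohort, specs


class TestAssociationScan:
    def test_planted_effect_detected_in_expected_direction(self):
        cohort, specs = _planted_cohort(seed=62)
        scores = signature_count_scores(cohort, specs)
        results = association_scan(scores, cohort, cohort.relationships, "all",
                                   "logistic_abnormal")
        assert all(r.estimable for r in results)
        assert all(r.coefficient > 0 for r in results)
        assert count_bonferroni_significant(results) == len(results)
        linear = association_scan(scores, cohort, cohort.relationships, "all",
                                  "linear_quantitative")
        assert all(r.coefficient > 0 and r.bonferroni_significant for r in linear)

    def test_controls_only_excludes_cases_yet_detects_undiagnosed_signal(self):
        vocab = make_vocab(12)
        specs = signature_specs(vocab, 1, prevalence=0.05, underdiagnosis=0.5,
                                biomarker_effect=2.0)
        cohort = generate_cohort(specs, 8000, vocab, seed=63)
        scores = signature_count_scores(cohort, specs)
        results = association_scan(scores, cohort, cohort.relationships,
                                   "controls_only", "logistic_abnormal")
        # undiagnosed cases are labeled controls but carry signatures and
        # shifted biomarkers: the association survives excluding known cases
        assert results[0].significant

    def test_null_predictions_have_type_I_error_near_alpha(self):
        # uninformative classifier, no biomarker effects: fraction of
        # nominally significant two-sided tests across replicates ~ alpha
        from scipy import stats

        n_sig = 0
        n_tests = 0
        for rep in range(25):
            cohort, specs = _planted_cohort(seed=700 + rep, effect=0.0, n=1200,
                                            n_diseases=2)
            rng = np.random.default_rng(800 + rep)
            frames = []
            for spec in specs:
                frames.append(pd.DataFrame({
                    "participant_id": cohort.participant_ids,
                    "query": spec.phecode,
                    "score": (rng.random(cohort.n) < 0.1).astype(float),
                    "in_training": False,
                }))
            scores = pd.concat(frames, ignore_index=True)
            results = association_scan(scores, cohort, cohort.relationships,
                                       "all", "linear_quantitative")
            # two-sided nominal test, ignoring direction
            n_sig += sum(r.estimable and r.p_value < 0.05 for r in results)
            n_tests += sum(r.estimable for r in results)
        hi = stats.binom.ppf(0.999, n_tests, 0.05)
        assert n_sig <= hi

    def test_fully_diagnosed_cohort_controls_only_linear_can_empty(self):
        vocab = make_vocab(6)
        spec = DiseaseSpec(phecode=vocab.codes[0], prevalence=1.0,
                           biomarker_effects=(BiomarkerEffect("t0", "above", 0.0),))
        cohort = generate_cohort([spec], 50, vocab, seed=64)
        scores = pd.DataFrame({"participant_id": cohort.participant_ids,
                               "query": spec.phecode, "score": 0.0,
                               "in_training": False})
        with pytest.raises(ValueError, match="empty analysis set"):
            association_scan(scores, cohort, cohort.relationships,
                             "controls_only", "logistic_abnormal")


class TestPermutationNull:
    def test_observed_zero_gives_p_one(self):
        cohort, specs = _planted_cohort(seed=65, effect=0.0, n=800, n_diseases=2)
        rng = np.random.default_rng(65)
        scores = signature_count_scores(cohort, specs).assign(
            score=lambda df: (rng.random(len(df)) < 0.05).astype(float)
        )
        null = permutation_null(cohort.relationships, scores, cohort, n_perm=10, seed=0)
        assert null["observed"] == 0
        assert null["empirical_p"] == 1.0

    def test_strong_planted_relationships_give_small_p(self):
        # 8 diseases, each with its own strongly shifted test: only the
        # identity pairing recovers all associations
        cohort, specs = _planted_cohort(seed=66, effect=2.5, n=4000, n_diseases=8)
        scores = signature_count_scores(cohort, specs)
        null = permutation_null(cohort.relationships, scores, cohort, n_perm=19, seed=3)
        assert null["observed"] >= 6
        assert null["empirical_p"] <= 0.05

    def test_needs_two_phecodes_and_tests(self):
        cohort, specs = _planted_cohort(seed=67, n=500, n_diseases=1)
        scores = signature_count_scores(cohort, specs)
        with pytest.raises(ValueError):
            permutation_null(cohort.relationships, scores, cohort, n_perm=5, seed=0)

    def test_empirical_p_consistent_with_counts(self):
        cohort, specs = _planted_cohort(seed=68, effect=2.0, n=2000, n_diseases=2)
        scores = signature_count_scores(cohort, specs)
        null = permutation_null(cohort.relationships, scores, cohort, n_perm=11, seed=5)
        expected = (1 + np.sum(null["permutation_counts"] >= null["observed"])) / 12
        assert null["empirical_p"] == pytest.approx(expected)
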