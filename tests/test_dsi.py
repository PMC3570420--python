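import dataclasses
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mciconvert.cohort import SubjectRecord, default_cohort_spec, generate_cohort
from mciconvert.dsi import (
    DsiFitError,
    DsiModel,
    DsiScoreError,
    classify,
    composite_dsi,
    dsi_category,
    export_fingerprint,
    fit_dsi_model,
    fit_feature_reference,
    read_fingerprint,
    split_cohort,
)


# ---------------------------------------------------------------------------
# independent oracles


def oracle_fitness(neg, pos, direction, x):
    """Hand ECDF computation with explicit counting loops."""
    def frac_leq(vals):
        return sum(1.0 for v in vals if v < x) / len(vals) + \
            0.5 * sum(1.0 for v in vals if v == x) / len(vals)

    def frac_geq(vals):
        return sum(1.0 for v in vals if v > x) / len(vals) + \
            0.5 * sum(1.0 for v in vals if v == x) / len(vals)

    if direction == "high":
        fn, fp = frac_leq(pos), frac_geq(neg)
    else:
        fn, fp = frac_geq(pos), frac_leq(neg)
    return 0.5 if fn + fp == 0 else fn / (fn + fp)


def oracle_youden(neg, pos, direction):
    """Exhaustive threshold sweep over all pooled midpoints."""
    pooled = sorted(set(neg) | set(pos))
    cuts = [(a + b) / 2 for a, b in zip(pooled, pooled[1:])]
    cuts += [pooled[0] - 1, pooled[-1] + 1]
    best = 0.0
    for t in cuts:
        if direction == "high":
            sens = sum(1 for v in pos if v > t) / len(pos)
            spec = sum(1 for v in neg if v <= t) / len(neg)
        else:
            sens = sum(1 for v in pos if v < t) / len(pos)
            spec = sum(1 for v in neg if v >= t) / len(neg)
        best = max(best, sens + spec - 1)
    return best


# ---------------------------------------------------------------------------
# fitness


class TestFitness:
    def test_positive_only_tail(self):
        ref = fit_feature_reference("f", [1, 2, 3], [4, 5, 6], "high")
        assert ref.fitness(5.0) == 1.0

    def test_negative_only_tail(self):
        ref = fit_feature_reference("f", [1, 2, 3], [4, 5, 6], "high")
        assert ref.fitness(1.5) == 0.0

    def test_gap_guard(self):
        ref = fit_feature_reference("f", [1, 2, 3], [4, 5, 6], "high")
        assert ref.fitness(3.5) == 0.5

    @pytest.mark.parametrize("direction", ["low", "high"])
    def test_matches_hand_ecdf(self, direction):
        rng = np.random.default_rng(0)
        neg = rng.integers(0, 8, size=9).tolist()
        pos = rng.integers(3, 11, size=7).tolist()
        ref = fit_feature_reference("f", neg, pos, direction)
        for x in np.linspace(-1, 12, 40):
            assert ref.fitness(float(x)) == pytest.approx(
                oracle_fitness(neg, pos, direction, float(x))
            )

    def test_range(self):
        rng = np.random.default_rng(1)
        ref = fit_feature_reference(
            "f", rng.normal(0, 1, 50), rng.normal(1, 1, 50), "high"
        )
        for x in rng.normal(0.5, 2, 100):
            assert 0.0 <= ref.fitness(float(x)) <= 1.0

    @given(
        neg=st.lists(st.integers(0, 10), min_size=2, max_size=10),
        pos=st.lists(st.integers(0, 10), min_size=2, max_size=10),
        x=st.integers(-2, 12),
    )
    @settings(max_examples=80, deadline=None)
    def test_label_swap_antisymmetry(self, neg, pos, x):
        # swapping the reference populations (and hence the orientation)
        # reflects fitness around 0.5
        a = fit_feature_reference("f", neg, pos, "high")
        b = fit_feature_reference("f", pos, neg, "low")
        assert a.fitness(float(x)) + b.fitness(float(x)) == pytest.approx(1.0)
        assert a.relevance == pytest.approx(b.relevance)


class TestRelevance:
    def test_identical_populations(self):
        ref = fit_feature_reference("f", [1, 2, 3], [1, 2, 3], "high")
        assert ref.relevance == 0.0

    def test_disjoint_populations(self):
        ref = fit_feature_reference("f", [1, 2, 3], [4, 5, 6], "high")
        assert ref.relevance == 1.0

    def test_interleaved(self):
        ref = fit_feature_reference("f", [1, 3], [2, 4], "high")
        assert ref.relevance == pytest.approx(0.5)

    @pytest.mark.parametrize("direction", ["low", "high"])
    def test_matches_exhaustive_sweep_toy(self, direction):
        rng = np.random.default_rng(2)
        for _ in range(20):
            neg = rng.integers(0, 10, size=rng.integers(2, 10)).tolist()
            pos = rng.integers(0, 10, size=rng.integers(2, 10)).tolist()
            ref = fit_feature_reference("f", neg, pos, direction)
            assert ref.relevance == pytest.approx(
                oracle_youden(neg, pos, direction)
            )

    def test_tau_parameters_match_sweep(self):
        rng = np.random.default_rng(3)
        neg = rng.normal(93, 61, 10_000)
        pos = rng.normal(118, 57, 10_000)
        ref = fit_feature_reference("csf_tau", neg, pos, "high")
        # independent oracle: Youden via the ROC curve
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve(
            np.r_[np.zeros(len(neg)), np.ones(len(pos))], np.r_[neg, pos]
        )
        assert ref.relevance == pytest.approx(float(np.max(tpr - fpr)), abs=0.02)

    def test_error_names_feature(self):
        with pytest.raises(DsiFitError, match="csf_tau"):
            fit_feature_reference("csf_tau", [], [1, 2], "high")


# ---------------------------------------------------------------------------
# categories / binary call


class TestCategories:
    @pytest.mark.parametrize("value,category", [
        (0.0, 1), (0.169999, 1), (0.17, 2), (0.33, 3), (0.499999, 3),
        (0.50, 4), (0.67, 5), (0.83, 6), (1.0, 6),
    ])
    def test_binning(self, value, category):
        assert dsi_category(value) == category

    def test_cutoff_call(self):
        assert classify(0.50) == "converter"
        assert classify(0.499999) == "nonconverter"

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            dsi_category(1.2)
        with pytest.raises(ValueError):
            classify(-0.1)


# ---------------------------------------------------------------------------
# composite


def flat_model(refs):
    return DsiModel(refs=refs, tree={"root": list(refs)})


class TestComposite:
    def test_single_feature_equals_fitness(self):
        ref = fit_feature_reference("f", [1, 2, 3], [4, 5, 6], "high")
        res = composite_dsi({"f": 4.5}, flat_model({"f": ref}))
        assert res.composite == ref.fitness(4.5)

    def test_all_fitness_one_gives_one(self):
        refs = {
            "a": fit_feature_reference("a", [1, 2], [5, 6], "high"),
            "b": fit_feature_reference("b", [10, 20], [50, 60], "high"),
        }
        res = composite_dsi({"a": 5.5, "b": 55.0}, flat_model(refs))
        assert res.composite == 1.0

    def test_two_leaf_weighted_mean(self):
        # leaf fitnesses 0.2 and 0.8 with equal relevance -> composite 0.5;
        # verified against an independent brute-force weighted mean
        ref_a = fit_feature_reference("a", [0] * 6 + [2] * 4, [0] * 1 + [2] * 9, "high")
        ref_b = fit_feature_reference("b", [0] * 9 + [2] * 1, [0] * 4 + [2] * 6, "high")
        fa, fb = ref_a.fitness(1.0), ref_b.fitness(1.0)
        assert (fa, fb) == (pytest.approx(0.2), pytest.approx(0.8))
        assert ref_a.relevance == pytest.approx(ref_b.relevance)
        res = composite_dsi({"a": 1.0, "b": 1.0}, flat_model({"a": ref_a, "b": ref_b}))
        expect = (ref_a.relevance * fa + ref_b.relevance * fb) / (
            ref_a.relevance + ref_b.relevance
        )
        assert res.composite == pytest.approx(expect) == pytest.approx(0.5)

    def test_missing_data_invariance(self, cohort):
        train, test = split_cohort(cohort, seed=3)
        model = fit_dsi_model(train)
        subject = next(r for r in test if r.csf_present and r.mri_present)
        # remove the CSF features from the subject...
        nulled = dataclasses.replace(
            subject,
            features={**subject.features, "csf_tau": None, "csf_abeta42": None},
        )
        # ...vs a model without the CSF leaves
        pruned_tree = {
            k: [c for c in v if c not in ("csf", "csf_tau", "csf_abeta42")]
            for k, v in model.tree.items()
            if k != "csf"
        }
        pruned = DsiModel(
            refs={k: v for k, v in model.refs.items()
                  if k not in ("csf_tau", "csf_abeta42")},
            tree=pruned_tree,
        )
        assert composite_dsi(nulled, model).composite == pytest.approx(
            composite_dsi(subject, pruned).composite
        )

    def test_monotone_in_observed_feature(self, cohort):
        train, test = split_cohort(cohort, seed=3)
        model = fit_dsi_model(train)
        for subject in test[:10]:
            if subject.features.get("csf_tau") is None:
                continue
            base = composite_dsi(subject, model).composite
            raised = dataclasses.replace(
                subject,
                features={**subject.features,
                          "csf_tau": subject.features["csf_tau"] + 50},
            )
            assert composite_dsi(raised, model).composite >= base - 1e-12

    def test_all_missing_raises(self):
        ref = fit_feature_reference("f", [1, 2], [3, 4], "high")
        with pytest.raises(DsiScoreError):
            composite_dsi({"f": None}, flat_model({"f": ref}))

    def test_range_on_cohort(self, cohort):
        train, test = split_cohort(cohort, seed=3)
        model = fit_dsi_model(train)
        for r in test:
            assert 0.0 <= composite_dsi(r, model).composite <= 1.0

    def test_deterministic_fit_and_score(self, cohort):
        train, _ = split_cohort(cohort, seed=3)
        m1, m2 = fit_dsi_model(train), fit_dsi_model(train)
        assert m1.to_json() == m2.to_json()


# ---------------------------------------------------------------------------
# fingerprint / serialization


class TestFingerprint:
    def test_round_trip(self, cohort, tmp_path):
        train, test = split_cohort(cohort, seed=3)
        model = fit_dsi_model(train)
        res = composite_dsi(test[0], model)
        path = tmp_path / "fp.json"
        export_fingerprint(res, path)
        parsed = read_fingerprint(path)
        assert parsed == json.loads(export_fingerprint(res))
        assert parsed["composite"] == res.composite
        assert parsed["tree"] == res.tree

    def test_single_leaf_model(self):
        ref = fit_feature_reference("f", [1, 2], [3, 4], "high")
        res = composite_dsi({"f": 3.5}, flat_model({"f": ref}))
        parsed = json.loads(export_fingerprint(res))
        assert set(parsed["nodes"]) == {"root", "f"}

    def test_missing_branch_flagged(self, cohort):
        train, test = split_cohort(cohort, seed=3)
        model = fit_dsi_model(train)
        subject = next(r for r in test if not r.csf_present)
        parsed = json.loads(export_fingerprint(composite_dsi(subject, model)))
        assert parsed["nodes"]["csf"]["no_data"] is True
        assert parsed["nodes"]["csf"]["dsi"] is None

    def test_model_serialization_round_trip(self, cohort, tmp_path):
        train, _ = split_cohort(cohort, seed=3)
        model = fit_dsi_model(train)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = DsiModel.from_json(path)
        assert loaded.to_json() == model.to_json()


# ---------------------------------------------------------------------------
# split


class TestSplit:
    def test_stratified_and_deterministic(self, cohort):
        train, test = split_cohort(cohort, seed=11)
        assert len(train) + len(test) == len(cohort)
        again = split_cohort(cohort, seed=11)
        assert (train, test) == again
        for group, total in (("converter", 158), ("reverter", 15)):
            n_test = sum(r.group == group for r in test)
            assert n_test == round(total / 2)

    def test_disjoint(self, cohort):
        train, test = split_cohort(cohort, seed=11)
        assert not {r.subject_id for r in train} & {r.subject_id for r in test}
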