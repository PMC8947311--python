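import numpy as np
import pytest

from igri.core_model import ExamRecord, ValidationError, default_index_model
from igri.evaluation import (
    ablation_nni,
    evaluate_cohort,
    group_summary,
    md_correlation,
    misclassification_rate,
    overlap_coefficient,
    stage_summary,
)
from igri.synthetic_cohort import CohortConfig, build_reference, generate_cohort


class TestMisclassificationRate:
    def test_printed_rows_correctly_separated(self):
        assert misclassification_rate(
            np.array([0.679, 0.191]), np.array([1, 0]), 0.36
        ) == 0.0

    def test_flipped_labels_complement(self):
        assert misclassification_rate(
            np.array([0.679, 0.191]), np.array([0, 1]), 0.36
        ) == 1.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        expected = sum(
            int((s > 0.36) != bool(l)) for s, l in zip(scores, labels)
        ) / 50
        assert misclassification_rate(scores, labels, 0.36) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            misclassification_rate(np.array([]), np.array([]), 0.36)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 80)
        labels = rng.integers(0, 2, 80)
        value = misclassification_rate(scores, labels, 0.4)
        perm = rng.permutation(80)
        assert misclassification_rate(scores[perm], labels[perm], 0.4) == value


class TestGroupSummary:
    def test_constant_groups(self):
        scores = np.array([0.2] * 5 + [0.6] * 5)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        out = group_summary(scores, groups)
        assert out["groups"]["a"]["mean"] == pytest.approx(0.2)
        assert out["groups"]["b"]["mean"] == pytest.approx(0.6)
        assert out["groups"]["a"]["n"] == 5

    def test_gaussian_group_means_within_3se(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.3, 0.05, 400)
        b = rng.normal(0.7, 0.05, 400)
        out = group_summary(
            np.concatenate([a, b]),
            np.array(["a"] * 400 + ["b"] * 400),
            test_pairs=[("a", "b")],
        )
        se = 0.05 / np.sqrt(400)
        assert abs(out["groups"]["a"]["mean"] - 0.3) < 3 * se
        assert abs(out["groups"]["b"]["mean"] - 0.7) < 3 * se
        assert out["tests"][0]["p_value"] < 1e-10

    def test_identical_groups_null_p(self):
        high_p = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = rng.normal(0.5, 0.1, 200)
            groups = np.array(["a", "b"] * 100)
            out = group_summary(scores, groups, test_pairs=[("a", "b")])
            if out["tests"][0]["p_value"] >= 0.5:
                high_p += 1
        assert high_p >= 3  # p uniform under null; >=0.5 about half the time

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            group_summary(np.array([1.0, 2.0]), np.array(["a", "b"]), [("a", "c")])


class TestOverlap:
    def test_disjoint_samples(self):
        assert overlap_coefficient(np.full(50, 0.1), np.full(50, 0.9)) == 0.0

    def test_identical_samples(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 100)
        assert overlap_coefficient(x, x) == pytest.approx(1.0)


class TestAblation:
    @pytest.fixture(scope="class")
    def setup(self):
        from igri.core_model import default_normalization_spec

        spec = default_normalization_spec()
        cohort = generate_cohort(CohortConfig(n_normal=150, n_glaucoma=200, seed=31))
        return cohort, build_reference(cohort, spec), spec

    def test_nni_ratio_zero_is_noop_comparison(self, setup):
        cohort, reference, spec = setup
        model = default_index_model().with_ratio(1.0)
        report = ablation_nni(cohort, reference, model, spec)
        assert report["overlap_reduction"] == 0.0
        assert report["with_nni"] == report["base_only"]

    def test_with_nni_not_worse_when_nni_perfect(self, spec, model):
        # Two tight clusters: NNI equals the true label for every row.
        rng = np.random.default_rng(8)
        normal = [
            ExamRecord(1.4 + rng.normal(0, 0.05), -1.5, 125, 140, 63, 13, label=0)
            for _ in range(60)
        ]
        glaucoma = [
            ExamRecord(9.5 + rng.normal(0, 0.05), -7.8, 56, 54, 48, 11, label=1)
            for _ in range(60)
        ]
        cohort = normal + glaucoma
        reference = build_reference(cohort, spec)
        report = ablation_nni(cohort, reference, model, spec)
        assert (
            report["with_nni"]["misclassification"]
            <= report["base_only"]["misclassification"]
        )

    def test_report_fields(self, setup, model):
        cohort, reference, spec = setup
        report = ablation_nni(cohort, reference, model, spec)
        for variant in ("with_nni", "base_only"):
            assert 0.0 <= report[variant]["misclassification"] <= 1.0
            assert 0.0 <= report[variant]["overlap"] <= 1.0


class TestMDCorrelation:
    def test_affine_decreasing_gives_abs_one(self):
        records = [
            ExamRecord(5, md, 80, 80, 50, 15, label=1) for md in np.linspace(-20, 0, 10)
        ]
        scores = np.array([0.9 - 0.04 * i for i in range(10)])  # decreasing in MD
        out = md_correlation(records, scores)
        assert out["abs_r"] == pytest.approx(1.0)
        assert out["r"] < 0

    def test_independent_scores_low_abs_r(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            records = [
                ExamRecord(5, float(md), 80, 80, 50, 15, label=1)
                for md in rng.uniform(-20, 0, 200)
            ]
            scores = rng.uniform(0, 1, 200)
            assert md_correlation(records, scores)["abs_r"] < 0.3

    def test_matches_textbook_formula(self, spec, model):
        from igri.index import score_cohort

        cohort = generate_cohort(CohortConfig(n_normal=100, n_glaucoma=150, seed=41))
        reference = build_reference(cohort, spec)
        igri, _, _ = score_cohort(cohort, spec, reference, model, leave_one_out=True)
        out = md_correlation(cohort, igri)
        md = np.array([r.md for r in cohort if r.label == 1])
        sub = igri[np.array([r.label == 1 for r in cohort])]
        mx, my = md.mean(), sub.mean()
        r_manual = ((md - mx) * (sub - my)).sum() / np.sqrt(
            ((md - mx) ** 2).sum() * ((sub - my) ** 2).sum()
        )
        assert out["r"] == pytest.approx(r_manual, abs=1e-12)

    def test_constant_input_rejected(self):
        records = [ExamRecord(5, -5, 80, 80, 50, 15, label=1) for _ in range(5)]
        with pytest.raises(ValidationError):
            md_correlation(records, np.full(5, 0.5))

    def test_too_few_glaucoma_rows(self):
        records = [ExamRecord(5, -5, 80, 80, 50, 15, label=0) for _ in range(5)]
        with pytest.raises(ValidationError):
            md_correlation(records, np.full(5, 0.5))


def test_evaluate_cohort_report_shape(spec, model):
    cohort = generate_cohort(CohortConfig(n_normal=100, n_glaucoma=150, seed=2))
    reference = build_reference(cohort, spec)
    report = evaluate_cohort(cohort, reference, model, spec)
    assert report["evaluation_mode"] == "in-sample"
    assert report["n"] == 250
    assert set(report["group_summary"]["groups"]) == {"glaucoma", "normal"}
    assert report["group_summary"]["groups"]["glaucoma"]["mean"] > (
        report["group_summary"]["groups"]["normal"]["mean"]
    )
    stages = set(report["stage_summary"]["groups"])
    assert "normal" in stages


def test_stage_summary_groups(spec, model):
    records = [
        ExamRecord(5, -15, 60, 60, 40, 15, label=1),
        ExamRecord(5, -8, 70, 70, 45, 15, label=1),
        ExamRecord(3, -2, 90, 90, 55, 14, label=1),
        ExamRecord(1, -1, 120, 130, 60, 13, label=0),
    ]
    scores = np.array([0.8, 0.6, 0.4, 0.2])
    out = stage_summary(records, scores, model)
    assert out["groups"]["advanced"]["mean"] == pytest.approx(0.8)
    assert out["groups"]["intermediate"]["mean"] == pytest.approx(0.6)
    assert out["groups"]["early"]["mean"] == pytest.approx(0.4)
    assert out["groups"]["normal"]["mean"] == pytest.approx(0.2)
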