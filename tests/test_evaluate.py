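"""LOOCV harness, report bookkeeping, presets, grid search, hierarchy."""

import numpy as np
import pytest

from kernelfield.classify import DecisionRule
from kernelfield.dataset import LabeledDataset
from kernelfield.evaluate import (
    PRESETS,
    PipelineConfig,
    fit_hierarchical,
    grid_search,
    hierarchical_predict,
    loocv,
    loocv_hierarchical,
)
from kernelfield.kernels import KernelSpec
from kernelfield.synth import (
    biased_protein_dataset,
    default_protein_profiles,
    make_concentric_shells,
    make_gaussian_blobs,
)


def linear_knn(K=1, **kw):
    return PipelineConfig(
        method="kpca", spec=KernelSpec("linear"), rule=DecisionRule("knn", K=K), **kw
    )


@pytest.fixture(scope="module")
def blobs():
    return make_gaussian_blobs([10, 10], dimensions=3, separation=10.0, seed=42)


class TestLoocv:
    def test_well_separated_classes_are_perfect(self, blobs):
        assert loocv(blobs, linear_knn()).overall == 1.0

    def test_identical_samples_fall_back_to_tie_breaking(self):
        """Four identical samples, labels (0, 0, 1, 2): every fold sees all
        neighbours at distance zero, so the vote reduces to the deterministic
        tie-break chain and only the two class-0 samples are recovered."""
        data = LabeledDataset(
            X=np.tile([1.0, 2.0], (4, 1)), labels=[0, 0, 1, 2], ids=list("abcd")
        )
        cfg = PipelineConfig(
            method="kpca",
            spec=KernelSpec("linear", theta=1.0),
            rule=DecisionRule("knn", K=3),
            k=1,
            scale=False,
            center=False,
        )
        rep = loocv(data, cfg)
        assert rep.overall == 0.5  # the majority-class frequency
        np.testing.assert_array_equal(np.diag(rep.confusion), [2, 0, 0])

    def test_constant_vote_reproduces_majority_frequency(self, rng):
        """K = n-1 KNN sees every other sample, so on a single-majority
        dataset the prediction is constant and LOOCV equals the majority
        frequency exactly."""
        X = rng.standard_normal((10, 3))
        data = LabeledDataset(X=X, labels=[0] * 6 + [1] * 4, ids=[f"s{i}" for i in range(10)])
        rep = loocv(data, linear_knn(K=9, scale=False))
        assert rep.overall == 0.6

    def test_confusion_bookkeeping(self, blobs):
        rep = loocv(blobs, linear_knn(K=3))
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), [10, 10])
        assert rep.overall == np.trace(rep.confusion) / rep.n
        for i, c in enumerate(rep.classes):
            assert rep.per_class[c] == rep.confusion[i, i] / rep.confusion[i].sum()

    def test_rerun_bit_identical(self, blobs):
        cfg = PipelineConfig(
            method="kpca", spec=KernelSpec("rbf", sigma=1.0), rule=DecisionRule("intensity")
        )
        r1, r2 = loocv(blobs, cfg), loocv(blobs, cfg)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.overall == r2.overall

    def test_refit_false_mode(self, blobs):
        cfg = linear_knn(K=1, refit=False)
        rep = loocv(blobs, cfg)
        assert rep.overall == 1.0
        assert rep.config["refit"] is False

    def test_gda_requires_three_per_class(self, rng):
        data = LabeledDataset(
            X=rng.standard_normal((5, 2)), labels=[0, 0, 0, 1, 1], ids=list("abcde")
        )
        cfg = PipelineConfig(
            method="gda", spec=KernelSpec("linear"), rule=DecisionRule("knn", K=1), k=1
        )
        with pytest.raises(ValueError, match=">= 3"):
            loocv(data, cfg)

    def test_duplicating_a_correct_sample_is_harmless(self, blobs):
        """Adding an exact duplicate of a correctly classified sample cannot
        reduce its class's LOOCV count (the duplicate is its own perfect
        neighbour)."""
        base = loocv(blobs, linear_knn())
        i = 0  # class-0 sample, correctly classified in the base run
        dup = LabeledDataset(
            X=np.vstack([blobs.X, blobs.X[i]]),
            labels=np.append(blobs.labels, blobs.labels[i]),
            ids=blobs.ids + ("dup",),
        )
        rep = loocv(dup, linear_knn())
        assert rep.confusion[0, 0] >= base.confusion[0, 0]


class TestPresets:
    def test_published_model_configurations(self):
        a = PRESETS["datasetA"]
        assert (a.method, a.spec.name, a.spec.sigma, a.rule.K) == ("kpca", "rbf", 0.5, 3)
        b = PRESETS["datasetB"]
        assert (b.method, b.spec.name, b.spec.degree, b.spec.theta) == ("gda", "polynomial", 4, 1.5)
        assert b.rule.method == "intensity"
        s1 = PRESETS["membrane-stage1"]
        assert (s1.method, s1.spec.name, s1.spec.degree, s1.spec.theta, s1.rule.K) == (
            "kpca", "polynomial", 2, 0.1, 5,
        )
        s2 = PRESETS["membrane-stage2"]
        assert (s2.method, s2.spec.name, s2.spec.sigma, s2.rule.method) == (
            "gda", "rbf", 5.0, "intensity",
        )

    def test_all_presets_run_end_to_end(self):
        data = biased_protein_dataset(default_protein_profiles(), [5] * 4, (80, 120), seed=3)
        for name, cfg in PRESETS.items():
            rep = loocv(data, cfg)
            assert 0.0 <= rep.overall <= 1.0, name


class TestGridSearch:
    def test_single_candidate_ranked_first(self, blobs):
        res = grid_search(blobs, [linear_knn()])
        assert res[0]["rank"] == 1 and res[0]["overall"] == 1.0

    def test_duplicate_candidates_keep_submission_order(self, blobs):
        c = linear_knn(K=3)
        res = grid_search(blobs, [c, c])
        assert [r["rank"] for r in res] == [1, 2]
        assert res[0]["overall"] == res[1]["overall"]

    def test_only_rbf_separates_shells(self):
        shells = make_concentric_shells([1.0, 3.0], [15, 15], noise=0.1, dimensions=10, seed=7)
        candidates = [
            linear_knn(K=3),
            PipelineConfig(
                method="kpca", spec=KernelSpec("rbf", sigma=1.0), rule=DecisionRule("knn", K=3)
            ),
        ]
        res = grid_search(shells, candidates)
        assert res[0]["config"].spec.name == "rbf"

    def test_failing_candidate_reported_not_fatal(self, blobs):
        bad = PipelineConfig(
            method="gda", spec=KernelSpec("linear"), rule=DecisionRule("knn", K=1), k=1
        )
        tiny = LabeledDataset(X=blobs.X[:5], labels=[0, 0, 0, 1, 1], ids=blobs.ids[:5])
        res = grid_search(tiny, [bad, linear_knn()])
        assert "error" in res[-1] and res[0]["overall"] >= 0.0

    def test_empty_candidates_rejected(self, blobs):
        with pytest.raises(ValueError, match="at least one"):
            grid_search(blobs, [])


@pytest.fixture(scope="module")
def five_class_proteins():
    profiles = default_protein_profiles()
    extra = np.full(20, 0.05)
    extra[[0, 5]] += 0.10           # strongly A/G-rich target class
    rest = [j for j in range(20) if j not in (0, 5)]
    extra[rest] -= 0.20 / len(rest)
    return biased_protein_dataset(profiles + [extra], [12] * 5, (200, 400), seed=13)


class TestHierarchical:
    def test_routing_target_never_reaches_stage_two(self, five_class_proteins):
        data = five_class_proteins
        model = fit_hierarchical(
            data, PRESETS["membrane-stage1"], PRESETS["membrane-stage2"], stage1_target_class=4
        )
        preds = model.predict(data.X)
        stage1 = model._stage1_predict(data.X)
        assert np.array_equal(preds == 4, stage1 == 1)

    def test_all_target_input_never_fits_stage_two(self, five_class_proteins):
        only_target = five_class_proteins.subset(five_class_proteins.labels == 4)
        model = fit_hierarchical(
            only_target, PRESETS["membrane-stage1"], PRESETS["membrane-stage2"], 4
        )
        preds = model.predict(only_target.X)
        assert (preds == 4).all()
        assert model._stage2_predict is None

    def test_stage_two_missing_classes_rejected(self, five_class_proteins):
        # keep the target class and a single other class
        mask = np.isin(five_class_proteins.labels, [3, 4])
        data = five_class_proteins.subset(mask)
        model = fit_hierarchical(data, PRESETS["membrane-stage1"], PRESETS["membrane-stage2"], 4)
        sub = data.subset(data.labels == 3)
        only3 = fit_hierarchical(sub.subset(np.arange(sub.n)), PRESETS["membrane-stage1"],
                                 PRESETS["membrane-stage2"], 3)
        with pytest.raises(ValueError, match="stage-2"):
            only3._ensure_stage2()

    def test_loocv_accuracy_consistent_with_stages(self, five_class_proteins):
        """End-to-end accuracy is at least the product of the two stages'
        standalone LOOCV accuracies (routing errors compound, nothing else)."""
        data = five_class_proteins
        binary = LabeledDataset(X=data.X, labels=(data.labels == 4).astype(int), ids=data.ids)
        s1 = loocv(binary, PRESETS["membrane-stage1"]).overall
        rest = data.subset(data.labels != 4)
        s2 = loocv(rest, PRESETS["membrane-stage2"]).overall
        rep = loocv_hierarchical(data, PRESETS["membrane-stage1"], PRESETS["membrane-stage2"], 4)
        assert rep.overall >= s1 * s2 - 0.1

    def test_rerun_bit_identical(self, five_class_proteins):
        p1 = hierarchical_predict(
            five_class_proteins, PRESETS["membrane-stage1"], PRESETS["membrane-stage2"], 4
        )
        p2 = hierarchical_predict(
            five_class_proteins, PRESETS["membrane-stage1"], PRESETS["membrane-stage2"], 4
        )
        np.testing.assert_array_equal(p1, p2)

    def test_absent_target_rejected(self, five_class_proteins):
        with pytest.raises(ValueError, match="absent"):
            hierarchical_predict(
                five_class_proteins, PRESETS["membrane-stage1"], PRESETS["membrane-stage2"], 9
            )
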