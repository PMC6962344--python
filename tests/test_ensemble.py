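import numpy as np
import pytest
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from modfuse.classifiers import fit_weird, weird_decision_values
from modfuse.ensemble import (
    EnsembleConfig,
    _fit_svc_on_kernel,
    _svc_decision_on_kernel,
    _weight_candidates,
    fit_ensemble,
    fuse,
    inner_cv_score,
    optimize_weights,
    predict_subject,
    select_modality_classifier,
)
from modfuse.panel_io import build_panel
from modfuse.synthetic_data import ModalityBlock, SyntheticSpec, generate_panel

from conftest import make_labels, make_table, xor_data

FAST = dict(inner_folds=3, c_folds=2)


class TestKernelFastPath:
    @pytest.mark.parametrize("first_label", [-1.0, 1.0])
    @pytest.mark.parametrize("C", [2.0**-5, 1.0, 2.0**10])
    def test_lowlevel_fit_matches_svc_decision_values(self, rng, C, first_label):
        n, f = 50, 6
        X = rng.standard_normal((n, f))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        y[:2] = [first_label, -first_label]  # pin libsvm's class ordering
        X[y > 0] += 0.5
        K = rbf_kernel(X, gamma=1.0 / f)
        tr, te = np.arange(40), np.arange(40, 50)
        ref = SVC(kernel="precomputed", C=C).fit(K[np.ix_(tr, tr)], y[tr])
        expected = ref.decision_function(K[np.ix_(te, tr)])
        model = _fit_svc_on_kernel(K, y, tr, C)
        got = _svc_decision_on_kernel(model, K, te, tr)
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestInnerCvScore:
    def test_separable_data_scores_one(self, rng):
        y = np.array([-1.0] * 20 + [1.0] * 20)
        X = rng.standard_normal((40, 3))
        X[y > 0] += 8.0
        assert inner_cv_score(X, y, "weird", n_folds=3) == 1.0
        assert inner_cv_score(X, y, "svm", n_folds=3, c_folds=2) == 1.0

    def test_permuted_labels_score_chance(self, rng):
        n, reps = 200, 200
        X = rng.standard_normal((n, 5))
        scores = []
        for _ in range(reps):
            y = np.array([-1.0] * (n // 2) + [1.0] * (n // 2))
            rng.shuffle(y)
            scores.append(inner_cv_score(X, y, "weird", n_folds=5, seed=0))
        se = np.std(scores, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(scores) - 0.5) < 3 * se + 0.01

    def test_deterministic_given_seed(self, two_class_data):
        X, y = two_class_data
        s1 = inner_cv_score(X, y, "svm", n_folds=3, c_folds=2, seed=11)
        s2 = inner_cv_score(X, y, "svm", n_folds=3, c_folds=2, seed=11)
        assert s1 == s2


class TestSelectModalityClassifier:
    def test_tie_goes_to_weird(self, rng):
        # perfectly separable: both candidates score 1.0, tie rule picks WeiRD
        y = np.array([-1.0] * 16 + [1.0] * 16)
        X = rng.standard_normal((32, 2))
        X[y > 0] += 10.0
        spec = select_modality_classifier(X, y, "m", n_folds=3, c_folds=2)
        assert spec.classifier_type == "weird"
        assert spec.C is None

    def test_xor_structure_selects_svm(self, rng):
        X, y = xor_data(rng, n_per=20)
        spec = select_modality_classifier(X, y, "m", n_folds=3, c_folds=2)
        assert spec.classifier_type == "svm"
        assert spec.C is not None and spec.inner_score > 0.9


def _panel_from_arrays(arrays, y, prefix="m"):
    subjects = [f"s{i:03d}" for i in range(len(y))]
    labels = make_labels(subjects, [s for s, yi in zip(subjects, y) if yi > 0])
    tables = {
        f"{prefix}{k}": make_table(f"{prefix}{k}", X, subjects=subjects)
        for k, X in enumerate(arrays)
    }
    return build_panel(tables, labels)


class TestOptimizeWeights:
    def test_single_modality_gets_weight_one(self, rng, two_class_data):
        X, y = two_class_data
        panel = _panel_from_arrays([X], y)
        model = fit_ensemble(panel, EnsembleConfig(classifier="weird", seed=0, **FAST))
        assert model.weights == {"m0": 1}

    def test_identical_modalities_tie_to_uniform(self, rng, two_class_data):
        X, y = two_class_data
        panel = _panel_from_arrays([X, X.copy()], y)
        cfg = EnsembleConfig(classifier="weird", seed=0, **FAST)
        model = fit_ensemble(panel, cfg)
        assert model.weights == {"m0": 1, "m1": 1}

    def test_informative_modality_upweighted_more_often(self):
        info_up, noise_up = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 60
            y = np.array([-1.0] * (n // 2) + [1.0] * (n // 2))
            X_info = rng.standard_normal((n, 10))
            X_info[y > 0, :4] += 0.9
            X_noise = rng.standard_normal((n, 10))
            panel = _panel_from_arrays([X_info, X_noise], y)
            cfg = EnsembleConfig(classifier="weird", seed=seed, **FAST)
            w = fit_ensemble(panel, cfg).weights
            if w["m0"] == 2 and w["m1"] == 1:
                info_up += 1
            elif w["m0"] == 1 and w["m1"] == 2:
                noise_up += 1
        assert info_up > noise_up

    def test_refuses_huge_exhaustive_search(self):
        with pytest.raises(ValueError, match="refused"):
            _weight_candidates(17)


class TestFusion:
    def test_continuous_fusion_arithmetic(self):
        d = np.array([[0.3, -0.2, 0.1]])
        assert fuse(d, np.array([1, 1, 1]))[0] == pytest.approx(0.2)

    def test_missing_modality_omitted(self):
        d = np.array([[0.3, -0.2, np.nan]])
        assert fuse(d, np.array([1, 2, 1]))[0] == pytest.approx(-0.1)

    def test_binary_tie_sums_to_zero(self):
        d = np.array([[0.3, -0.2, 0.1]])
        s = fuse(d, np.array([1, 2, 1]), mode="binary")
        assert s[0] == pytest.approx(0.0)

    def test_positive_rescaling_never_changes_continuous_predictions(self, rng):
        d = rng.standard_normal((50, 4))
        d[rng.random((50, 4)) < 0.2] = np.nan
        d[np.all(np.isnan(d), axis=1), 0] = 1.0  # keep >=1 modality per subject
        w = rng.integers(1, 3, 4)
        base = np.sign(fuse(d, w))
        for lam in (1e-3, 7.0, 1e4):
            np.testing.assert_array_equal(np.sign(fuse(d * lam, w)), base)


class TestEnsembleEndToEnd:
    def test_single_modality_equals_unimodal_predictions(self, rng, two_class_data):
        X, y = two_class_data
        panel = _panel_from_arrays([X], y)
        cfg = EnsembleConfig(classifier="weird", weights="optimized", seed=0, **FAST)
        model = fit_ensemble(panel, cfg)
        # reference: preprocess + WeiRD by hand on the same training set
        from modfuse.preprocessing import apply_soft_normalizer, fit_soft_normalizer

        table = panel.tables["m0"]
        norm = fit_soft_normalizer(table, table.subject_ids)
        Xn = apply_soft_normalizer(norm, table).data.to_numpy()
        d_ref = weird_decision_values(fit_weird(Xn, panel.y()), Xn)
        for i, s in enumerate(panel.subjects):
            rec = predict_subject(model, panel, s)
            assert rec.weighted_sum == pytest.approx(model.weights["m0"] * d_ref[i])
            assert rec.predicted == ("patient" if d_ref[i] > 0 else "control")

    def test_binary_uniform_equals_majority_vote(self, small_panel):
        cfg = EnsembleConfig(classifier="weird", weights="uniform", fusion="binary",
                             seed=0, **FAST)
        model = fit_ensemble(small_panel, cfg)
        for s in small_panel.subjects:
            rec = predict_subject(model, small_panel, s)
            votes = [np.sign(d) for d in rec.decision_values.values()]
            majority = "patient" if sum(votes) > 0 else "control"
            assert rec.predicted == majority

    def test_removing_modality_equals_marking_it_missing(self, small_panel):
        cfg = EnsembleConfig(classifier="weird", weights="uniform", seed=0, **FAST)
        model = fit_ensemble(small_panel, cfg)
        masked = small_panel.mask_modality("b", small_panel.subjects)
        for s in masked.subjects:
            rec_masked = predict_subject(model, masked, s)
            assert set(rec_masked.decision_values) == {"a"}
            rec_full = predict_subject(model, small_panel, s)
            assert rec_masked.decision_values["a"] == rec_full.decision_values["a"]

    def test_no_available_modality_errors(self, small_panel):
        cfg = EnsembleConfig(classifier="weird", seed=0, **FAST)
        model = fit_ensemble(small_panel, cfg)
        stranger_panel = small_panel  # subject id not in any table
        with pytest.raises(ValueError, match="no available modality"):
            predict_subject(model, stranger_panel, "nobody")

    def test_same_seed_gives_identical_serialized_model(self, small_panel):
        cfg = EnsembleConfig(classifier="optimized", weights="optimized", seed=5, **FAST)
        m1 = fit_ensemble(small_panel, cfg)
        m2 = fit_ensemble(small_panel, cfg)
        assert m1.serialize() == m2.serialize()

    def test_uniform_config_fixes_all_weights_to_one(self, small_panel):
        cfg = EnsembleConfig(classifier="weird", weights="uniform", seed=0, **FAST)
        model = fit_ensemble(small_panel, cfg)
        assert set(model.weights.values()) == {1}

    def test_optimized_config_permits_mixed_classifier_types(self, rng):
        # one linearly-shifted modality (WeiRD-friendly) + one XOR modality
        n = 60
        y = np.array([-1.0] * (n // 2) + [1.0] * (n // 2))
        X_lin = rng.standard_normal((n, 20))
        X_lin[y > 0] += 0.35
        X_xor, y_xor = xor_data(rng, n_per=15)
        order = np.argsort(y_xor, kind="stable")  # align label blocks
        panel = _panel_from_arrays([X_lin, X_xor[order]], y)
        cfg = EnsembleConfig(classifier="optimized", weights="optimized", seed=2, **FAST)
        model = fit_ensemble(panel, cfg)
        types = {m: fm.spec.classifier_type for m, fm in model.fitted.items()}
        assert types["m1"] == "svm"

    def test_modality_with_too_few_subjects_is_dropped(self, rng):
        n = 20
        y = np.array([-1.0] * 10 + [1.0] * 10)
        X_ok = rng.standard_normal((n, 4))
        panel = _panel_from_arrays([X_ok, rng.standard_normal((n, 3))], y)
        # restrict modality m1 to one control + patients only
        thin = panel.mask_modality("m1", panel.subjects[1:10])
        cfg = EnsembleConfig(classifier="weird", weights="uniform", seed=0, **FAST)
        model = fit_ensemble(thin, cfg)
        assert list(model.fitted) == ["m0"]


class TestMissingnessDuringTraining:
    def test_weight_search_runs_with_partial_availability(self):
        blocks = (
            ModalityBlock("a", 8, 3, effect_size=1.0, missing_rate=0.25),
            ModalityBlock("b", 6, 2, effect_size=0.5, missing_rate=0.25),
        )
        panel, _ = generate_panel(SyntheticSpec(20, 20, blocks, seed=4))
        cfg = EnsembleConfig(classifier="weird", weights="optimized", seed=0, **FAST)
        model = fit_ensemble(panel, cfg)
        assert set(model.weights) == {"a", "b"}
        for s in panel.subjects:
            rec = predict_subject(model, panel, s)
            avail = {m for m in panel.modalities if s in panel.tables[m].data.index}
            assert set(rec.decision_values) == avail
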