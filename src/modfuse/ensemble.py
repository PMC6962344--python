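"""Multimodal late-fusion ensemble.

For each modality a classifier is trained on that modality's available
training subjects.  Three modality-specific factors are optimized on
training data only, by nested cross-validation: the classifier type (SVM
or WeiRD), the SVM cost parameter C where applicable, and an integer
modality weight w_m ∈ {1, 2}.  At prediction time every available modality
emits a signed decision value d_m and the ensemble predicts patient iff
the weighted sum  S = Σ w_m · d_m  is positive (a binary variant sums
w_m · sign(d_m) instead).  A modality missing for a subject is simply
omitted from the sum, so no imputation is ever needed.

All SVM candidate fits inside the nested loops run on a precomputed RBF
kernel over the modality's training subjects, sliced per fold, which makes
the 16-value C grid cheap; results are identical to fitting on raw
features since gamma is fixed before the loop.
"""

from __future__ import annotations

import itertools
import logging
import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from modfuse.classifiers import (
    C_GRID,
    FittedSvm,
    SvmSpec,
    WeirdModel,
    fit_weird,
    weird_decision_values,
)
from modfuse.panel_io import CONTROL, PATIENT, FeatureTable, ModalityPanel
from modfuse.preprocessing import (
    NormalizerParams,
    ResidualizerParams,
    apply_residualizer,
    apply_soft_normalizer,
    fit_residualizer,
    fit_soft_normalizer,
)

logger = logging.getLogger(__name__)

WEIRD = "weird"
SVM = "svm"

MAX_EXHAUSTIVE_MODALITIES = 16


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of the multimodal scheme.

    classifier: 'optimized' selects SVM vs WeiRD per modality by inner CV;
        'svm'/'weird' force one type everywhere (SVM still tunes C).
    weights: 'optimized' searches {1,2}^M exhaustively; 'uniform' fixes 1.
    fusion: 'decision' sums continuous decision values, 'binary' their signs.
    inner_folds / c_folds: stratified fold counts for the inner CV and the
        second-level CV that scores the SVM's C grid during type selection.
    """

    classifier: str = "optimized"      # optimized | svm | weird
    weights: str = "optimized"         # optimized | uniform
    fusion: str = "decision"           # decision | binary
    residualize: bool = True           # only applies when covariates exist
    global_preproc: bool = False       # fit preprocessing once on the full panel
    standardize_decisions: bool = False  # divide d by its training-set std
    inner_folds: int = 10
    c_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in ("optimized", SVM, WEIRD):
            raise ValueError(f"unknown classifier mode {self.classifier!r}")
        if self.weights not in ("optimized", "uniform"):
            raise ValueError(f"unknown weights mode {self.weights!r}")
        if self.fusion not in ("decision", "binary"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")


@dataclass
class ModalityClassifierSpec:
    """Outcome of per-modality classifier-type selection."""

    modality_name: str
    classifier_type: str               # 'weird' | 'svm'
    C: float | None = None             # present iff classifier_type == 'svm'
    inner_score: float | None = None   # inner-CV balanced accuracy achieved

    def __post_init__(self) -> None:
        if (self.classifier_type == SVM) != (self.C is not None):
            raise ValueError("C must be present iff classifier_type is 'svm'")


@dataclass
class FittedModality:
    """Preprocessing params plus the final classifier for one modality."""

    spec: ModalityClassifierSpec
    train_subjects: list[str]
    residualizer: ResidualizerParams | None
    normalizer: NormalizerParams
    model: WeirdModel | FittedSvm
    decision_scale: float = 1.0


@dataclass
class EnsembleModel:
    """Fitted multimodal ensemble: per-modality classifiers plus weights."""

    fitted: dict[str, FittedModality]
    weights: dict[str, int]
    config: EnsembleConfig

    @property
    def modalities(self) -> list[str]:
        return list(self.fitted)

    def serialize(self) -> bytes:
        return pickle.dumps(self)


@dataclass
class PredictionRecord:
    """Per-subject fused prediction with its per-modality decision values."""

    subject_id: str
    decision_values: dict[str, float]   # only available modalities appear
    weighted_sum: float                 # continuous fusion  Σ w·d
    weighted_sum_binary: float          # binary fusion      Σ w·sign(d)
    predicted: str                      # under the model's fusion mode

    def predicted_class(self, fusion: str = "decision") -> str:
        s = self.weighted_sum if fusion == "decision" else self.weighted_sum_binary
        return PATIENT if s > 0 else CONTROL


# ---------------------------------------------------------------------------
# scoring helpers

def balanced_accuracy_score_signed(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class accuracies for ±1 labels (chance level 0.5)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    accs = []
    for cls in (-1.0, 1.0):
        mask = y_true == cls
        if not mask.any():
            raise ValueError("balanced accuracy needs both classes present")
        accs.append(float((y_pred[mask] == cls).mean()))
    return float(np.mean(accs))


def _sign_predict(s: np.ndarray) -> np.ndarray:
    """Decision threshold at 0; the exact tie S == 0 goes to control."""
    return np.where(np.asarray(s, dtype=float) > 0, 1.0, -1.0)


def _stratified_splits(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    y = np.asarray(y)
    min_class = min(int((y < 0).sum()), int((y > 0).sum()))
    if min_class < 2:
        raise ValueError("cross-validation needs at least 2 subjects per class")
    k = min(n_folds, min_class)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    return list(skf.split(np.zeros(len(y)), y))


def _seed_chain(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(int(seed)).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# kernel-cache SVM internals
#
# The nested loops fit thousands of small SVMs per evaluation; going through
# the low-level libsvm binding skips per-call input validation and is ~7x
# faster while producing bit-identical decision values (pinned by a test
# against SVC).  Falls back to the public estimator if the binding moves.

try:
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _libsvm = None


@dataclass
class _KernelSvm:
    support: np.ndarray   # local indices into the training subset
    coef: np.ndarray      # alpha_i * y_i for the support vectors
    intercept: float
    sign: float           # libsvm orders classes by first appearance in y


def _fit_svc_on_kernel(K: np.ndarray, y: np.ndarray, tr: np.ndarray, C: float):
    Ksub = np.ascontiguousarray(K[np.ix_(tr, tr)])
    ysub = np.ascontiguousarray(y[tr])
    if _libsvm is not None:
        out = _libsvm.fit(Ksub, ysub, svm_type=0, kernel="precomputed",
                          C=float(C), tol=1e-3, cache_size=200.0)
        support, _, _, sv_coef, intercept = out[:5]
        # with ±1 labels libsvm's internal class ordering is fixed, and its raw
        # decision must be negated to make positive mean the +1 (patient)
        # class; verified against SVC for both label orders in the test suite
        return _KernelSvm(np.asarray(support), np.asarray(sv_coef).ravel().copy(),
                          float(intercept[0]), -1.0)
    return SVC(kernel="precomputed", C=C).fit(Ksub, ysub)  # pragma: no cover


def _svc_decision_on_kernel(model, K: np.ndarray, te: np.ndarray, tr: np.ndarray) -> np.ndarray:
    Kte = K[np.ix_(te, tr)]
    if isinstance(model, _KernelSvm):
        return (Kte[:, model.support] @ model.coef + model.intercept) * model.sign
    return model.decision_function(Kte)  # pragma: no cover


def _select_C_on_kernel(
    K: np.ndarray, y: np.ndarray, idx: np.ndarray, n_folds: int, seed: int
) -> float:
    """Grid-search C by pooled balanced accuracy of a stratified CV; ties -> smallest C."""
    splits = _stratified_splits(y[idx], n_folds, seed)
    best_C, best_score = C_GRID[0], -np.inf
    for C in C_GRID:
        true_all, pred_all = [], []
        for tr_loc, te_loc in splits:
            tr, te = idx[tr_loc], idx[te_loc]
            svc = _fit_svc_on_kernel(K, y, tr, C)
            d = _svc_decision_on_kernel(svc, K, te, tr)
            true_all.append(y[te])
            pred_all.append(_sign_predict(d))
        score = balanced_accuracy_score_signed(np.concatenate(true_all), np.concatenate(pred_all))
        if score > best_score:  # strict: ties keep the smaller C seen first
            best_C, best_score = C, score
    return best_C


# ---------------------------------------------------------------------------
# public nested-CV operations

def inner_cv_score(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = WEIRD,
    C: float | None = None,
    n_folds: int = 10,
    c_folds: int = 5,
    seed: int = 0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Inner-CV balanced accuracy, pooled over held-out predictions.

    For the SVM with ``C=None`` the cost parameter is chosen anew inside each
    training split by a second-level CV over the 16-value grid, so the score
    is an honest estimate of the tuned SVM's performance.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if splits is None:
        splits = _stratified_splits(y, n_folds, seed)
    sub_seeds = _seed_chain(seed + 1, len(splits))
    if classifier == SVM:
        K = rbf_kernel(X, gamma=1.0 / X.shape[1])
    true_all, pred_all = [], []
    for i, (tr, te) in enumerate(splits):
        tr = np.asarray(tr)
        te = np.asarray(te)
        if classifier == WEIRD:
            model = fit_weird(X[tr], y[tr])
            d = weird_decision_values(model, X[te])
        elif classifier == SVM:
            C_fold = C if C is not None else _select_C_on_kernel(K, y, tr, c_folds, sub_seeds[i])
            svc = _fit_svc_on_kernel(K, y, tr, C_fold)
            d = _svc_decision_on_kernel(svc, K, te, tr)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        true_all.append(y[te])
        pred_all.append(_sign_predict(d))
    return balanced_accuracy_score_signed(np.concatenate(true_all), np.concatenate(pred_all))


def select_modality_classifier(
    X: np.ndarray,
    y: np.ndarray,
    modality_name: str = "",
    n_folds: int = 10,
    c_folds: int = 5,
    seed: int = 0,
) -> ModalityClassifierSpec:
    """Choose WeiRD vs tuned SVM by inner-CV balanced accuracy; ties go to WeiRD.

    Both candidates are scored on the same fold assignment.  If the SVM wins,
    its cost parameter is then estimated anew on the entire training data.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    splits = _stratified_splits(y, n_folds, seed)
    weird_score = inner_cv_score(X, y, WEIRD, splits=splits, seed=seed)
    svm_score = inner_cv_score(X, y, SVM, c_folds=c_folds, splits=splits, seed=seed)
    if svm_score > weird_score:
        K = rbf_kernel(X, gamma=1.0 / X.shape[1])
        C = _select_C_on_kernel(K, y, np.arange(len(y)), n_folds, seed + 7)
        return ModalityClassifierSpec(modality_name, SVM, C=C, inner_score=svm_score)
    return ModalityClassifierSpec(modality_name, WEIRD, inner_score=weird_score)


# ---------------------------------------------------------------------------
# preprocessing plumbing shared by fit and weight search

def _preprocess_fit(
    table: FeatureTable,
    covariates: pd.DataFrame | None,
    fit_subjects: list[str],
    residualize: bool,
) -> tuple[ResidualizerParams | None, NormalizerParams]:
    resid = None
    work = table
    if residualize and covariates is not None:
        resid = fit_residualizer(table, covariates, fit_subjects)
        work = apply_residualizer(resid, table, covariates)
    norm = fit_soft_normalizer(work, fit_subjects)
    return resid, norm


def _preprocess_apply(
    table: FeatureTable,
    covariates: pd.DataFrame | None,
    resid: ResidualizerParams | None,
    norm: NormalizerParams,
) -> FeatureTable:
    work = table
    if resid is not None:
        work = apply_residualizer(resid, table, covariates)
    return apply_soft_normalizer(norm, work)


def _decision_values(model: WeirdModel | FittedSvm, X: np.ndarray) -> np.ndarray:
    if isinstance(model, WeirdModel):
        return weird_decision_values(model, X)
    return model.svc.decision_function(np.atleast_2d(X))


# ---------------------------------------------------------------------------
# weight optimization

def _weight_candidates(n_modalities: int) -> list[tuple[int, ...]]:
    if n_modalities > MAX_EXHAUSTIVE_MODALITIES:
        raise ValueError(
            f"exhaustive weight search over {{1,2}}^{n_modalities} refused; "
            f"limit is {MAX_EXHAUSTIVE_MODALITIES} modalities"
        )
    return list(itertools.product((1, 2), repeat=n_modalities))


def fuse(d: np.ndarray, w: np.ndarray, mode: str = "decision") -> np.ndarray:
    """Weighted sums over available (non-NaN) modality decision values.

    ``d`` is (n_subjects, n_modalities) with NaN where a modality is missing;
    missing modalities are omitted from the sum.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    contrib = d if mode == "decision" else np.sign(d)
    return np.nansum(contrib * np.asarray(w, dtype=float), axis=1)


def optimize_weights(
    panel_train: ModalityPanel,
    specs: dict[str, ModalityClassifierSpec],
    config: EnsembleConfig,
    seed: int = 0,
    preproc_override: dict | None = None,
) -> dict[str, int]:
    """Exhaustive {1,2}^M weight search scored by inner-CV fused balanced accuracy.

    A fresh nested CV over all training subjects: inside each inner fold every
    modality's preprocessing and classifier (type and C fixed from ``specs``)
    are refit on the inner-training subjects and decision values computed for
    the inner-test subjects; all 2^M candidate weight vectors are then scored
    on these cached values with continuous fusion.  Ties are broken by lowest
    total weight, then lexicographic order.  Training subjects missing a
    modality contribute through the omission rule, exactly as at test time.
    """
    modalities = [m for m in panel_train.modalities if m in specs]
    candidates = _weight_candidates(len(modalities))
    y_all = panel_train.y()
    subj_index = {s: i for i, s in enumerate(panel_train.subjects)}
    splits = _stratified_splits(y_all, config.inner_folds, seed)

    D = np.full((len(subj_index), len(modalities)), np.nan)
    for tr_loc, te_loc in splits:
        tr_set = {panel_train.subjects[i] for i in tr_loc}
        te_set = {panel_train.subjects[i] for i in te_loc}
        for j, m in enumerate(modalities):
            table = panel_train.tables[m]
            fit_subj = [s for s in table.subject_ids if s in tr_set]
            te_subj = [s for s in table.subject_ids if s in te_set]
            if not te_subj:
                continue
            y_fit = panel_train.y(fit_subj)
            if (y_fit < 0).sum() < 2 or (y_fit > 0).sum() < 2:
                continue  # modality unusable in this fold: stays missing
            if preproc_override is not None:
                resid, norm = preproc_override[m]
            else:
                resid, norm = _preprocess_fit(
                    table, panel_train.covariates, fit_subj, config.residualize
                )
            proc = _preprocess_apply(table, panel_train.covariates, resid, norm)
            X_fit = proc.data.loc[fit_subj].to_numpy()
            X_te = proc.data.loc[te_subj].to_numpy()
            spec = specs[m]
            if spec.classifier_type == WEIRD:
                model = fit_weird(X_fit, y_fit)
                d = weird_decision_values(model, X_te)
            else:
                fitted = FittedSvm(
                    SVC(kernel="rbf", C=spec.C, gamma=1.0 / X_fit.shape[1]).fit(X_fit, y_fit),
                    gamma=1.0 / X_fit.shape[1],
                )
                d = fitted.svc.decision_function(X_te)
            for s, val in zip(te_subj, d):
                D[subj_index[s], j] = val

    scorable = ~np.all(np.isnan(D), axis=1)
    best: tuple[int, ...] | None = None
    best_key: tuple | None = None
    for w in candidates:
        s = fuse(D[scorable], np.array(w), mode="decision")
        score = balanced_accuracy_score_signed(y_all[scorable], _sign_predict(s))
        key = (-score, sum(w), w)  # max score, then lowest total weight, then lexicographic
        if best_key is None or key < best_key:
            best, best_key = w, key
    return dict(zip(modalities, best))


# ---------------------------------------------------------------------------
# fitting and prediction

def fit_ensemble(
    panel_train: ModalityPanel,
    config: EnsembleConfig | None = None,
    seed: int | None = None,
    preproc_override: dict | None = None,
) -> EnsembleModel:
    """Train the full multimodal scheme on a training panel.

    Per modality: fit preprocessing, select (or force) the classifier type,
    tune C where applicable, refit the final classifier on all available
    training subjects; then optimize the modality weights (or fix them to 1).
    Modalities with fewer than 2 training subjects per class are dropped with
    a warning.  ``preproc_override`` maps modality -> (residualizer,
    normalizer) fit elsewhere (the global-preprocessing variant).
    """
    config = config or EnsembleConfig()
    seed = config.seed if seed is None else int(seed)
    seeds = _seed_chain(seed, 2 * len(panel_train.modalities) + 1)

    fitted: dict[str, FittedModality] = {}
    specs: dict[str, ModalityClassifierSpec] = {}
    for i, m in enumerate(panel_train.modalities):
        table = panel_train.tables[m]
        subj = table.subject_ids
        y_m = panel_train.y(subj)
        if (y_m < 0).sum() < 2 or (y_m > 0).sum() < 2:
            logger.warning("modality %r dropped: fewer than 2 training subjects per class", m)
            continue
        if preproc_override is not None and m in preproc_override:
            resid, norm = preproc_override[m]
        else:
            resid, norm = _preprocess_fit(table, panel_train.covariates, subj, config.residualize)
        proc = _preprocess_apply(table, panel_train.covariates, resid, norm)
        X = proc.data.to_numpy()

        if config.classifier == "optimized":
            spec = select_modality_classifier(
                X, y_m, m, n_folds=config.inner_folds, c_folds=config.c_folds, seed=seeds[2 * i]
            )
        elif config.classifier == WEIRD:
            spec = ModalityClassifierSpec(m, WEIRD)
        else:
            K = rbf_kernel(X, gamma=1.0 / X.shape[1])
            C = _select_C_on_kernel(K, y_m, np.arange(len(y_m)), config.inner_folds, seeds[2 * i])
            spec = ModalityClassifierSpec(m, SVM, C=C)

        if spec.classifier_type == WEIRD:
            model: WeirdModel | FittedSvm = fit_weird(X, y_m)
        else:
            gamma = 1.0 / X.shape[1]
            model = FittedSvm(SVC(kernel="rbf", C=spec.C, gamma=gamma).fit(X, y_m), gamma,
                              SvmSpec(C=spec.C))
        scale = 1.0
        if config.standardize_decisions:
            d_train = _decision_values(model, X)
            scale = float(max(np.std(d_train), 1e-12))
        fitted[m] = FittedModality(spec, subj, resid, norm, model, scale)
        specs[m] = spec

    if not fitted:
        raise ValueError("no modality has enough training subjects per class")

    if config.weights == "optimized" and len(fitted) > 1:
        dropped = set(panel_train.modalities) - set(fitted)
        sub_panel = _panel_without(panel_train, dropped) if dropped else panel_train
        weights = optimize_weights(sub_panel, specs, config, seed=seeds[-1],
                                   preproc_override=preproc_override)
    else:
        weights = {m: 1 for m in fitted}
    return EnsembleModel(fitted, weights, config)


def _panel_without(panel: ModalityPanel, drop: set[str]) -> ModalityPanel:
    out = panel
    for m in drop:
        out = out.drop_modality(m)
    return out


def decision_value_for(
    model: EnsembleModel,
    modality: str,
    table: FeatureTable,
    covariates: pd.DataFrame | None,
    subject_id: str,
) -> float:
    """Decision value of one modality's fitted classifier for one subject row."""
    fm = model.fitted[modality]
    row = FeatureTable(modality, table.data.loc[[subject_id]])
    proc = _preprocess_apply(row, covariates, fm.residualizer, fm.normalizer)
    d = _decision_values(fm.model, proc.data.to_numpy())
    return float(d[0]) / fm.decision_scale


def predict_subject(
    model: EnsembleModel,
    panel: ModalityPanel,
    subject_id: str,
) -> PredictionRecord:
    """Fused prediction for one subject; missing modalities are omitted.

    Predicted patient iff the weighted sum is strictly positive; the exact
    tie S = 0 (possible in binary fusion) goes to control.
    """
    d_vals: dict[str, float] = {}
    for m in model.modalities:
        table = panel.tables.get(m)
        if table is None or subject_id not in table.data.index:
            continue
        d_vals[m] = decision_value_for(model, m, table, panel.covariates, subject_id)
    if not d_vals:
        raise ValueError(f"subject {subject_id!r} has no available modality")
    s_cont = sum(model.weights[m] * d for m, d in d_vals.items())
    s_bin = sum(model.weights[m] * float(np.sign(d)) for m, d in d_vals.items())
    s = s_cont if model.config.fusion == "decision" else s_bin
    return PredictionRecord(
        subject_id=subject_id,
        decision_values=d_vals,
        weighted_sum=s_cont,
        weighted_sum_binary=s_bin,
        predicted=PATIENT if s > 0 else CONTROL,
    )
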