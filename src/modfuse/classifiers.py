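"""Binary classifiers under a common signed decision-value contract.

Both classifiers are fit on a feature matrix with labels in {-1, +1}
(control = -1, patient = +1) and emit one signed continuous decision value
per test sample: the sign encodes the predicted class and the absolute
value the certainty of the classifier.

WeiRD (weighted robust distance) is a parameter-free distance-to-centroid
classifier.  Training computes the two class centroids and a per-feature
weight |t_f| from a pooled-variance two-sample t-test; a test sample is
assigned to the class whose prototype is nearer in the weighted Manhattan
distance.  Its decision value is the (signed) difference of the two
weighted distances.

The SVM is a soft-margin RBF-kernel support vector machine (libsvm via
scikit-learn); only the cost parameter C is tuned, on the grid
C = 2^x, x = -5..10 (16 candidates), with the kernel width fixed at
gamma = 1/n_features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

#: cost-parameter grid for the SVM: 2^x, x = -5..10
C_GRID: tuple[float, ...] = tuple(float(2.0**x) for x in range(-5, 11))


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    classes = np.unique(y)
    if not np.array_equal(classes, [-1.0, 1.0]):
        raise ValueError(f"labels must contain both classes -1 and +1, got {classes}")
    return y


# ---------------------------------------------------------------------------
# WeiRD

@dataclass
class WeirdModel:
    """Class centroids plus per-feature |t| weights for one modality."""

    centroid_control: np.ndarray
    centroid_patient: np.ndarray
    weight: np.ndarray  # |t| per feature, >= 0; degenerate t set to 0


def pooled_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t statistic per feature (patient − control).

    Features with zero pooled variance get t = 0: a feature constant within
    both classes carries no evidence and must not vote.
    """
    ctr, pat = X[y < 0], X[y > 0]
    n0, n1 = len(ctr), len(pat)
    m0, m1 = ctr.mean(axis=0), pat.mean(axis=0)
    ss0 = ((ctr - m0) ** 2).sum(axis=0)
    ss1 = ((pat - m1) ** 2).sum(axis=0)
    sp2 = (ss0 + ss1) / (n0 + n1 - 2)
    denom = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m0) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def fit_weird(X: np.ndarray, y: np.ndarray) -> WeirdModel:
    X = np.asarray(X, dtype=np.float64)
    y = _check_two_classes(y)
    if (y < 0).sum() < 2 or (y > 0).sum() < 2:
        raise ValueError("WeiRD needs at least 2 training subjects per class")
    return WeirdModel(
        centroid_control=X[y < 0].mean(axis=0),
        centroid_patient=X[y > 0].mean(axis=0),
        weight=np.abs(pooled_t(X, y)),
    )


def weird_decision_values(model: WeirdModel, X: np.ndarray) -> np.ndarray:
    """Signed decision values for each row of X.

    d = sum_f w_f * (|x_f − c_control,f| − |x_f − c_patient,f|): positive when
    the sample is nearer (weighted Manhattan) to the patient prototype.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    contrib = np.abs(X - model.centroid_control) - np.abs(X - model.centroid_patient)
    return contrib @ model.weight


def weird_decision(model: WeirdModel, x: np.ndarray) -> float:
    """Decision value for a single feature vector."""
    return float(weird_decision_values(model, np.asarray(x).reshape(1, -1))[0])


def weird_votes(model: WeirdModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature importance: mean class-aligned signed vote.

    Each feature's vote for a sample is its weighted contribution to the
    decision value, signed so that a contribution pointing towards the
    sample's true class is positive; importances are the votes averaged
    over samples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    contrib = np.abs(X - model.centroid_control) - np.abs(X - model.centroid_patient)
    return (y[:, None] * contrib * model.weight).mean(axis=0)


# ---------------------------------------------------------------------------
# SVM

@dataclass
class SvmSpec:
    """RBF-kernel SVM hyperparameters: cost C from the 16-value grid, fixed gamma."""

    C: float = 1.0
    gamma: float | None = None  # None -> 1/n_features

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class FittedSvm:
    """Fitted RBF SVM plus the training gamma actually used."""

    svc: SVC
    gamma: float
    spec: SvmSpec = field(default_factory=SvmSpec)


def fit_svm(X: np.ndarray, y: np.ndarray, spec: SvmSpec | None = None) -> FittedSvm:
    X = np.asarray(X, dtype=np.float64)
    y = _check_two_classes(y)
    spec = spec or SvmSpec()
    gamma = spec.gamma if spec.gamma is not None else 1.0 / X.shape[1]
    svc = SVC(kernel="rbf", C=spec.C, gamma=gamma)
    svc.fit(X, y)
    return FittedSvm(svc, gamma, spec)


def svm_decision_values(model: FittedSvm, X: np.ndarray) -> np.ndarray:
    """Signed decision values; positive = patient (+1 class) side of the margin."""
    return model.svc.decision_function(np.atleast_2d(np.asarray(X, dtype=np.float64)))


def svm_importance(model: FittedSvm) -> np.ndarray:
    """Descriptive per-feature importance from the dual solution.

    Sum_i alpha_i y_i sv_i maps the hyperplane normal back into input space.
    With an RBF kernel the feature space is not the input space, so this is
    an approximation useful for descriptive ranking only.
    """
    return (model.svc.dual_coef_ @ model.svc.support_vectors_).ravel()
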