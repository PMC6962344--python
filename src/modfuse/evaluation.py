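"""Leave-one-out evaluation driver and metric suite.

Metrics follow the diagnostic-classification conventions: patient is the
positive class; performance is reported as balanced accuracy (mean of
sensitivity and specificity, chance level 0.5 regardless of class
imbalance), with a Bayesian posterior for significance: sensitivity and
specificity get independent Beta(k+1, n−k+1) posteriors from their
confusion counts, the balanced-accuracy posterior is the distribution of
their mean (computed by numerical convolution on a fixed grid), the
p-value is the posterior probability that balanced accuracy ≤ 0.5, and the
interval is the central 95% of the posterior.

Inter-modality agreement of LOO predictions is quantified by Cohen's
kappa; modality importance by re-running the whole evaluation with each
modality left out once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from modfuse.ensemble import (
    EnsembleConfig,
    _preprocess_fit,
    fit_ensemble,
    predict_subject,
)
from modfuse.panel_io import PATIENT, ModalityPanel

logger = logging.getLogger(__name__)

POSTERIOR_GRID_SIZE = 4096


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts with patient as the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_patients(self) -> int:
        return self.TP + self.FN

    @property
    def n_controls(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class EvaluationReport:
    counts: ConfusionCounts
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    p_value: float
    interval: tuple[float, float]


def balanced_accuracy(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(balanced accuracy, sensitivity, specificity) from confusion counts."""
    if counts.n_patients == 0 or counts.n_controls == 0:
        raise ValueError("balanced accuracy needs evaluated subjects in both classes")
    sens = counts.TP / counts.n_patients
    spec = counts.TN / counts.n_controls
    return (sens + spec) / 2.0, sens, spec


def _posterior_grid(counts: ConfusionCounts) -> tuple[np.ndarray, np.ndarray, float]:
    """Density of (sens + spec)/2 on a uniform grid by discrete convolution."""
    n = POSTERIOR_GRID_SIZE
    x = np.linspace(0.0, 1.0, n)
    dx = x[1] - x[0]
    pdf_sens = stats.beta.pdf(x, counts.TP + 1, counts.FN + 1)
    pdf_spec = stats.beta.pdf(x, counts.TN + 1, counts.FP + 1)
    conv = np.convolve(pdf_sens, pdf_spec)  # density of the sum on [0, 2]
    mass = conv.sum()
    if not np.isfinite(mass) or mass <= 0:
        raise ValueError("degenerate posterior")
    conv /= mass
    balacc_grid = np.linspace(0.0, 2.0, 2 * n - 1) / 2.0
    return balacc_grid, conv, dx


def balacc_posterior(counts: ConfusionCounts) -> tuple[float, tuple[float, float]]:
    """Posterior p-value P(balanced accuracy ≤ 0.5) and central 95% interval."""
    grid, mass, _ = _posterior_grid(counts)
    cdf = np.cumsum(mass)
    p_value = float(np.interp(0.5, grid, cdf))
    lo = float(grid[np.searchsorted(cdf, 0.025)])
    hi = float(grid[np.searchsorted(cdf, 0.975)])
    return p_value, (lo, hi)


def balacc_posterior_mc(
    counts: ConfusionCounts, n_draws: int = 1_000_000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo cross-check of :func:`balacc_posterior`."""
    rng = np.random.default_rng(seed)
    sens = rng.beta(counts.TP + 1, counts.FN + 1, size=n_draws)
    spec = rng.beta(counts.TN + 1, counts.FP + 1, size=n_draws)
    bal = (sens + spec) / 2.0
    lo, hi = np.quantile(bal, [0.025, 0.975])
    return float((bal <= 0.5).mean()), (float(lo), float(hi))


def make_report(counts: ConfusionCounts) -> EvaluationReport:
    bal, sens, spec = balanced_accuracy(counts)
    p, interval = balacc_posterior(counts)
    return EvaluationReport(counts, bal, sens, spec, p, interval)


# ---------------------------------------------------------------------------
# Cohen's kappa

def cohens_kappa(pred_a: np.ndarray, pred_b: np.ndarray) -> float:
    """Chance-corrected agreement of two paired binary prediction vectors.

    κ = (p_o − p_e) / (1 − p_e) with p_e the marginal-product chance
    agreement.  If both raters are constant and identical (p_e = 1) the
    agreement is perfect and κ is defined as 1.
    """
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("kappa needs two equal-length non-empty vectors")
    classes = np.unique(np.concatenate([a, b]))
    p_o = float((a == b).mean())
    p_e = float(sum((a == c).mean() * (b == c).mean() for c in classes))
    if p_e >= 1.0 - 1e-15:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_matrix(predictions: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Cohen's kappa between modality prediction columns.

    ``predictions`` holds one column per modality (NaN where the modality is
    missing for a subject); each pair is scored on subjects where both are
    available.  The matrix is symmetric with unit diagonal.
    """
    mods = list(predictions.columns)
    out = pd.DataFrame(np.eye(len(mods)), index=mods, columns=mods)
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            both = predictions[[a, b]].dropna()
            if len(both) == 0:
                raise ValueError(f"no overlapping subjects for modalities {a!r}, {b!r}")
            k = cohens_kappa(both[a].to_numpy(), both[b].to_numpy())
            out.loc[a, b] = out.loc[b, a] = k
    return out


# ---------------------------------------------------------------------------
# leave-one-out driver

def _fold_seed(master_seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([int(master_seed), int(fold)]).generate_state(1)[0] % (2**31))


def _global_preproc(panel: ModalityPanel, config: EnsembleConfig) -> dict:
    """Preprocessing fit once on the whole panel (the leakage-prone variant)."""
    return {
        m: _preprocess_fit(panel.tables[m], panel.covariates, panel.tables[m].subject_ids,
                           config.residualize)
        for m in panel.modalities
    }


def loocv(
    panel: ModalityPanel,
    config: EnsembleConfig | None = None,
) -> tuple[pd.DataFrame, EvaluationReport]:
    """Leave-one-out evaluation of the multimodal scheme.

    In each fold all modalities of one subject are held out; preprocessing,
    classifier selection, C tuning and weight optimization are re-run on the
    remaining subjects, and the held-out subject is predicted once.  Returns
    one record per subject (per-modality decision values ``d_<modality>``,
    both fused sums, predicted and true class) plus the report under the
    configured fusion mode.  Deterministic given ``config.seed``.
    """
    config = config or EnsembleConfig()
    y_all = panel.y()
    if (y_all < 0).sum() < 2 or (y_all > 0).sum() < 2:
        raise ValueError("leave-one-out evaluation needs at least 2 subjects per class")
    preproc = _global_preproc(panel, config) if config.global_preproc else None

    rows = []
    for i, subject in enumerate(panel.subjects):
        train = panel.drop_subjects([subject])
        model = fit_ensemble(train, config, seed=_fold_seed(config.seed, i),
                             preproc_override=preproc)
        rec = predict_subject(model, panel, subject)
        row = {
            "subject_id": subject,
            "true": panel.labels.loc[subject],
            "predicted": rec.predicted,
            "weighted_sum": rec.weighted_sum,
            "weighted_sum_binary": rec.weighted_sum_binary,
        }
        for m in panel.modalities:
            row[f"d_{m}"] = rec.decision_values.get(m, np.nan)
        rows.append(row)
    records = pd.DataFrame(rows)
    return records, report_from_records(records, fusion=config.fusion)


def counts_from_records(records: pd.DataFrame, fusion: str = "decision") -> ConfusionCounts:
    col = "weighted_sum" if fusion == "decision" else "weighted_sum_binary"
    pred_patient = records[col].to_numpy() > 0
    true_patient = (records["true"] == PATIENT).to_numpy()
    return ConfusionCounts(
        TP=int((pred_patient & true_patient).sum()),
        FN=int((~pred_patient & true_patient).sum()),
        TN=int((~pred_patient & ~true_patient).sum()),
        FP=int((pred_patient & ~true_patient).sum()),
    )


def report_from_records(records: pd.DataFrame, fusion: str = "decision") -> EvaluationReport:
    return make_report(counts_from_records(records, fusion))


# ---------------------------------------------------------------------------
# unimodal analysis

def single_modality_panel(panel: ModalityPanel, modality: str) -> ModalityPanel:
    table = panel.tables[modality]
    subj = table.subject_ids
    cov = panel.covariates.loc[subj] if panel.covariates is not None else None
    return ModalityPanel({modality: table}, panel.labels.loc[subj], cov)


def unimodal_loocv(
    panel: ModalityPanel,
    modality: str,
    classifier: str,
    config: EnsembleConfig | None = None,
) -> tuple[pd.DataFrame, EvaluationReport]:
    """LOO evaluation of one modality with one forced classifier type."""
    config = config or EnsembleConfig()
    config = replace(config, classifier=classifier, weights="uniform", fusion="decision")
    return loocv(single_modality_panel(panel, modality), config)


def unimodal_table(
    panel: ModalityPanel,
    config: EnsembleConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-modality LOO performance of both classifiers, plus best predictions.

    Returns a table with one row per (modality, classifier) and a frame of
    each modality's predictions under its better classifier (ties to WeiRD),
    suitable for :func:`kappa_matrix`.
    """
    config = config or EnsembleConfig()
    rows = []
    best_preds: dict[str, pd.Series] = {}
    for m in panel.modalities:
        reports = {}
        preds = {}
        for clf in ("svm", "weird"):
            records, report = unimodal_loocv(panel, m, clf, config)
            reports[clf] = report
            preds[clf] = pd.Series(
                np.where(records["weighted_sum"].to_numpy() > 0, 1.0, -1.0),
                index=records["subject_id"],
            )
            rows.append({
                "modality": m,
                "classifier": clf,
                "balanced_accuracy": report.balanced_accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "p_value": report.p_value,
            })
        best = "weird" if reports["weird"].balanced_accuracy >= reports["svm"].balanced_accuracy else "svm"
        best_preds[m] = preds[best]
    table = pd.DataFrame(rows).set_index(["modality", "classifier"])
    pred_frame = pd.DataFrame(best_preds).reindex(panel.subjects)
    return table, pred_frame


# ---------------------------------------------------------------------------
# ablation grid and modality knock-out

def ablation_grid(panel: ModalityPanel, config: EnsembleConfig | None = None) -> pd.DataFrame:
    """Balanced accuracy for every (classifier × weights × fusion) cell.

    All 3 × 2 × 2 = 12 cells share the fold structure and seed; the two
    fusion modes of a (classifier, weights) pair are computed from the same
    fitted folds, so the grid isolates the effect of each design choice.
    """
    config = config or EnsembleConfig()
    rows = []
    for clf in ("svm", "weird", "optimized"):
        for weights in ("uniform", "optimized"):
            cfg = replace(config, classifier=clf, weights=weights, fusion="decision")
            records, _ = loocv(panel, cfg)
            for fusion in ("decision", "binary"):
                report = report_from_records(records, fusion)
                rows.append({
                    "classifier": clf,
                    "weights": weights,
                    "fusion": fusion,
                    "balanced_accuracy": report.balanced_accuracy,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                    "p_value": report.p_value,
                    "interval_low": report.interval[0],
                    "interval_high": report.interval[1],
                })
    return pd.DataFrame(rows)


def leave_one_modality_out(
    panel: ModalityPanel,
    config: EnsembleConfig | None = None,
) -> pd.DataFrame:
    """Δ-table: full-model LOO vs LOO with each modality excluded once."""
    config = config or EnsembleConfig()
    if len(panel.modalities) < 2:
        raise ValueError("leave-one-modality-out needs at least 2 modalities")
    _, full = loocv(panel, config)
    rows = []
    for m in panel.modalities:
        _, rep = loocv(panel.drop_modality(m), config)
        rows.append({
            "excluded": m,
            "balanced_accuracy": rep.balanced_accuracy,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "delta_balanced_accuracy": rep.balanced_accuracy - full.balanced_accuracy,
            "delta_sensitivity": rep.sensitivity - full.sensitivity,
            "delta_specificity": rep.specificity - full.specificity,
        })
    return pd.DataFrame(rows).set_index("excluded")
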