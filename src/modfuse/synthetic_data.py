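"""Synthetic multimodal cohort generator.

Emulates the statistical structure the fusion framework assumes: several
modalities of very different dimensionality, class effects of varying
strength, controllable cross-modality redundancy, per-modality missing
subjects and linear nuisance-covariate contamination.

The construction uses one latent class-signal expression per subject and
modality: a common standard-normal subject factor ``g`` is mixed with a
modality-specific factor at weight sqrt(ρ), so ``ρ`` is exactly the
cross-modality correlation of the latent signals — the single knob that
controls how redundant the modalities are.  Each informative feature of a
modality is unit-variance Gaussian noise plus the class sign times
``(d/2) · s``, where the subject's signal expression ``s = 1 + λ·latent``
modulates effect strength around its mean: the between-class mean
difference is ``d`` in units of the noise standard deviation.  With
``certainty_calibration`` enabled (λ > 0) subjects vary in how strongly
they express the class signal, coherently across the informative features,
so classifier decision-value magnitudes genuinely track correctness — the
regime in which continuous fusion should beat binary voting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from modfuse.panel_io import CONTROL, PATIENT, FeatureTable, ModalityPanel, build_panel


@dataclass(frozen=True)
class ModalityBlock:
    """Spec for one synthetic modality."""

    name: str
    n_features: int
    n_informative: int
    effect_size: float = 0.0        # standardized between-class mean shift d
    missing_rate: float = 0.0       # MCAR per-subject dropout probability
    #: exact (n_control, n_patient) to drop instead of a rate, or None
    missing_counts: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError(
                f"modality {self.name!r}: n_informative ({self.n_informative}) "
                f"exceeds n_features ({self.n_features})"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class CovariateEffects:
    """Per-covariate contamination strength (sd of per-feature loadings)."""

    age: float = 0.0
    gender: float = 0.0
    site: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    n_control: int
    n_patient: int
    blocks: tuple[ModalityBlock, ...]
    redundancy: float = 0.0          # ρ: cross-modality latent correlation
    latent_sd: float = 0.5           # λ: sd of per-subject signal expression
    certainty_calibration: bool = True
    covariate_effects: CovariateEffects | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_patient <= 0:
            raise ValueError("subject counts must be positive")
        if not 0.0 <= self.redundancy <= 1.0:
            raise ValueError("redundancy must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generator bookkeeping consistent with the emitted panel."""

    latent: pd.DataFrame             # subjects x modalities latent signal
    expression: pd.DataFrame         # subjects x modalities signal expression s
    informative: dict[str, list[str]]
    missing: dict[str, list[str]]    # subjects dropped per modality


def _draw_missing(
    rng: np.random.Generator,
    block: ModalityBlock,
    controls: list[str],
    patients: list[str],
    protected: dict[str, int],
) -> list[str]:
    """Subjects to drop for one modality, honouring panel invariants.

    A subject whose remaining modality count (tracked in ``protected``) is 1
    is never dropped, so every subject keeps at least one modality; at least
    2 subjects per class are always retained.
    """
    dropped: list[str] = []
    for cls_subjects, n_exact in zip((controls, patients),
                                     block.missing_counts or (None, None)):
        droppable = [s for s in cls_subjects if protected[s] > 1]
        if n_exact is not None:
            k = min(n_exact, len(droppable), len(cls_subjects) - 2)
            chosen = list(rng.choice(droppable, size=k, replace=False)) if k else []
        else:
            flips = rng.random(len(droppable)) < block.missing_rate
            chosen = [s for s, f in zip(droppable, flips) if f]
            chosen = chosen[: max(0, len(cls_subjects) - 2)]
        dropped.extend(chosen)
    for s in dropped:
        protected[s] -= 1
    return dropped


def generate_panel(spec: SyntheticSpec) -> tuple[ModalityPanel, SyntheticTruth]:
    """Draw a reproducible multimodal cohort from the spec."""
    rng = np.random.default_rng(spec.seed)
    controls = [f"c{i:04d}" for i in range(spec.n_control)]
    patients = [f"p{i:04d}" for i in range(spec.n_patient)]
    subjects = controls + patients
    n = len(subjects)
    y = np.array([-1.0] * spec.n_control + [1.0] * spec.n_patient)

    # covariates are drawn (and attached to the panel) only when they are
    # asked to contaminate features; a covariate-free panel skips
    # residualization entirely
    covariates = None if spec.covariate_effects is None else pd.DataFrame(
        {
            "age": rng.normal(45.0, 10.0, size=n).round(1),
            "gender": rng.choice(["m", "f"], size=n),
            "site": rng.choice(["A", "B"], size=n),
        },
        index=subjects,
    )

    # latent signal: common factor mixed at weight sqrt(ρ)
    g = rng.standard_normal(n)
    sqrt_rho = np.sqrt(spec.redundancy)
    lam = spec.latent_sd if spec.certainty_calibration else 0.0
    # master noise pool: at ρ = 1 modalities share not only the latent
    # signal but the entire noise realization of their feature blocks, so
    # equal-shaped blocks become literal duplicates and their predictions
    # coincide — redundancy at the prediction level, not just in the signal
    max_features = max((b.n_features for b in spec.blocks), default=0)
    noise_pool = rng.standard_normal((n, max_features))

    tables: dict[str, FeatureTable] = {}
    latent_cols: dict[str, np.ndarray] = {}
    expr_cols: dict[str, np.ndarray] = {}
    informative: dict[str, list[str]] = {}
    missing: dict[str, list[str]] = {}
    protected = {s: len(spec.blocks) for s in subjects}

    for block in spec.blocks:
        e = rng.standard_normal(n)
        latent = sqrt_rho * g + np.sqrt(1.0 - spec.redundancy) * e
        expression = 1.0 + lam * latent
        nf = block.n_features
        X = (
            sqrt_rho * noise_pool[:, :nf]
            + np.sqrt(1.0 - spec.redundancy) * rng.standard_normal((n, nf))
        )
        feat_ids = [f"{block.name}_f{j:04d}" for j in range(nf)]
        info_idx = np.arange(block.n_informative)
        X[:, info_idx] += (y * (block.effect_size / 2.0) * expression)[:, None]

        if spec.covariate_effects is not None:
            ce = spec.covariate_effects
            age_c = (covariates["age"].to_numpy() - 45.0) / 10.0
            gender_c = (covariates["gender"] == "m").to_numpy(float) - 0.5
            site_c = (covariates["site"] == "B").to_numpy(float) - 0.5
            for strength, cov in ((ce.age, age_c), (ce.gender, gender_c), (ce.site, site_c)):
                if strength > 0:
                    loadings = rng.normal(0.0, strength, size=block.n_features)
                    X += np.outer(cov, loadings)

        dropped = _draw_missing(rng, block, controls, patients, protected)
        keep = [s for s in subjects if s not in set(dropped)]
        df = pd.DataFrame(X, index=subjects, columns=feat_ids).loc[keep]
        tables[block.name] = FeatureTable(block.name, df)
        latent_cols[block.name] = latent
        expr_cols[block.name] = expression
        informative[block.name] = [feat_ids[j] for j in info_idx]
        missing[block.name] = sorted(dropped)

    labels = pd.Series([CONTROL] * spec.n_control + [PATIENT] * spec.n_patient,
                       index=subjects)
    panel = build_panel(tables, labels, covariates)
    truth = SyntheticTruth(
        latent=pd.DataFrame(latent_cols, index=subjects),
        expression=pd.DataFrame(expr_cols, index=subjects),
        informative=informative,
        missing=missing,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# presets

def _five_blocks(d: tuple[float, ...], missing_rate: float = 0.0) -> tuple[ModalityBlock, ...]:
    shapes = [("m1", 30, 8), ("m2", 12, 4), ("m3", 60, 10), ("m4", 100, 12), ("m5", 30, 6)]
    return tuple(
        ModalityBlock(name, nf, ni, effect_size=di, missing_rate=missing_rate)
        for (name, nf, ni), di in zip(shapes, d)
    )


def preset(name: str, seed: int = 0, n_scale: float = 1.0) -> SyntheticSpec:
    """Documented study scenarios.

    - ``null``: five modalities, no class effect anywhere (d = 0) — the
      calibration scenario in which any classifier must sit at chance.
    - ``complementary``: five modestly informative modalities with low
      cross-modality redundancy (ρ = 0.2) and certainty calibration — the
      regime in which weighted continuous fusion should help.
    - ``redundant``: five exchangeable duplicate blocks with ρ = 1 — the
      modalities share both the class signal and the informative-feature
      noise, so their predictions all but coincide and fusion is predicted
      to give no benefit.
    - ``single_informative``: one informative modality among four pure-noise
      ones — the weight search should favour it and knocking it out should
      hurt most.
    - ``lead_like``: mirrors a five-modality alcohol-dependence cohort:
      feature counts 110/11/358/1461/110, 97 controls / 119 patients with
      per-modality availability (97/119, 97/119, 96/119, 74/80, 84/93), a
      dominant structural modality, moderate redundancy and covariate
      contamination.  ``n_scale`` shrinks the cohort (and the exact missing
      counts) proportionally for faster runs.
    """
    if name == "null":
        return SyntheticSpec(30, 30, _five_blocks((0.0,) * 5), redundancy=0.2, seed=seed)
    if name == "complementary":
        return SyntheticSpec(
            60, 60, _five_blocks((0.45, 0.55, 0.35, 0.30, 0.40)),
            redundancy=0.2, latent_sd=0.6, certainty_calibration=True, seed=seed,
        )
    if name == "redundant":
        # five exchangeable copies of one block: full redundancy means the
        # modalities are duplicates of the same information source
        blocks = tuple(
            ModalityBlock(f"m{i + 1}", 30, 8, effect_size=0.40) for i in range(5)
        )
        return SyntheticSpec(
            60, 60, blocks,
            redundancy=1.0, latent_sd=0.6, certainty_calibration=True, seed=seed,
        )
    if name == "single_informative":
        return SyntheticSpec(30, 30, _five_blocks((0.6, 0.0, 0.0, 0.0, 0.0)),
                             redundancy=0.2, seed=seed)
    if name == "lead_like":
        def s(k: int) -> int:
            return max(2, round(k * n_scale))

        n_ctr, n_pat = s(97), s(119)
        blocks = (
            ModalityBlock("gmd", 110, 16, 0.50, missing_counts=(0, 0)),
            ModalityBlock("csf", 11, 4, 0.55, missing_counts=(0, 0)),
            ModalityBlock("cth", 358, 24, 0.28, missing_counts=(s(97) - s(96), 0)),
            ModalityBlock("rwr", 1461, 30, 0.22,
                          missing_counts=(n_ctr - s(74), n_pat - s(80))),
            ModalityBlock("nac", 110, 10, 0.25,
                          missing_counts=(n_ctr - s(84), n_pat - s(93))),
        )
        return SyntheticSpec(
            n_ctr, n_pat, blocks, redundancy=0.25, latent_sd=0.6,
            certainty_calibration=True,
            covariate_effects=CovariateEffects(age=0.1, gender=0.05, site=0.1),
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")
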