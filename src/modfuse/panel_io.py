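"""Feature-table and cohort-panel I/O.

A *modality* is one source of per-subject features (e.g. grey-matter
density, cortical thickness), stored as a delimited text table with one row
per subject and one column per feature.  A :class:`ModalityPanel` bundles
several such tables with diagnostic labels, optional nuisance covariates
(age, gender, site) and a boolean availability mask: a subject is available
for a modality iff it has a row in that modality's table.  Missingness is
modelled only at whole-(subject, modality) granularity — tables must not
contain missing cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CONTROL = "control"
PATIENT = "patient"

#: sign convention: negative decision values mean control, positive patient
LABEL_SIGN = {CONTROL: -1, PATIENT: +1}


@dataclass(frozen=True)
class FeatureTable:
    """A validated subjects x features matrix for one modality."""

    name: str
    data: pd.DataFrame  # index: subject ids, columns: feature ids, float64

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if len(idx) == 0 or len(cols) == 0:
            raise ValueError(f"modality {self.name!r}: empty feature table")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"modality {self.name!r}: duplicate subject id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"modality {self.name!r}: duplicate feature id {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"modality {self.name!r}: non-numeric cells present")
        if not np.isfinite(values).all():
            raise ValueError(
                f"modality {self.name!r}: non-finite values; missing subjects must be "
                "expressed by absent rows, not sentinel cells"
            )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data.index)

    @property
    def n_features(self) -> int:
        return len(self.data.columns)

    def restrict(self, subjects: Sequence[str]) -> "FeatureTable":
        """Keep only the given subjects (those present in this table), in table order."""
        keep = self.data.index.intersection(pd.Index(subjects))
        return FeatureTable(self.name, self.data.loc[keep])


def load_feature_table(path: str | Path, modality_name: str) -> FeatureTable:
    """Read a CSV feature table (first column subject id, header of feature ids)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(np.float64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"modality {modality_name!r}: non-numeric cell in {path}: {exc}") from exc
    return FeatureTable(modality_name, df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "subject_id"
    df.to_csv(path)


def load_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, index_col=0)
    series = df.iloc[:, 0].astype(str).str.lower()
    series.index = series.index.astype(str)
    bad = set(series.unique()) - {CONTROL, PATIENT}
    if bad:
        raise ValueError(f"labels must be 'control'/'patient', found {sorted(bad)}")
    return series


def write_labels(labels: pd.Series, path: str | Path) -> None:
    out = labels.rename("label").rename_axis("subject_id")
    out.to_csv(path)


def load_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    missing = {"age", "gender", "site"} - set(df.columns)
    if missing:
        raise ValueError(f"covariate file lacks columns {sorted(missing)}")
    df["age"] = df["age"].astype(float)
    df["gender"] = df["gender"].astype(str)
    df["site"] = df["site"].astype(str)
    return df[["age", "gender", "site"]]


@dataclass
class ModalityPanel:
    """Aligned multimodal cohort: tables, labels, covariates and availability."""

    tables: dict[str, FeatureTable]
    labels: pd.Series  # index: all retained subjects, values 'control'/'patient'
    covariates: pd.DataFrame | None = None
    availability: pd.DataFrame = field(default=None)  # subjects x modalities, bool

    def __post_init__(self) -> None:
        if self.availability is None:
            self.availability = pd.DataFrame(
                {m: self.labels.index.isin(t.data.index) for m, t in self.tables.items()},
                index=self.labels.index,
            )
        self.validate()

    def validate(self) -> None:
        for m, t in self.tables.items():
            unlabelled = set(t.subject_ids) - set(self.labels.index)
            if unlabelled:
                raise ValueError(f"modality {m!r}: subjects without label: {sorted(unlabelled)[:5]}")
            in_table = self.labels.index.isin(t.data.index)
            if not (self.availability[m].to_numpy() == in_table).all():
                raise ValueError(f"modality {m!r}: availability mask inconsistent with table rows")
        if len(self.tables) and not self.availability.to_numpy().any(axis=1).all():
            orphan = self.availability.index[~self.availability.to_numpy().any(axis=1)]
            raise ValueError(f"subjects with no available modality: {list(orphan)[:5]}")

    # -- introspection ----------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return list(self.labels.index)

    @property
    def modalities(self) -> list[str]:
        return list(self.tables)

    def y(self, subjects: Sequence[str] | None = None) -> np.ndarray:
        """Labels as ±1 (control=-1, patient=+1)."""
        lab = self.labels if subjects is None else self.labels.loc[list(subjects)]
        return lab.map(LABEL_SIGN).to_numpy(dtype=np.float64)

    def available_subjects(self, modality: str) -> list[str]:
        mask = self.availability[modality]
        return list(mask.index[mask])

    def summary(self) -> pd.DataFrame:
        """Per-modality subject/feature counts (N controls, N patients, features)."""
        rows = []
        for m, t in self.tables.items():
            avail = self.labels.loc[self.available_subjects(m)]
            rows.append(
                {
                    "modality": m,
                    "n_control": int((avail == CONTROL).sum()),
                    "n_patient": int((avail == PATIENT).sum()),
                    "n_features": t.n_features,
                }
            )
        return pd.DataFrame(rows).set_index("modality")

    # -- subsetting -------------------------------------------------------

    def subset(self, subjects: Sequence[str]) -> "ModalityPanel":
        """Panel restricted to the given subjects (keeps panel order)."""
        keep = [s for s in self.subjects if s in set(subjects)]
        tables = {m: t.restrict(keep) for m, t in self.tables.items()}
        tables = {m: t for m, t in tables.items() if len(t.data)}
        cov = self.covariates.loc[keep] if self.covariates is not None else None
        return ModalityPanel(tables, self.labels.loc[keep], cov)

    def drop_subjects(self, subjects: Iterable[str]) -> "ModalityPanel":
        drop = set(subjects)
        return self.subset([s for s in self.subjects if s not in drop])

    def drop_modality(self, modality: str) -> "ModalityPanel":
        tables = {m: t for m, t in self.tables.items() if m != modality}
        if not tables:
            raise ValueError("cannot drop the only modality")
        keep = [s for s in self.subjects
                if any(s in t.data.index for t in tables.values())]
        cov = self.covariates.loc[keep] if self.covariates is not None else None
        return ModalityPanel(tables, self.labels.loc[keep], cov)

    def mask_modality(self, modality: str, subjects: Iterable[str]) -> "ModalityPanel":
        """Mark a modality missing for the given subjects by deleting their rows."""
        drop = set(subjects)
        tables = dict(self.tables)
        t = tables[modality]
        keep = [s for s in t.subject_ids if s not in drop]
        if keep:
            tables[modality] = FeatureTable(modality, t.data.loc[keep])
        else:
            del tables[modality]
        retained = [s for s in self.subjects
                    if any(s in tt.data.index for tt in tables.values())]
        cov = self.covariates.loc[retained] if self.covariates is not None else None
        return ModalityPanel(tables, self.labels.loc[retained], cov)

    def equals(self, other: "ModalityPanel") -> bool:
        if self.modalities != other.modalities or self.subjects != other.subjects:
            return False
        if not self.labels.equals(other.labels):
            return False
        for m in self.modalities:
            if not self.tables[m].data.equals(other.tables[m].data):
                return False
        return True


def build_panel(
    tables: Mapping[str, FeatureTable],
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> ModalityPanel:
    """Assemble a panel from in-memory pieces.

    Subjects are the union of table rows, restricted to labelled subjects and
    ordered lexicographically so downstream iteration is deterministic.
    Subjects appearing in a table without a label are dropped (logged);
    subjects with a label but no data are excluded.
    """
    union: set[str] = set()
    for t in tables.values():
        union.update(t.subject_ids)
    unlabelled = union - set(labels.index)
    if unlabelled:
        logger.info("dropping %d subject(s) without labels", len(unlabelled))
    retained = sorted(union & set(labels.index))
    if not retained:
        raise ValueError("no overlap between labelled subjects and feature tables")
    out_tables = {m: t.restrict(retained) for m, t in tables.items()}
    out_tables = {m: FeatureTable(m, t.data.loc[[s for s in retained if s in t.data.index]])
                  for m, t in out_tables.items()}
    cov = None
    if covariates is not None:
        missing_cov = set(retained) - set(covariates.index)
        if missing_cov:
            raise ValueError(f"covariates missing for subjects: {sorted(missing_cov)[:5]}")
        cov = covariates.loc[retained]
    return ModalityPanel(out_tables, labels.loc[retained].copy(), cov)


def load_manifest(path: str | Path) -> dict:
    """Read a JSON or YAML manifest; paths inside are resolved relative to it."""
    path = Path(path)
    text = path.read_text()
    manifest = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not manifest.get("modalities"):
        raise ValueError("manifest lists no modalities")
    base = path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    for entry in manifest["modalities"]:
        entry["path"] = str(_resolve(entry["path"]))
    manifest["labels"] = str(_resolve(manifest["labels"]))
    if manifest.get("covariates"):
        manifest["covariates"] = str(_resolve(manifest["covariates"]))
    return manifest


def assemble_panel(
    manifest: str | Path | Mapping,
    label_path: str | Path | None = None,
    covariate_path: str | Path | None = None,
) -> ModalityPanel:
    """Load and align a panel from a manifest (path or dict).

    The manifest is ``{modalities: [{name, path}, ...], labels: path,
    covariates: path?}``; explicit ``label_path``/``covariate_path`` arguments
    override the manifest entries.
    """
    if isinstance(manifest, (str, Path)):
        manifest = load_manifest(manifest)
    tables = {e["name"]: load_feature_table(e["path"], e["name"]) for e in manifest["modalities"]}
    label_path = label_path or manifest.get("labels")
    if label_path is None:
        raise ValueError("no label file given")
    labels = load_labels(label_path)
    covariate_path = covariate_path or manifest.get("covariates")
    covariates = load_covariates(covariate_path) if covariate_path else None
    return build_panel(tables, labels, covariates)


def write_panel(panel: ModalityPanel, out_dir: str | Path) -> Path:
    """Write a panel as CSVs plus a YAML manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for m, t in panel.tables.items():
        fname = f"{m}.csv"
        write_feature_table(t, out / fname)
        entries.append({"name": m, "path": fname})
    write_labels(panel.labels, out / "labels.csv")
    manifest = {"modalities": entries, "labels": "labels.csv"}
    if panel.covariates is not None:
        cov = panel.covariates.rename_axis("subject_id")
        cov.to_csv(out / "covariates.csv")
        manifest["covariates"] = "covariates.csv"
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
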