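"""Feature-table and label I/O plus subject alignment across views."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import LabeledViews


class TableLoadError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclasses.dataclass
class FeatureTable:
    """Subjects x regions values with ordered unique IDs and region names."""

    subject_ids: list[str]
    region_names: list[str]
    values: np.ndarray  # subjects x regions
    view_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.region_names)):
            raise TableLoadError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.region_names)} regions"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise TableLoadError("duplicate subject IDs")
        if not np.isfinite(self.values).all():
            raise TableLoadError("non-finite values in table")

    def as_block(self) -> np.ndarray:
        """d x n feature block (regions x subjects)."""
        return self.values.T


def read_feature_table(path: str | Path, view_tag: str = "") -> FeatureTable:
    """Read a delimited feature table: first column subject ID, header row
    of region names. Missing, duplicate or non-numeric cells are errors
    that name the offending rows/columns."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise TableLoadError(f"{path}: need a subject-ID column plus at least one region")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TableLoadError(f"{path}: duplicate subject IDs {dupes}")
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        cells = [
            f"(subject {ids[i]}, column {body.columns[j]})"
            for i, j in zip(*np.nonzero(bad.to_numpy()))
        ]
        raise TableLoadError(f"{path}: missing or non-numeric cells at {cells[:10]}")
    return FeatureTable(
        subject_ids=ids,
        region_names=[str(c) for c in body.columns],
        values=numeric.to_numpy(dtype=float),
        view_tag=view_tag,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as CSV with 17-significant-digit floats,
    so that read(write(T)) reproduces T exactly."""
    path = Path(path)
    df = pd.DataFrame(table.values, columns=table.region_names)
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_labels(path: str | Path) -> pd.Series:
    """Labels CSV: subject_id, group. Returns a Series indexed by ID."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise TableLoadError(f"{path}: need subject-ID and group columns")
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise TableLoadError(f"{path}: duplicate subject IDs in labels")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=ids)


def align_views(ct: FeatureTable, cv: FeatureTable, labels: pd.Series) -> tuple[LabeledViews, list[str]]:
    """Align the two views and the labels on identical subject-ID sets.

    Columns are ordered by the CT table's subject order; returns the
    aligned LabeledViews and the subject ID order used.
    """
    ct_ids, cv_ids, lab_ids = set(ct.subject_ids), set(cv.subject_ids), set(labels.index)
    if not (ct_ids == cv_ids == lab_ids):
        missing = sorted((ct_ids | cv_ids | lab_ids) - (ct_ids & cv_ids & lab_ids))
        raise AlignmentError(f"subject sets differ across inputs; unmatched IDs: {missing}")
    if ct.values.shape[1] != cv.values.shape[1]:
        raise AlignmentError(
            f"views disagree on feature count: {ct.values.shape[1]} vs {cv.values.shape[1]}"
        )
    order = ct.subject_ids
    cv_pos = {sid: i for i, sid in enumerate(cv.subject_ids)}
    cv_vals = cv.values[[cv_pos[sid] for sid in order]]
    lab = np.asarray([labels[sid] for sid in order])
    views = LabeledViews(X_CT=ct.values.T, X_CV=cv_vals.T, labels=lab)
    return views, order


def write_biomarkers(ids: list[str], Fea: np.ndarray, path: str | Path) -> Path:
    """Biomarker CSV: subject ID plus one column per subspace dimension."""
    Fea = np.asarray(Fea, dtype=float)
    cols = [f"biomarker_{j + 1}" for j in range(Fea.shape[1])]
    df = pd.DataFrame(Fea, columns=cols)
    df.insert(0, "subject_id", ids)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path
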