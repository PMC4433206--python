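"""Tabular input/output: DI tables, cohort manifests, feature matrices, model archives.

All on-disk formats are delimited text (tab by default; comma is auto-detected
from the header line). DI values are kept at full input precision — binning
happens exactly once, during reconstruction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    ModelFormatError,
    ModelVersionError,
    ValidationError,
)

VALID_LABELS = ("normal", "olk", "oscc", "unknown")

#: Half-open DI intervals of the 16-bin reconstruction, [0, 0.5) ... [7.5, 8.0].
BIN_EDGES = np.arange(0.0, 8.5, 0.5)
BIN_COLUMNS = [
    f"bin_{lo:.1f}_{hi:.1f}" for lo, hi in zip(BIN_EDGES[:-1], BIN_EDGES[1:])
]

MODEL_FORMAT_VERSION = 1


@dataclasses.dataclass
class DICase:
    """One subject's DNA-index measurements: one positive real per cell.

    ``true_components`` carries the generating component index of each cell
    when the case comes from the synthetic simulator; it is ``None`` for
    cases read from disk.
    """

    case_id: str
    di_values: np.ndarray
    label: str | None = None
    true_components: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.di_values = np.asarray(self.di_values, dtype=float)
        if self.di_values.size == 0:
            raise ValidationError(f"case {self.case_id!r}: no DI values")
        if not np.all(np.isfinite(self.di_values)):
            raise ValidationError(f"case {self.case_id!r}: non-finite DI value")
        if np.any(self.di_values <= 0):
            raise ValidationError(f"case {self.case_id!r}: non-positive DI value")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValidationError(
                f"case {self.case_id!r}: unknown label {self.label!r}"
            )

    @property
    def n_cells(self) -> int:
        return int(self.di_values.size)


@dataclasses.dataclass
class FeatureMatrix:
    """Per-case 16-bin feature vectors with case ids and labels."""

    case_ids: list
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(BIN_COLUMNS):
            raise ValidationError(
                f"feature matrix must have {len(BIN_COLUMNS)} columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.case_ids) != self.values.shape[0]:
            raise ValidationError("case_ids length does not match rows")
        if len(self.labels) != self.values.shape[0]:
            raise ValidationError("labels length does not match rows")
        if self.values.size and np.min(self.values) < 0.0001 - 1e-12:
            raise ValidationError("feature values must be >= 0.0001")

    @classmethod
    def from_vectors(cls, vectors: Sequence) -> "FeatureMatrix":
        """Build from objects exposing ``bins``, ``case_id`` and ``label``."""
        return cls(
            case_ids=[v.case_id for v in vectors],
            labels=[v.label for v in vectors],
            values=np.vstack([np.asarray(v.bins, dtype=float) for v in vectors])
            if vectors
            else np.empty((0, 16)),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=BIN_COLUMNS)
        df.insert(0, "case_id", self.case_ids)
        df.insert(1, "label", self.labels)
        return df

    def __len__(self) -> int:
        return self.values.shape[0]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    return ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = _detect_sep(path)
    with open(path) as fh:
        columns = fh.readline().rstrip("\n").split(sep)
    if len(columns) != len(set(columns)):
        raise FormatError(f"{path}: duplicate column in header: {columns}")
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest (case_id, label[, n_cells, seed])."""
    df = _read_table(path)
    if "case_id" not in df.columns or "label" not in df.columns:
        raise FormatError(f"{path}: manifest needs case_id and label columns")
    bad = ~df["label"].astype(str).isin(VALID_LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: unknown label {df['label'].iloc[row]!r} at data row {row}"
        )
    df["case_id"] = df["case_id"].astype(str)
    return df


def read_di_table(
    path: str | Path, manifest_path: str | Path | None = None
) -> list[DICase]:
    """Read a long-format DI table into one :class:`DICase` per case_id.

    The table needs ``case_id`` and ``di`` columns; ``cell_id`` is optional.
    Cell order within each case is preserved. Labels are joined from the
    manifest when one is given.
    """
    df = _read_table(path)
    if "di" not in df.columns:
        raise FormatError(f"{path}: missing required column 'di'")
    if "case_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'case_id'")
    di = pd.to_numeric(df["di"], errors="coerce").to_numpy()
    bad = ~np.isfinite(di) | (di <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{path}: invalid DI value {df['di'].iloc[row]!r} at data row {row}"
        )
    labels: dict[str, str] = {}
    if manifest_path is not None:
        man = read_manifest(manifest_path)
        labels = dict(zip(man["case_id"], man["label"].astype(str)))

    cases = []
    for case_id, sub in df.groupby("case_id", sort=False):
        cases.append(
            DICase(
                case_id=str(case_id),
                di_values=pd.to_numeric(sub["di"]).to_numpy(dtype=float),
                label=labels.get(str(case_id)),
            )
        )
    return cases


def write_di_table(
    cases: Sequence[DICase],
    path: str | Path,
    manifest_path: str | Path | None = None,
    sep: str = "\t",
) -> None:
    """Write cases as a long table (case_id, cell_id, di[, true_component])."""
    frames = []
    for case in cases:
        frame = pd.DataFrame(
            {
                "case_id": case.case_id,
                "cell_id": np.arange(case.n_cells),
                "di": case.di_values,
            }
        )
        if case.true_components is not None:
            frame["true_component"] = case.true_components
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
    if manifest_path is not None:
        write_manifest(cases, manifest_path, sep=sep)


def write_manifest(
    cases: Sequence[DICase], path: str | Path, sep: str = "\t"
) -> None:
    pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "label": [c.label if c.label is not None else "unknown" for c in cases],
            "n_cells": [c.n_cells for c in cases],
            "seed": [c.seed if c.seed is not None else -1 for c in cases],
        }
    ).to_csv(path, sep=sep, index=False)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the 16-bin feature matrix as TSV; round-trips to full precision."""
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = _read_table(path)
    missing = [c for c in ["case_id", "label", *BIN_COLUMNS] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature columns {missing}")
    labels = [None if pd.isna(v) else str(v) for v in df["label"]]
    return FeatureMatrix(
        case_ids=[str(c) for c in df["case_id"]],
        labels=labels,
        values=df[BIN_COLUMNS].to_numpy(dtype=float),
    )


def save_model(model, path: str | Path) -> None:
    """Persist a fitted risk model with a format-version stamp."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "payload": model}, path)


def load_model(path: str | Path):
    try:
        archive = joblib.load(path)
    except Exception as exc:  # noqa: BLE001 - any unpickling failure is fatal
        raise ModelFormatError(f"{path}: not a readable model archive ({exc})") from exc
    if not isinstance(archive, dict) or "format_version" not in archive:
        raise ModelFormatError(f"{path}: missing format_version stamp")
    if archive["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"{path}: format version {archive['format_version']} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    return archive["payload"]
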