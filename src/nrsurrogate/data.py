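"""Tabular data model and CSV I/O.

The universal exchange type is :class:`FeatureTable`: an n x d numeric feature
matrix with ordered feature names, an optional numeric target vector (tensile
stress at 600% strain, MPa) and a per-row provenance tag recording whether a
row came from the original dataset or from one of the two augmentation stages.

Default columns follow the coarse-grained natural-rubber descriptors:
``omega`` (phospholipid + protein total mass fraction), ``eps_h`` and
``eps_nh`` (hydrogen-bond and non-hydrogen-bond interaction strengths,
kcal/mol); target column ``ts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InvalidTableError,
    MissingTargetError,
    NonNumericDataError,
    TableReadError,
)

DEFAULT_FEATURES: tuple[str, ...] = ("omega", "eps_h", "eps_nh")
TARGET_COLUMN = "ts"
PROVENANCE_COLUMN = "provenance"

#: allowed provenance tags, in pipeline order
PROVENANCE_TAGS = ("original", "nni", "smote")


@dataclass
class FeatureTable:
    """n samples x d features, optional target, per-row provenance.

    Parameters
    ----------
    X
        (n, d) float array; no NaN/inf allowed.
    feature_names
        d ordered column identifiers.
    y
        optional length-n target vector (tensile stress, MPa).
    provenance
        length-n array of tags from :data:`PROVENANCE_TAGS`; defaults to all
        ``"original"``.
    """

    X: np.ndarray
    feature_names: tuple[str, ...] = DEFAULT_FEATURES
    y: np.ndarray | None = None
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InvalidTableError(f"X must be 2-D, got shape {self.X.shape}")
        n, d = self.X.shape
        if n < 1 or d < 1:
            raise InvalidTableError(f"need n >= 1 and d >= 1, got {n} x {d}")
        self.feature_names = tuple(str(f) for f in self.feature_names)
        if len(self.feature_names) != d:
            raise InvalidTableError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        if not np.isfinite(self.X).all():
            raise InvalidTableError("X contains NaN or infinite entries")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float).ravel()
            if self.y.shape[0] != n:
                raise InvalidTableError(f"len(y)={self.y.shape[0]} but n={n}")
            if not np.isfinite(self.y).all():
                raise InvalidTableError("y contains NaN or infinite entries")
        if self.provenance is None:
            self.provenance = np.full(n, "original", dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object).ravel()
            if self.provenance.shape[0] != n:
                raise InvalidTableError("provenance length mismatch")
            bad = set(self.provenance) - set(PROVENANCE_TAGS)
            if bad:
                raise InvalidTableError(f"unknown provenance tags: {sorted(bad)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def has_target(self) -> bool:
        return self.y is not None

    def original_mask(self) -> np.ndarray:
        return self.provenance == "original"

    def subset(self, idx) -> "FeatureTable":
        """Row subset (copy); idx is any valid numpy row indexer."""
        idx = np.asarray(idx)
        return FeatureTable(
            X=self.X[idx].copy(),
            feature_names=self.feature_names,
            y=None if self.y is None else self.y[idx].copy(),
            provenance=self.provenance[idx].copy(),
        )

    def copy(self) -> "FeatureTable":
        return self.subset(np.arange(self.n))

    # -- conversions -------------------------------------------------------
    def to_frame(self, include_provenance: bool | None = None) -> pd.DataFrame:
        """As a pandas DataFrame; provenance column included when any row is
        synthetic (or as forced by *include_provenance*)."""
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        if self.y is not None:
            df[TARGET_COLUMN] = self.y
        if include_provenance is None:
            include_provenance = bool((self.provenance != "original").any())
        if include_provenance:
            df[PROVENANCE_COLUMN] = self.provenance
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, has_target: bool = True) -> "FeatureTable":
        df = df.copy()
        provenance = None
        if PROVENANCE_COLUMN in df.columns:
            provenance = df.pop(PROVENANCE_COLUMN).to_numpy(dtype=object)
        y = None
        if has_target:
            if TARGET_COLUMN not in df.columns:
                raise MissingTargetError(
                    f"target column {TARGET_COLUMN!r} not found in "
                    f"{list(df.columns)}"
                )
            y = df.pop(TARGET_COLUMN).to_numpy()
        elif TARGET_COLUMN in df.columns:
            df = df.drop(columns=[TARGET_COLUMN])
        return cls(
            X=df.to_numpy(),
            feature_names=tuple(df.columns),
            y=y,
            provenance=provenance,
        )


def concat_tables(*tables: FeatureTable) -> FeatureTable:
    """Stack tables sharing feature names; targets must be all present or all
    absent."""
    first = tables[0]
    for t in tables[1:]:
        if t.feature_names != first.feature_names:
            raise InvalidTableError("feature name mismatch in concat")
        if t.has_target != first.has_target:
            raise InvalidTableError("mixed target presence in concat")
    return FeatureTable(
        X=np.vstack([t.X for t in tables]),
        feature_names=first.feature_names,
        y=np.concatenate([t.y for t in tables]) if first.has_target else None,
        provenance=np.concatenate([t.provenance for t in tables]),
    )


def read_table(path: str | Path, has_target: bool = True) -> FeatureTable:
    """Read a CSV (comma-separated, '.' decimal, UTF-8, mandatory header).

    Raises
    ------
    TableReadError
        file missing or unreadable.
    NonNumericDataError
        a body cell does not parse as a number.
    MissingTargetError
        *has_target* is set but no ``ts`` column exists.
    """
    path = Path(path)
    if not path.is_file():
        raise TableReadError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except OSError as exc:  # pragma: no cover - unreadable file
        raise TableReadError(str(exc)) from exc
    numeric_cols = [c for c in df.columns if c != PROVENANCE_COLUMN]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise NonNumericDataError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row}"
            )
        if converted.isna().any():
            raise NonNumericDataError(f"missing value in column {col!r}")
        df[col] = converted
    return FeatureTable.from_frame(df, has_target=has_target)


def write_table(table: FeatureTable, path: str | Path) -> None:
    """Write CSV with header; provenance column appears only when any row is
    synthetic."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False)
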