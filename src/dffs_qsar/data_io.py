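"""Descriptor/label table ingestion, activity-unit conversion, descriptor
filtering, min–max normalization, and train/test splitting.

Tables follow the PaDEL-descriptor CSV dialect: one identifier column
(``Name`` by default) and numeric descriptor columns. Labels come in two
schemas: a continuous activity column (``pIC50``, or ``IC50`` plus a unit)
and five binary ADMET columns (Caco-2, CYP3A4, hERG, HOB, MN).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

ADMET_PROPERTIES: tuple[str, ...] = ("Caco-2", "CYP3A4", "hERG", "HOB", "MN")

#: IC50 unit -> multiplier to molar concentration.
_UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6, "M": 1.0}


# ---------------------------------------------------------------------------
# containers


@dataclass
class DescriptorMatrix:
    """Compounds x named numeric descriptors.

    ``values`` is an ``(n, p)`` float array; ``compound_ids`` and
    ``descriptor_names`` are unique and ordered. All entries are finite.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.compound_ids) or p != len(self.descriptor_names):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.compound_ids)} ids x {len(self.descriptor_names)} names"
            )
        _check_unique(self.compound_ids, "compound id")
        _check_unique(self.descriptor_names, "descriptor name")
        if not np.all(np.isfinite(self.values)):
            i, j = map(int, np.argwhere(~np.isfinite(self.values))[0])
            raise ValueError(
                f"non-finite value at compound {self.compound_ids[i]!r}, "
                f"descriptor {self.descriptor_names[j]!r}"
            )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def to_dataframe(self, id_column: str = "Name") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, id_column, self.compound_ids)
        return df

    def subset_descriptors(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Column subset, in the order of ``names``."""
        index = {d: j for j, d in enumerate(self.descriptor_names)}
        missing = [d for d in names if d not in index]
        if missing:
            raise KeyError(f"unknown descriptor name(s): {missing}")
        cols = [index[d] for d in names]
        return DescriptorMatrix(
            list(self.compound_ids), list(names), self.values[:, cols]
        )

    def subset_compounds(self, ids: Sequence[str]) -> "DescriptorMatrix":
        index = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise KeyError(f"unknown compound id(s): {missing[:5]}")
        rows = [index[c] for c in ids]
        return DescriptorMatrix(
            list(ids), list(self.descriptor_names), self.values[rows, :]
        )


@dataclass
class ActivityTable:
    """Continuous activity labels (pIC50 = -log10 of molar IC50)."""

    compound_ids: list[str]
    pic50: np.ndarray

    def __post_init__(self) -> None:
        self.pic50 = np.asarray(self.pic50, dtype=float)
        _check_unique(self.compound_ids, "compound id")
        if self.pic50.shape != (len(self.compound_ids),):
            raise ValueError("pic50 must be one value per compound")
        if not np.all(np.isfinite(self.pic50)):
            raise ValueError("pic50 contains non-finite values")

    def aligned_to(self, ids: Sequence[str]) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.compound_ids)}
        try:
            rows = [index[c] for c in ids]
        except KeyError as exc:
            raise KeyError(f"compound {exc.args[0]!r} missing from activity table")
        return self.pic50[rows]


@dataclass
class ADMETTable:
    """Five binary pharmacokinetic/safety endpoints per compound."""

    compound_ids: list[str]
    labels: np.ndarray  # (n, 5) over {0, 1}
    property_names: tuple[str, ...] = ADMET_PROPERTIES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _check_unique(self.compound_ids, "compound id")
        if tuple(self.property_names) != ADMET_PROPERTIES:
            raise ValueError(f"ADMET properties must be {ADMET_PROPERTIES}")
        if self.labels.shape != (len(self.compound_ids), 5):
            raise ValueError("labels must be (n_compounds, 5)")
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"ADMET value outside {{0,1}} at compound "
                f"{self.compound_ids[i]!r}, property {self.property_names[j]!r}"
            )
        self.labels = self.labels.astype(int)

    def column(self, prop: str) -> np.ndarray:
        return self.labels[:, self.property_names.index(prop)]

    def aligned_to(self, ids: Sequence[str]) -> "ADMETTable":
        index = {c: i for i, c in enumerate(self.compound_ids)}
        rows = [index[c] for c in ids]
        return ADMETTable(list(ids), self.labels[rows, :])


@dataclass
class NormalizationStats:
    """Per-descriptor min/max, fitted on one partition only."""

    descriptor_names: list[str]
    minima: np.ndarray
    maxima: np.ndarray
    fitted_on: str = "train"

    def __post_init__(self) -> None:
        self.minima = np.asarray(self.minima, dtype=float)
        self.maxima = np.asarray(self.maxima, dtype=float)
        if not (len(self.descriptor_names) == self.minima.size == self.maxima.size):
            raise ValueError("stats must cover every descriptor exactly once")
        if np.any(self.maxima < self.minima):
            raise ValueError("max < min in normalization stats")


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/test identifier partition."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    ratio: float = 0.8

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# readers


def _check_unique(items: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            raise ValueError(f"duplicate {what}: {item!r}")
        seen.add(item)


def _numeric_frame(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Coerce all columns to float, reporting the first offending cell."""
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ValueError(
                f"{path}: missing value at row {row + 2}, column {col!r} "
                "(imputation is not performed)"
            )
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric cell {df[col].iloc[row]!r} at "
                f"row {row + 2}, column {col!r}"
            )
        out[col] = coerced.astype(float)
    return pd.DataFrame(out)


def read_descriptor_table(path: str | Path, id_column: str = "Name") -> DescriptorMatrix:
    """Read a PaDEL-dialect descriptor CSV into a :class:`DescriptorMatrix`.

    Column order of the file is preserved; the identifier column is excluded
    from the numeric block. Missing or non-numeric cells are rejected with
    their row/column location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, dtype={0: str} if id_column else None, float_precision="round_trip"
    )
    if df.empty:
        raise ValueError(f"{path}: empty table")
    if id_column not in df.columns:
        raise ValueError(f"{path}: identifier column {id_column!r} not found")
    ids = df[id_column].astype(str).tolist()
    numeric = _numeric_frame(df.drop(columns=[id_column]), path)
    if numeric.shape[1] == 0:
        raise ValueError(f"{path}: no descriptor columns")
    return DescriptorMatrix(ids, list(numeric.columns), numeric.to_numpy())


def read_label_table(
    path: str | Path,
    schema: Literal["activity", "admet"],
    id_column: str = "Name",
    activity_column: str = "pIC50",
) -> ActivityTable | ADMETTable:
    """Read an activity or ADMET label CSV.

    ``schema="activity"`` expects ``activity_column`` (pIC50 values);
    ``schema="admet"`` expects the five canonical property columns with
    entries strictly in {0, 1}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise ValueError(f"{path}: identifier column {id_column!r} not found")
    ids = df[id_column].astype(str).tolist()
    if schema == "activity":
        if activity_column not in df.columns:
            raise ValueError(f"{path}: missing column {activity_column!r}")
        vals = _numeric_frame(df[[activity_column]], path)[activity_column]
        return ActivityTable(ids, vals.to_numpy())
    if schema == "admet":
        missing = [c for c in ADMET_PROPERTIES if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing ADMET column(s) {missing}")
        raw = _numeric_frame(df[list(ADMET_PROPERTIES)], path).to_numpy()
        return ADMETTable(ids, raw)
    raise ValueError(f"unknown schema {schema!r}")


def write_descriptor_table(
    m: DescriptorMatrix, path: str | Path, id_column: str = "Name"
) -> None:
    """Write a descriptor CSV; round-trips finite doubles bit-identically."""
    df = m.to_dataframe(id_column)
    # repr-precision floats survive CSV round-trip exactly
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# transformations


def ic50_to_pic50(ic50_value: float, unit: str = "nM") -> float:
    """Convert an IC50 concentration to pIC50 = -log10(IC50 in molar)."""
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_TO_MOLAR)}")
    if not (ic50_value > 0):
        raise ValueError(f"IC50 must be positive, got {ic50_value}")
    return -math.log10(ic50_value * _UNIT_TO_MOLAR[unit])


def pic50_to_ic50(pic50: float, unit: str = "nM") -> float:
    """Inverse of :func:`ic50_to_pic50` (same unit convention)."""
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown unit {unit!r}")
    return 10.0 ** (-pic50) / _UNIT_TO_MOLAR[unit]


def drop_uninformative_descriptors(
    m: DescriptorMatrix,
    mode: Literal["zero_constant", "zero_variance"] = "zero_constant",
) -> tuple[DescriptorMatrix, list[str]]:
    """Remove descriptors carrying no information.

    ``zero_constant`` removes columns that are identically zero (the
    conservative reading); ``zero_variance`` removes every constant column.
    Returns the surviving matrix (order preserved) and the removed names in
    original column order.
    """
    if mode == "zero_constant":
        drop = np.all(m.values == 0.0, axis=0)
    elif mode == "zero_variance":
        drop = np.ptp(m.values, axis=0) == 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if drop.all():
        raise ValueError("all descriptors are uninformative; degenerate dataset")
    removed = [d for d, flag in zip(m.descriptor_names, drop) if flag]
    kept = [d for d, flag in zip(m.descriptor_names, drop) if not flag]
    return (
        DescriptorMatrix(list(m.compound_ids), kept, m.values[:, ~drop]),
        removed,
    )


def fit_minmax(m: DescriptorMatrix, fitted_on: str = "train") -> NormalizationStats:
    """Fit per-descriptor min/max on one partition (no leakage)."""
    return NormalizationStats(
        list(m.descriptor_names),
        m.values.min(axis=0),
        m.values.max(axis=0),
        fitted_on=fitted_on,
    )


def apply_minmax(m: DescriptorMatrix, stats: NormalizationStats) -> DescriptorMatrix:
    """Scale to (x - min) / (max - min) with the fitted stats.

    Values outside the fitted range are NOT clamped (test rows may leave
    [0, 1]). Descriptors constant on the fitted partition map to 0, with a
    warning.
    """
    index = {d: j for j, d in enumerate(stats.descriptor_names)}
    missing = [d for d in m.descriptor_names if d not in index]
    if missing:
        raise KeyError(f"normalization stats missing descriptor(s): {missing[:5]}")
    cols = [index[d] for d in m.descriptor_names]
    mins = stats.minima[cols]
    span = stats.maxima[cols] - mins
    constant = span == 0.0
    if constant.any():
        names = [d for d, c in zip(m.descriptor_names, constant) if c]
        warnings.warn(
            f"{len(names)} descriptor(s) constant on the fitted partition map "
            f"to 0 after min-max scaling (e.g. {names[0]!r})",
            stacklevel=2,
        )
    safe_span = np.where(constant, 1.0, span)
    scaled = (m.values - mins) / safe_span
    scaled[:, constant] = 0.0
    return DescriptorMatrix(list(m.compound_ids), list(m.descriptor_names), scaled)


def split_train_test(
    ids: Sequence[str], ratio: float = 0.8, seed: int = 0
) -> DatasetSplit:
    """Seeded uniform split with |train| = floor(ratio * n)."""
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = len(ids)
    n_train = int(math.floor(ratio * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"n={n} with ratio={ratio} yields an empty partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = list(ids)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return DatasetSplit(train, test, seed=seed, ratio=ratio)


def write_run_manifest(path: str | Path, **entries) -> None:
    """Write a small JSON manifest (seed, counts, removed descriptors, ...)."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
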