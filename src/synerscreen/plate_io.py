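"""Reading, validation and normalization of viability plate data.

Raw plate readings (e.g. resazurin/Alamar-blue fluorescence) are converted to
surviving fractions relative to vehicle-control wells.  Tables are long-format
pandas DataFrames throughout:

raw readings
    ``compound_id, dose_a_nM, dose_b_nM, replicate, signal`` (+ optional ``plate``)
normalized viability
    ``compound_id, dose_a_nM, dose_b_nM, survival, n_replicates``
tumor measurements
    ``group, day, length_mm, width_mm, height_mm`` (-> ``volume_mm3``)

Drug A is the library compound, drug B the anchor drug (JQ1 in the screen this
package models); a dose of 0 means vehicle for that drug.  All doses are stored
in nM.
"""

from __future__ import annotations

import io
import re
from typing import Iterable

import numpy as np
import pandas as pd

RAW_COLUMNS = ["compound_id", "dose_a_nM", "dose_b_nM", "replicate", "signal"]
VIABILITY_COLUMNS = ["compound_id", "dose_a_nM", "dose_b_nM", "survival", "n_replicates"]
TUMOR_COLUMNS = ["group", "day", "length_mm", "width_mm", "height_mm"]
TUMOR_GROUPS = ("control", "drug_a", "drug_b", "combination")

_DOSE_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(nM|uM|um|nm|µM)?\s*$")


def parse_dose(value) -> float:
    """Parse a dose cell to nM.  Accepts bare numbers (nM) or a 'uM'/'nM' suffix."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        dose = float(value)
    else:
        match = _DOSE_RE.match(str(value))
        if match is None:
            raise ValueError(f"unparseable dose: {value!r}")
        dose = float(match.group(1))
        unit = match.group(2)
        if unit is not None and unit.lower() in ("um", "µm"):
            dose *= 1000.0
    if dose < 0:
        raise ValueError(f"negative dose: {value!r}")
    return dose


def _check_duplicates(df: pd.DataFrame, keys: list[str]) -> None:
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise ValueError(f"duplicate {tuple(keys)} keys at rows {rows}")


def normalize_to_control(readings: pd.DataFrame) -> pd.DataFrame:
    """Convert raw signals to surviving fractions relative to vehicle controls.

    Control wells are those with ``dose_a_nM == 0`` and ``dose_b_nM == 0``.  If a
    ``plate`` column is present, each plate is normalized against its own
    controls; otherwise a single pooled control mean is used.  Per-replicate
    signals are divided by the control mean and then averaged per condition;
    survival is clipped to [0, 1] (signals above control reflect proliferation,
    which the downstream kill statistics do not model).

    Raises
    ------
    ValueError
        If control wells are absent (naming the plate), any signal is negative,
        or replicate keys are duplicated.
    """
    df = readings.copy()
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (df["signal"] < 0).any():
        bad = df.index[df["signal"] < 0].tolist()[:10]
        raise ValueError(f"negative signal at rows {bad}")
    key_cols = ["compound_id", "dose_a_nM", "dose_b_nM", "replicate"]
    group_col = "plate" if "plate" in df.columns else None
    _check_duplicates(df, ([group_col] if group_col else []) + key_cols)

    def _normalize(plate: pd.DataFrame, label) -> pd.DataFrame:
        is_control = (plate["dose_a_nM"] == 0) & (plate["dose_b_nM"] == 0)
        if not is_control.any() or plate.loc[is_control, "signal"].mean() <= 0:
            raise ValueError(f"no usable vehicle-control wells in plate {label!r}")
        control_mean = plate.loc[is_control, "signal"].mean()
        frac = plate["signal"] / control_mean
        out = (
            plate.assign(survival=frac)
            .groupby(["compound_id", "dose_a_nM", "dose_b_nM"], as_index=False)
            .agg(survival=("survival", "mean"), n_replicates=("survival", "size"))
        )
        out["survival"] = out["survival"].clip(0.0, 1.0)
        # vehicle wells define the unit of the survival scale
        ctrl = (out["dose_a_nM"] == 0) & (out["dose_b_nM"] == 0)
        out.loc[ctrl, "survival"] = 1.0
        return out

    if group_col is None:
        return _normalize(df, "<pooled>")
    parts = [_normalize(g, label) for label, g in df.groupby(group_col, sort=True)]
    merged = pd.concat(parts, ignore_index=True)
    return (
        merged.groupby(["compound_id", "dose_a_nM", "dose_b_nM"], as_index=False)
        .agg(survival=("survival", "mean"), n_replicates=("n_replicates", "sum"))
    )


def reduction_percent(survival) -> float | np.ndarray:
    """Percent reduction in viable cells: ``100 * (1 - survival)``."""
    s = np.asarray(survival, dtype=float)
    out = 100.0 * (1.0 - s)
    return float(out) if out.ndim == 0 else out


def tumor_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Caliper tumor volume in mm^3: (length x width x height) / 2."""
    if length_mm <= 0 or width_mm <= 0 or height_mm <= 0:
        raise ValueError("tumor dimensions must be positive")
    return length_mm * width_mm * height_mm / 2.0


def add_tumor_volumes(measurements: pd.DataFrame) -> pd.DataFrame:
    """Validate a tumor-measurement table and append a ``volume_mm3`` column."""
    df = measurements.copy()
    missing = [c for c in TUMOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    dims = df[["length_mm", "width_mm", "height_mm"]].to_numpy(dtype=float)
    if (dims <= 0).any():
        raise ValueError("tumor dimensions must be positive")
    df["volume_mm3"] = dims.prod(axis=1) / 2.0
    return df


def read_viability_table(path_or_buffer) -> pd.DataFrame:
    """Read a long-format viability CSV into the normalized-table layout.

    Doses may carry a ``nM``/``uM`` unit suffix (uM converted x1000).  Unknown
    columns are preserved in ``df.attrs['extra_columns']``.  Raw tables (with a
    ``signal`` column) are returned as raw; run :func:`normalize_to_control`
    afterwards.
    """
    df = pd.read_csv(path_or_buffer, dtype={"compound_id": str})
    for col in ("dose_a_nM", "dose_b_nM"):
        if col not in df.columns:
            raise ValueError(f"missing dose column {col!r}")
        try:
            df[col] = df[col].map(parse_dose)
        except ValueError as err:
            raise ValueError(f"column {col!r}: {err}") from err
    is_raw = "signal" in df.columns
    expected = RAW_COLUMNS if is_raw else VIABILITY_COLUMNS
    extra = [c for c in df.columns if c not in expected and c != "plate"]
    keys = ["compound_id", "dose_a_nM", "dose_b_nM"] + (["replicate"] if is_raw else [])
    if "plate" in df.columns:
        keys = ["plate"] + keys
    _check_duplicates(df, keys)
    out = df[[c for c in df.columns if c not in extra]]
    out.attrs["extra_columns"] = df[extra] if extra else None
    return out


def write_viability_table(records: pd.DataFrame, path_or_buffer) -> None:
    """Write a viability (or raw-reading) table as CSV, doses in nM."""
    records.to_csv(path_or_buffer, index=False)


def read_tumor_table(path_or_buffer) -> pd.DataFrame:
    """Read a tumor-measurement CSV and derive volumes."""
    df = pd.read_csv(path_or_buffer)
    return add_tumor_volumes(df)
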