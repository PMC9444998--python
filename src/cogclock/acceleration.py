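"""Age accelerations and their correlation structure.

A clock's *age acceleration* for a participant is the deviation of the
clock's age from the age expected at that participant's chronological age:
either the plain difference (clock - chronological) or, by default, the
residual from an OLS regression of clock age on chronological age — the
standard convention in the epigenetic-clock literature, which removes any
systematic calibration slope/offset of the clock.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

MODES = ("difference", "residual")


def compute_acceleration(clock_age: Sequence[float], chronological_age: Sequence[float],
                         mode: str = "residual") -> np.ndarray:
    """Per-participant acceleration in years; NaN where clock age is NaN.

    Residual mode fits OLS on the rows where both ages are finite, so the
    finite accelerations have mean zero and zero correlation with
    chronological age.
    """
    if mode not in MODES:
        raise ConfigError(f"unknown acceleration mode {mode!r}; expected {MODES}")
    clock_age = np.asarray(clock_age, dtype=float)
    chrono = np.asarray(chronological_age, dtype=float)
    if clock_age.shape != chrono.shape:
        raise DataError("clock_age and chronological_age are misaligned")
    if mode == "difference":
        return clock_age - chrono

    keep = np.isfinite(clock_age) & np.isfinite(chrono)
    if keep.sum() < 3:
        raise DataError("residual mode requires at least 3 complete pairs")
    if np.std(chrono[keep]) == 0:
        raise DataError("residual mode requires non-constant chronological age")
    slope, intercept = np.polyfit(chrono[keep], clock_age[keep], deg=1)
    out = np.full(clock_age.shape, np.nan)
    out[keep] = clock_age[keep] - (intercept + slope * chrono[keep])
    return out


def build_acceleration_panel(ages: pd.DataFrame, chronological: Sequence[float],
                             mode: str = "residual") -> pd.DataFrame:
    """One acceleration column per clock-age column of ``ages``.

    Each clock is regressed on chronological age using its own complete
    rows (pairwise-complete handling, e.g. for a DNA-methylation subset).
    The mode is recorded in ``DataFrame.attrs["mode"]``.
    """
    chrono = np.asarray(chronological, dtype=float)
    panel = pd.DataFrame(index=ages.index)
    for col in ages.columns:
        panel[col] = compute_acceleration(ages[col].to_numpy(dtype=float), chrono, mode)
    panel.attrs["mode"] = mode
    return panel


def correlation_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the columns.

    Symmetric with unit diagonal; constant columns yield NaN entries.
    """
    if panel.shape[1] < 2:
        raise DataError("correlation_matrix requires at least 2 columns")
    corr = panel.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, np.where(panel.notna().sum() >= 1, 1.0, np.nan))
    constant = [c for c in panel.columns
                if panel[c].dropna().nunique() <= 1 and panel[c].notna().any()]
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    out = panel.copy()
    out["mode"] = panel.attrs.get("mode", "")
    out.to_csv(path, index=True, index_label="id")


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise DataError(f"{path}: acceleration panel requires an 'id' column")
    df = df.set_index("id")
    mode = ""
    if "mode" in df.columns:
        modes = df["mode"].dropna().unique()
        mode = str(modes[0]) if len(modes) else ""
        df = df.drop(columns=["mode"])
    df = df.astype(float)
    df.attrs["mode"] = mode
    return df
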