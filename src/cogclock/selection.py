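"""Age-association screening of cognitive quantifiers.

Each quantifier is tested for zero Pearson correlation with the chosen age
variable via the exact t-transform, p-values are Benjamini-Hochberg
adjusted, and quantifiers are ranked by adjusted p (ties by raw p, then
name). The default significance threshold on adjusted p is 0.001.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError

DEFAULT_ALPHA = 1e-3


def pearson_with_pvalue(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-test p-value.

    p is computed from t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of
    freedom. Degenerate input (constant vector, n < 3) returns (nan, nan)
    rather than raising so callers can flag it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    rho = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, p


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, in the input order.

    adjusted_(i) = min_{j >= i} m * p_(j) / j over the ascending order
    statistics, capped at 1; monotone in the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def select_quantifiers(matrix: pd.DataFrame, age: Sequence[float],
                       alpha: float = DEFAULT_ALPHA,
                       target_name: str = "age") -> pd.DataFrame:
    """Correlation screen of every quantifier column against ``age``.

    Returns one row per quantifier with rho, raw and BH-adjusted p, rank
    (ascending adjusted p, ties by raw p then name; degenerate columns
    after all finite-p columns) and a ``significant`` flag (p_adj < alpha).
    Rows with NA in a column are dropped pairwise for that column.
    """
    age = np.asarray(age, dtype=float)
    if len(matrix) != age.size:
        raise DataError(f"matrix has {len(matrix)} rows but age vector has {age.size}")

    records = []
    for col in matrix.columns:
        v = matrix[col].to_numpy(dtype=float)
        keep = np.isfinite(v) & np.isfinite(age)
        rho, p = pearson_with_pvalue(v[keep], age[keep])
        records.append({"quantifier": col, "rho": rho, "p_raw": p,
                        "degenerate": not np.isfinite(p)})
    df = pd.DataFrame(records)

    finite = ~df["degenerate"]
    df["p_adj"] = np.nan
    if finite.any():
        df.loc[finite, "p_adj"] = benjamini_hochberg(df.loc[finite, "p_raw"].to_numpy())

    # rank: finite first by (p_adj, p_raw, name); degenerate after, by name
    sort_key = df.assign(_deg=df["degenerate"].astype(int)).sort_values(
        ["_deg", "p_adj", "p_raw", "quantifier"], kind="stable")
    df.loc[sort_key.index, "rank"] = np.arange(1, len(df) + 1)
    df["rank"] = df["rank"].astype(int)
    df["significant"] = finite & (df["p_adj"] < alpha)
    df["target"] = target_name
    return df.sort_values("rank").reset_index(drop=True)


def ranked_quantifier_names(selection: pd.DataFrame,
                            restrict_to_significant: bool | None = None,
                            min_significant: int = 5) -> list[str]:
    """Quantifier names in rank order, for top-k clock search.

    By default the list is restricted to significant quantifiers when at
    least ``min_significant`` exist, otherwise all finite-p quantifiers
    are returned in rank order.
    """
    finite = selection[~selection["degenerate"]]
    sig = finite[finite["significant"]]
    if restrict_to_significant is None:
        restrict_to_significant = len(sig) >= min_significant
    chosen = sig if restrict_to_significant else finite
    return list(chosen.sort_values("rank")["quantifier"])


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    Utility for cohort/subset comparability checks (e.g. whether the
    participants with DNA-methylation data are age-representative).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("ks_compare requires two non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def write_selection(selection: pd.DataFrame, path: str | Path) -> None:
    cols = ["quantifier", "rho", "p_raw", "p_adj", "rank", "significant",
            "degenerate", "target"]
    selection[cols].to_csv(path, index=False)


def read_selection(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"quantifier", "rho", "p_raw", "p_adj", "rank", "significant"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: selection table missing columns {sorted(missing)}")
    if "degenerate" not in df.columns:
        df["degenerate"] = ~np.isfinite(df["p_raw"])
    return df
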