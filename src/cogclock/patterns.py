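"""Age-relative performance patterns and their clustering.

Every participant is compared against a Gaussian-age-weighted reference of
peers: for each pattern quantifier, a moving weighted mean and SD are
evaluated at the participant's own age (kernel SD 7 years by default), and
the participant's value is coded ternary — "better", "normal" or "worse" —
depending on whether it deviates from the weighted mean by more than half
the weighted SD in the favourable or unfavourable direction. Time, error
and shade-threshold quantifiers count as better when smaller; count-type
quantifiers as better when larger.

The ternary patterns (encoded +1/0/-1 with better = +1) are clustered by
K-means (default k = 7, groups relabelled A, B, ... by descending mean
"better" count), and each group's mean cognitive age acceleration is
tested against zero with a one-sample two-sided t-test.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .errors import ConfigError, DataError

DEFAULT_KERNEL_SD = 7.0
DEFAULT_THRESHOLD_FACTOR = 0.5
DEFAULT_K = 7

LABEL_TO_CODE = {"better": 1, "normal": 0, "worse": -1}

#: the default pattern quantifiers (mean-statistic columns of the
#: campimetry and sensorimotor indices used for behavioural grouping)
DEFAULT_PATTERN_QUANTIFIERS = (
    "CM dH+ mean", "CM dH- mean", "CM t+ mean", "CM t- mean",
    "SM1 MR mean", "SM1 SMR mean", "SM2 MR mean", "SM2 SMR mean",
)

DEFAULT_DIRECTIONS: dict[str, str] = {q: "lower_is_better"
                                      for q in DEFAULT_PATTERN_QUANTIFIERS}


def gaussian_weighted_stats(values: Sequence[float], ages: Sequence[float],
                            center_age: float, kernel_sd: float = DEFAULT_KERNEL_SD
                            ) -> tuple[float, float]:
    """Gaussian-age-weighted mean and (population-form) SD at ``center_age``.

    w_i = exp(-(age_i - center)^2 / (2 sd^2)); mean = sum(w v)/sum(w);
    SD = sqrt(sum(w (v - mean)^2)/sum(w)).
    """
    if kernel_sd <= 0:
        raise ConfigError("kernel_sd must be > 0")
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape:
        raise DataError("values and ages are misaligned")
    keep = np.isfinite(v) & np.isfinite(a)
    v, a = v[keep], a[keep]
    if v.size < 2:
        raise DataError("gaussian_weighted_stats requires at least 2 peers")
    w = np.exp(-((a - center_age) ** 2) / (2.0 * kernel_sd ** 2))
    total = w.sum()
    if not total > 0:
        raise DataError(f"no peers in age window around {center_age:g} y")
    mean = float(np.dot(w, v) / total)
    sd = float(np.sqrt(np.dot(w, (v - mean) ** 2) / total))
    return mean, sd


def classify_performance(value: float, weighted_mean: float, weighted_sd: float,
                         direction: str,
                         threshold_factor: float = DEFAULT_THRESHOLD_FACTOR) -> str:
    """Ternary label relative to age peers; strict inequalities at the band."""
    if direction not in ("lower_is_better", "higher_is_better"):
        raise ConfigError(f"invalid direction {direction!r}")
    if threshold_factor <= 0:
        raise ConfigError("threshold_factor must be > 0")
    if weighted_sd < 0:
        raise DataError("weighted_sd must be >= 0")
    # degenerate reference: an SD at floating-point noise level counts as zero
    tol = 1e-9 * max(1.0, abs(weighted_mean))
    if weighted_sd <= tol:
        if abs(value - weighted_mean) <= tol:
            return "normal"
        low = value < weighted_mean
    else:
        band = threshold_factor * weighted_sd
        if weighted_mean - band <= value <= weighted_mean + band:
            return "normal"
        low = value < weighted_mean
    if direction == "lower_is_better":
        return "better" if low else "worse"
    return "worse" if low else "better"


def build_pattern_matrix(matrix: pd.DataFrame, ages: Sequence[float],
                         direction_map: Mapping[str, str] | None = None,
                         pattern_quantifiers: Sequence[str] | None = None,
                         kernel_sd: float = DEFAULT_KERNEL_SD,
                         threshold_factor: float = DEFAULT_THRESHOLD_FACTOR
                         ) -> pd.DataFrame:
    """Participants x pattern-quantifiers ternary label matrix.

    Each participant is included in its own reference population (its own
    age carries kernel weight 1), which keeps the moving statistics smooth.
    """
    if pattern_quantifiers is None:
        pattern_quantifiers = [q for q in DEFAULT_PATTERN_QUANTIFIERS
                               if q in matrix.columns]
    if direction_map is None:
        direction_map = DEFAULT_DIRECTIONS
    missing_cols = [q for q in pattern_quantifiers if q not in matrix.columns]
    if missing_cols:
        raise DataError(f"pattern quantifier(s) not in matrix: {missing_cols}")
    missing_dir = [q for q in pattern_quantifiers if q not in direction_map]
    if missing_dir:
        raise DataError(f"no direction configured for quantifier(s): {missing_dir}")

    ages = np.asarray(ages, dtype=float)
    if len(matrix) != ages.size:
        raise DataError("matrix rows and age vector are misaligned")

    out = pd.DataFrame(index=matrix.index, columns=list(pattern_quantifiers),
                       dtype=object)
    for q in pattern_quantifiers:
        v = matrix[q].to_numpy(dtype=float)
        direction = direction_map[q]
        for i in range(ages.size):
            if not np.isfinite(v[i]):
                out.iloc[i, out.columns.get_loc(q)] = "normal"
                continue
            mean, sd = gaussian_weighted_stats(v, ages, ages[i], kernel_sd)
            out.iloc[i, out.columns.get_loc(q)] = classify_performance(
                v[i], mean, sd, direction, threshold_factor)
    return out


def encode_patterns(patterns: pd.DataFrame) -> pd.DataFrame:
    """Map labels to the numeric coding better=+1, normal=0, worse=-1."""
    try:
        return patterns.apply(lambda col: col.map(LABEL_TO_CODE)).astype(int)
    except (TypeError, ValueError) as exc:
        raise DataError(f"pattern matrix contains non-ternary labels: {exc}") from exc


def cluster_patterns(patterns: pd.DataFrame, k: int = DEFAULT_K, seed: int = 0,
                     n_restarts: int = 50) -> pd.Series:
    """K-means grouping of ternary patterns; labels "A", "B", ...

    Euclidean K-means on the +1/0/-1 encoding, best of ``n_restarts``
    initialisations by within-cluster sum of squares. Groups are relabelled
    deterministically in descending order of mean per-member "better"
    count (ties by descending size, then original cluster id).
    """
    codes = encode_patterns(patterns)
    n_distinct = codes.drop_duplicates().shape[0]
    if k > n_distinct:
        raise DataError(f"k={k} exceeds the {n_distinct} distinct pattern(s); "
                        "choose a smaller k")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(codes.to_numpy(dtype=float))

    better_counts = (codes.to_numpy() == 1).sum(axis=1)
    order = sorted(range(k), key=lambda c: (-better_counts[raw == c].mean(),
                                            -(raw == c).sum(), c))
    letters = {c: chr(ord("A") + i) for i, c in enumerate(order)}
    return pd.Series([letters[c] for c in raw], index=patterns.index, name="group")


def test_group_acceleration(accelerations: Sequence[float],
                            labels: Sequence[str]) -> pd.DataFrame:
    """Per-group one-sample two-sided t-test of mean acceleration vs zero.

    Groups with fewer than 2 members or zero variance get NaN t and p.
    Columns: group, n, mean_accel, t, p.
    """
    acc = np.asarray(accelerations, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if acc.shape != labels.shape:
        raise DataError("accelerations and labels are misaligned")
    if np.any(~np.isfinite(acc)):
        raise DataError("every labeled participant needs an acceleration value")

    rows = []
    for g in sorted(set(labels)):
        vals = acc[labels == g]
        t = p = float("nan")
        if vals.size >= 2 and np.std(vals, ddof=1) > 0:
            res = sps.ttest_1samp(vals, popmean=0.0)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"group": g, "n": int(vals.size),
                     "mean_accel": float(vals.mean()), "t": t, "p": p})
    return pd.DataFrame(rows)


def plot_pattern_heatmap(patterns: pd.DataFrame, groups: pd.Series, path: str | Path):
    """Green/white/red heatmap of patterns, rows ordered by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    order = groups.sort_values(kind="stable").index
    codes = encode_patterns(patterns.loc[order])
    cmap = ListedColormap(["#c0392b", "#ffffff", "#27ae60"])  # worse/normal/better
    fig, ax = plt.subplots(figsize=(0.6 * patterns.shape[1] + 2,
                                    0.08 * len(patterns) + 2))
    ax.imshow(codes.to_numpy(), aspect="auto", cmap=cmap, vmin=-1, vmax=1)
    ax.set_xticks(range(patterns.shape[1]))
    ax.set_xticklabels(patterns.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    boundaries = np.flatnonzero(groups.loc[order].to_numpy()[1:]
                                != groups.loc[order].to_numpy()[:-1])
    for b in boundaries:
        ax.axhline(b + 0.5, color="black", lw=0.5)
    ax.set_ylabel("participants (grouped)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
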