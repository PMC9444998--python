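"""Cognitive quantifiers: summary statistics of per-participant index series.

Each cognitive index (a trial series such as stimulus-recognition times, or
a scalar such as an error fraction) is reduced to named summary statistics
("quantifiers"): mean, min, max, SD, median and the first/third quartiles.
The default mapping turns the 16 default indices into 64 quantifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .synthetic import Cohort, IndexSpec

log = logging.getLogger(__name__)

SERIES_STATS = ("mean", "min", "max", "sd", "median", "q1", "q3")
ALL_STATS = SERIES_STATS + ("identity",)


def summarize_series(values: Sequence[float], stats: Iterable[str]) -> dict[str, float]:
    """Compute the requested statistics of one trial series.

    SD uses the unbiased (n-1) denominator, with the convention sd = 0 for a
    single-element series. Quartiles use linear interpolation between order
    statistics. An empty (or all-NaN) series yields NaN for every requested
    statistic rather than raising.
    """
    stats = list(stats)
    for s in stats:
        if s not in ALL_STATS:
            raise ConfigError(f"unknown statistic {s!r}; expected one of {ALL_STATS}")
    arr = np.asarray([v for v in values if not (isinstance(v, float) and np.isnan(v))],
                     dtype=float)
    if arr.size == 0:
        log.warning("empty series: all requested statistics set to NA")
        return {s: float("nan") for s in stats}
    out: dict[str, float] = {}
    for s in stats:
        if s == "mean":
            out[s] = float(np.mean(arr))
        elif s == "min":
            out[s] = float(np.min(arr))
        elif s == "max":
            out[s] = float(np.max(arr))
        elif s == "sd":
            out[s] = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        elif s == "median":
            out[s] = float(np.median(arr))
        elif s == "q1":
            out[s] = float(np.percentile(arr, 25, method="linear"))
        elif s == "q3":
            out[s] = float(np.percentile(arr, 75, method="linear"))
        elif s == "identity":
            if arr.size != 1:
                raise DataError("'identity' requires exactly one value "
                                f"(got a series of length {arr.size})")
            out[s] = float(arr[0])
    return out


@dataclass(frozen=True)
class QuantifierMapping:
    """An ordered list of (index name, statistic) pairs.

    The derived quantifier column name is ``"<index> <stat>"``.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for index, stat in self.entries:
            if stat not in ALL_STATS:
                raise ConfigError(f"mapping entry ({index!r}, {stat!r}): unknown statistic")
            if (index, stat) in seen:
                raise ConfigError(f"duplicate mapping entry ({index!r}, {stat!r})")
            seen.add((index, stat))

    @property
    def column_names(self) -> list[str]:
        return [f"{index} {stat}" for index, stat in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "QuantifierMapping":
        """Read a two-column (index, stat) CSV table."""
        df = pd.read_csv(path)
        if not {"index", "stat"}.issubset(df.columns):
            raise DataError(f"{path}: mapping file requires columns 'index' and 'stat'")
        return cls(tuple((str(r["index"]), str(r["stat"])) for _, r in df.iterrows()))

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["index", "stat"]).to_csv(path, index=False)


def default_mapping(index_specs: Sequence[IndexSpec]) -> QuantifierMapping:
    """Build the shipped default mapping from index specs.

    Full-summary series contribute all seven statistics; "mean" series
    contribute their mean; scalar indices pass through via "identity".
    With the 16 default indices this yields exactly 64 quantifiers.
    """
    entries: list[tuple[str, str]] = []
    for spec in index_specs:
        if spec.summary == "full":
            entries.extend((spec.name, s) for s in SERIES_STATS)
        elif spec.summary == "mean":
            entries.append((spec.name, "mean"))
        else:
            entries.append((spec.name, "identity"))
    return QuantifierMapping(tuple(entries))


def build_quantifier_matrix(cohort: Cohort, mapping: QuantifierMapping) -> pd.DataFrame:
    """Participants x quantifiers matrix (rows in cohort order).

    Raises if the mapping references an index the cohort does not carry.
    """
    available = set(cohort.index_names)
    unknown = sorted({index for index, _ in mapping.entries} - available)
    if unknown:
        raise DataError(f"unknown index name(s) {unknown}; "
                        f"available indices: {sorted(available)}")

    by_index: dict[str, list[str]] = {}
    for index, stat in mapping.entries:
        by_index.setdefault(index, []).append(stat)

    rows = []
    for p in cohort.participants:
        row: dict[str, float] = {}
        for index, stats in by_index.items():
            computed = summarize_series(p.index_series[index], stats)
            for stat in stats:
                row[f"{index} {stat}"] = computed[stat]
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(cohort.ids, name="id"),
                        columns=mapping.column_names)


def write_quantifiers(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index=True)


def read_quantifiers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise DataError(f"{path}: quantifier table requires an 'id' column")
    return df.set_index("id")
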