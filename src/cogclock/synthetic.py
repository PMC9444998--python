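"""Synthetic cohort generator.

Emulates a cohort of volunteers taking three web-based cognitive tests —
campimetry (CM, shade discrimination), an arithmetic-evaluation test (SM1)
and a reversed-letter test (SM2) — together with precomputed biological
ages (Phenotypic Age and four DNA-methylation clocks).

The statistical structure mirrors what the downstream analysis assumes:

* chronological ages uniform on a configured range (default 19-85 y);
* a per-participant latent aging acceleration (years), shared across all
  cognitive indices, drawn Normal(0, ``accel_sd``);
* per-index trial series whose location drifts with *effective* age
  (chronological + latent acceleration), with heteroscedastic and
  optionally bimodal trial noise (a slow-response mixture component);
* error-fraction indices generated as Binomial(k, p)/k with p logistic in
  effective age, so values stay in [0, 1];
* biological-age columns that track chronological age with a configurable
  loading on the same latent acceleration plus independent noise.

The latent acceleration is ground truth kept for recovery tests only; it is
written to a separate truth file that no analysis stage reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError, DataError

REFERENCE_AGE = 20.0

#: canonical biological-age column names, as they appear in cohort tables
BIO_CLOCK_COLUMNS = (
    "PhenoAge",
    "DNAmAge",
    "DNAmAgeHannum",
    "DNAmPhenoAge",
    "DNAmGrimAge",
)


@dataclass(frozen=True)
class IndexSpec:
    """Generative description of one cognitive index.

    ``baseline`` is the expected value at the reference age of 20 years;
    ``age_slope`` is the drift per year of effective age (for fraction
    indices it is in logit units per year). ``summary`` controls the
    default quantifier mapping: "full" series get all seven summary
    statistics, "mean" series contribute their mean only, "identity"
    scalars pass through unchanged.
    """

    name: str
    kind: str  # "series" | "scalar"
    baseline: float
    age_slope: float
    noise_sd: float = 0.0
    n_trials: int = 1
    mixture_weight: float = 0.0
    slow_mode_shift: float = 0.0
    direction: str = "lower_is_better"
    fraction: bool = False
    n_items: int = 40
    summary: str = "full"  # "full" | "mean" | "identity"
    between_sd: float = 0.0  # stable per-participant trait offset (logit units for fractions)
    noise_age_slope: float = 0.0  # heteroscedasticity: trial-noise SD drift per year
    response: str = "linear"  # "linear" | "saturating" age-response shape
    response_scale: float = 25.0  # e-folding scale (years) of the saturating response

    def validate(self) -> None:
        if self.kind not in ("series", "scalar"):
            raise ConfigError(f"index {self.name!r}: kind must be 'series' or 'scalar'")
        if self.kind == "series" and self.n_trials < 1:
            raise ConfigError(f"index {self.name!r}: n_trials must be >= 1 for series")
        if self.noise_sd < 0:
            raise ConfigError(f"index {self.name!r}: noise_sd must be >= 0")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ConfigError(f"index {self.name!r}: mixture_weight must be in [0, 1]")
        if self.direction not in ("lower_is_better", "higher_is_better"):
            raise ConfigError(f"index {self.name!r}: invalid direction {self.direction!r}")
        if self.fraction and not 0.0 < self.baseline < 1.0:
            raise ConfigError(f"index {self.name!r}: fraction baseline must be in (0, 1)")
        if self.fraction and self.n_items < 1:
            raise ConfigError(f"index {self.name!r}: n_items must be >= 1")
        if self.between_sd < 0:
            raise ConfigError(f"index {self.name!r}: between_sd must be >= 0")
        if self.summary not in ("full", "mean", "identity"):
            raise ConfigError(f"index {self.name!r}: invalid summary {self.summary!r}")
        if self.response not in ("linear", "saturating"):
            raise ConfigError(f"index {self.name!r}: invalid response {self.response!r}")
        if self.response_scale <= 0:
            raise ConfigError(f"index {self.name!r}: response_scale must be > 0")


@dataclass(frozen=True)
class BioClockSpec:
    """Linear generative model for one biological-age column.

    bio_age = intercept + slope * chrono + shared_accel_loading * latent_accel
              + Normal(0, independent_noise_sd)
    """

    name: str
    intercept: float = 0.0
    slope: float = 1.0
    shared_accel_loading: float = 0.0
    independent_noise_sd: float = 0.0

    def validate(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ConfigError(f"bio clock {self.name!r}: slope/intercept must be finite")
        if self.independent_noise_sd < 0:
            raise ConfigError(f"bio clock {self.name!r}: independent_noise_sd must be >= 0")


@dataclass(frozen=True)
class SubgroupSpec:
    """A fraction of the cohort whose latent acceleration is shifted.

    Used to inject decelerated ("good performer") or accelerated ("poor
    performer") subpopulations for end-to-end recovery experiments.
    """

    fraction: float
    accel_shift: float

    def validate(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError("subgroup fraction must be in [0, 1]")


def default_index_specs() -> tuple[IndexSpec, ...]:
    """The 16 default cognitive indices (8 time series + 8 scalar/count).

    Times are in milliseconds, shade thresholds in sharpening/decay steps,
    errors as fractions. Five indices carry a strong age trend (shade
    recognition/hiding times CM t+/t-, sharpening threshold CM dH+, the
    arithmetic false-rejection fraction SM1 ERR-1 and the reversed-letter
    motor reaction SM2 MR); the rest drift only weakly with age, so that
    roughly a third of the 64 quantifiers are detectably age-associated at
    a stringent threshold in a cohort of ~120. Between-participant trait
    variance dominates the residual, keeping single-quantifier age
    correlations near 0.5, and a slow attentional-lapse mixture mode makes
    the trial distributions broad and bimodal.
    """
    time = dict(kind="series", direction="lower_is_better", summary="full")
    steps = dict(kind="series", direction="lower_is_better", summary="mean")
    err = dict(kind="scalar", direction="lower_is_better", fraction=True, summary="identity")
    return (
        # campimetry: stimulus recognition / hiding times (ms), strong age trend
        IndexSpec("CM t+", baseline=900, age_slope=9.0, noise_sd=240, n_trials=12,
                  mixture_weight=0.15, slow_mode_shift=450, between_sd=280,
                  noise_age_slope=1.5, **time),
        IndexSpec("CM t-", baseline=1100, age_slope=10.0, noise_sd=280, n_trials=12,
                  mixture_weight=0.15, slow_mode_shift=500, between_sd=320,
                  noise_age_slope=1.5, **time),
        # arithmetic test: motor / sensorimotor reaction, decision time (ms), weak trend
        IndexSpec("SM1 MR", baseline=420, age_slope=1.2, noise_sd=110, n_trials=15,
                  mixture_weight=0.10, slow_mode_shift=220, between_sd=160, **time),
        IndexSpec("SM1 SMR", baseline=760, age_slope=2.0, noise_sd=190, n_trials=15,
                  mixture_weight=0.12, slow_mode_shift=320, between_sd=250, **time),
        IndexSpec("SM1 DT", baseline=620, age_slope=1.5, noise_sd=160, n_trials=15,
                  mixture_weight=0.10, slow_mode_shift=280, between_sd=210, **time),
        # reversed-letter test: motor reaction ages strongly, the rest weakly (ms)
        IndexSpec("SM2 MR", baseline=430, age_slope=3.0, noise_sd=110, n_trials=15,
                  mixture_weight=0.10, slow_mode_shift=230, between_sd=90,
                  noise_age_slope=0.8, **time),
        IndexSpec("SM2 SMR", baseline=800, age_slope=2.0, noise_sd=200, n_trials=15,
                  mixture_weight=0.12, slow_mode_shift=340, between_sd=260, **time),
        IndexSpec("SM2 DT", baseline=650, age_slope=1.8, noise_sd=170, n_trials=15,
                  mixture_weight=0.10, slow_mode_shift=290, between_sd=230, **time),
        # campimetry shade thresholds (steps until distinguish / merge)
        IndexSpec("CM dH+", baseline=7.0, age_slope=0.07, noise_sd=2.2, n_trials=12,
                  between_sd=1.6, **steps),
        IndexSpec("CM dH-", baseline=8.0, age_slope=0.01, noise_sd=2.2, n_trials=12,
                  between_sd=1.8, **steps),
        # error fractions (false rejections / false acceptances)
        IndexSpec("SM1 ERR-1", baseline=0.06, age_slope=0.035, n_items=40,
                  between_sd=0.45, **err),
        IndexSpec("SM1 ERR-2", baseline=0.05, age_slope=0.004, n_items=40,
                  between_sd=0.50, **err),
        IndexSpec("SM2 ERR-1", baseline=0.07, age_slope=0.006, n_items=40,
                  between_sd=0.50, **err),
        IndexSpec("SM2 ERR-2", baseline=0.05, age_slope=0.004, n_items=40,
                  between_sd=0.50, **err),
        # number of correct answers per test block
        IndexSpec("SM1 NC", kind="scalar", baseline=34.0, age_slope=-0.02, noise_sd=2.0,
                  between_sd=3.0, direction="higher_is_better", summary="identity"),
        IndexSpec("SM2 NC", kind="scalar", baseline=33.0, age_slope=-0.02, noise_sd=2.0,
                  between_sd=3.0, direction="higher_is_better", summary="identity"),
    )


def default_bio_clock_specs() -> tuple[BioClockSpec, ...]:
    """Default biological-age generators.

    Loadings decrease from Phenotypic Age to GrimAge so that acceleration
    correlations with the cognitive latent span strong-to-weak, matching
    the qualitative ordering the analysis is meant to resolve.
    """
    return (
        BioClockSpec("PhenoAge", intercept=0.0, slope=1.0,
                     shared_accel_loading=0.9, independent_noise_sd=2.5),
        BioClockSpec("DNAmAge", intercept=2.0, slope=0.95,
                     shared_accel_loading=0.7, independent_noise_sd=4.0),
        BioClockSpec("DNAmAgeHannum", intercept=-1.0, slope=0.97,
                     shared_accel_loading=0.6, independent_noise_sd=5.0),
        BioClockSpec("DNAmPhenoAge", intercept=-3.0, slope=1.02,
                     shared_accel_loading=0.5, independent_noise_sd=8.0),
        BioClockSpec("DNAmGrimAge", intercept=5.0, slope=0.9,
                     shared_accel_loading=0.3, independent_noise_sd=5.0),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full generative configuration for one synthetic cohort."""

    n_participants: int = 118
    age_min: float = 19.0
    age_max: float = 85.0
    female_fraction: float = 81.0 / 118.0
    index_specs: tuple[IndexSpec, ...] = field(default_factory=default_index_specs)
    accel_sd: float = 5.0
    bio_clock_specs: tuple[BioClockSpec, ...] = field(default_factory=default_bio_clock_specs)
    subgroups: tuple[SubgroupSpec, ...] = ()
    sex_age_offset: float = 0.0  # years added to male effective age (robustness knob)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if not self.age_min < self.age_max:
            raise ConfigError("age_min must be < age_max")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")
        if self.accel_sd < 0:
            raise ConfigError("accel_sd must be >= 0")
        names = [s.name for s in self.index_specs]
        if len(set(names)) != len(names):
            raise ConfigError("index_specs: index names must be unique")
        for s in self.index_specs:
            s.validate()
        for b in self.bio_clock_specs:
            b.validate()
        total = 0.0
        for g in self.subgroups:
            g.validate()
            total += g.fraction
        if total > 1.0 + 1e-12:
            raise ConfigError("subgroups: fractions must sum to <= 1")


@dataclass
class Participant:
    id: str
    sex: str  # "F" | "M"
    chronological_age: float
    latent_accel: float
    index_series: dict[str, list[float]]
    biological_ages: dict[str, float]


@dataclass
class Cohort:
    """An in-memory cohort with its generating config (when synthetic)."""

    participants: list[Participant]
    index_names: list[str]
    config: CohortConfig | None = None

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.participants]

    @property
    def ages(self) -> np.ndarray:
        return np.array([p.chronological_age for p in self.participants])

    @property
    def latent_accels(self) -> np.ndarray:
        return np.array([p.latent_accel for p in self.participants])

    def cohort_frame(self) -> pd.DataFrame:
        """Participant-level table: id, sex, age, biological-age columns."""
        rows = []
        bio_cols: list[str] = []
        for p in self.participants:
            for c in p.biological_ages:
                if c not in bio_cols:
                    bio_cols.append(c)
        for p in self.participants:
            row = {"id": p.id, "sex": p.sex, "age": p.chronological_age}
            for c in bio_cols:
                row[c] = p.biological_ages.get(c, np.nan)
            rows.append(row)
        return pd.DataFrame(rows, columns=["id", "sex", "age", *bio_cols])

    def indices_frame(self) -> pd.DataFrame:
        """Long-format trial table: id, index, trial, value."""
        rows = []
        for p in self.participants:
            for name in self.index_names:
                for t, v in enumerate(p.index_series[name]):
                    rows.append((p.id, name, t, v))
        return pd.DataFrame(rows, columns=["id", "index", "trial", "value"])

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "latent_accel": self.latent_accels})


def _generate_index_values(spec: IndexSpec, effective_age: float,
                           rng: np.random.Generator) -> list[float]:
    years = effective_age - REFERENCE_AGE
    if spec.response == "saturating":
        # drift with initial slope age_slope, saturating over response_scale years
        drift = spec.age_slope * spec.response_scale * -np.expm1(-years / spec.response_scale)
    else:
        drift = spec.age_slope * years
    n = spec.n_trials if spec.kind == "series" else 1
    trait = rng.normal(0.0, spec.between_sd) if spec.between_sd > 0 else 0.0
    if spec.fraction:
        p = float(expit(logit(spec.baseline) + drift + trait))
        vals = rng.binomial(spec.n_items, p, size=n) / spec.n_items
        return [float(v) for v in vals]
    loc = spec.baseline + drift + trait
    trial_sd = max(0.0, spec.noise_sd + spec.noise_age_slope * years)
    vals = loc + rng.normal(0.0, trial_sd, size=n) if trial_sd > 0 else np.full(n, loc)
    if spec.mixture_weight > 0:
        slow = rng.random(n) < spec.mixture_weight
        vals = vals + slow * spec.slow_mode_shift
    return [float(v) for v in vals]


def generate_biological_ages(chronological_age: float, latent_accel: float,
                             specs: Sequence[BioClockSpec],
                             rng: np.random.Generator) -> dict[str, float]:
    """Draw the biological-age columns for one participant."""
    out = {}
    for s in specs:
        s.validate()
        noise = rng.normal(0.0, s.independent_noise_sd) if s.independent_noise_sd > 0 else 0.0
        out[s.name] = float(s.intercept + s.slope * chronological_age
                            + s.shared_accel_loading * latent_accel + noise)
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort, deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    ages = rng.uniform(config.age_min, config.age_max, size=n)
    sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")
    accel = rng.normal(0.0, config.accel_sd, size=n) if config.accel_sd > 0 else np.zeros(n)

    # subgroup membership via one uniform draw against cumulative fractions
    if config.subgroups:
        u = rng.random(n)
        lo = 0.0
        for g in config.subgroups:
            hi = lo + g.fraction
            accel = accel + np.where((u >= lo) & (u < hi), g.accel_shift, 0.0)
            lo = hi

    width = max(4, len(str(max(n, 1))))
    participants = []
    for i in range(n):
        eff = ages[i] + accel[i]
        if sexes[i] == "M":
            eff += config.sex_age_offset
        series = {spec.name: _generate_index_values(spec, eff, rng)
                  for spec in config.index_specs}
        bio = generate_biological_ages(ages[i], accel[i], config.bio_clock_specs, rng)
        participants.append(Participant(
            id=f"P{i:0{width}d}", sex=str(sexes[i]),
            chronological_age=float(ages[i]), latent_accel=float(accel[i]),
            index_series=series, biological_ages=bio))
    return Cohort(participants=participants,
                  index_names=[s.name for s in config.index_specs],
                  config=config)


# ---------------------------------------------------------------------------
# file I/O: cohort.csv / indices.csv / truth.csv

def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write cohort.csv, indices.csv and truth.csv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": directory / "cohort.csv",
        "indices": directory / "indices.csv",
        "truth": directory / "truth.csv",
    }
    cohort.cohort_frame().to_csv(paths["cohort"], index=False)
    cohort.indices_frame().to_csv(paths["indices"], index=False)
    cohort.truth_frame().to_csv(paths["truth"], index=False)
    return paths


def read_truth(path: str | Path) -> pd.Series:
    """Read the ground-truth latent accelerations (recovery tests only)."""
    df = pd.read_csv(path)
    if "id" not in df.columns or "latent_accel" not in df.columns:
        raise DataError(f"{path}: truth file requires columns 'id' and 'latent_accel'")
    return df.set_index("id")["latent_accel"]


def read_cohort(directory: str | Path,
                expected_indices: Sequence[str] | None = None) -> Cohort:
    """Read cohort.csv + indices.csv back into a Cohort.

    The truth file is deliberately NOT read: latent accelerations are set to
    NaN so analysis stages cannot peek at ground truth.
    """
    directory = Path(directory)
    cohort_path = directory / "cohort.csv"
    indices_path = directory / "indices.csv"
    if not cohort_path.exists():
        raise DataError(f"missing cohort table: {cohort_path}")
    if not indices_path.exists():
        raise DataError(f"missing index-series table: {indices_path}")

    cdf = pd.read_csv(cohort_path)
    for col in ("id", "age"):
        if col not in cdf.columns:
            raise DataError(f"{cohort_path}: required column {col!r} is missing")
    if cdf["id"].duplicated().any():
        dup = cdf.loc[cdf["id"].duplicated(), "id"].iloc[0]
        raise DataError(f"{cohort_path}: duplicate participant id {dup!r}")

    idf = pd.read_csv(indices_path)
    for col in ("id", "index", "trial", "value"):
        if col not in idf.columns:
            raise DataError(f"{indices_path}: required column {col!r} is missing")
    index_names = list(pd.unique(idf["index"]))
    if expected_indices is not None:
        unknown = sorted(set(index_names) - set(expected_indices))
        if unknown:
            raise DataError(
                f"{indices_path}: unknown index name(s) {unknown}; "
                f"known indices: {sorted(expected_indices)}")

    bio_cols = [c for c in cdf.columns if c not in ("id", "sex", "age")]
    series_by_id: dict[str, dict[str, list[float]]] = {}
    for (pid, name), grp in idf.groupby(["id", "index"], sort=False):
        series_by_id.setdefault(str(pid), {})[str(name)] = [
            float(v) for v in grp.sort_values("trial")["value"]]

    participants = []
    for _, row in cdf.iterrows():
        pid = str(row["id"])
        series = series_by_id.get(pid, {})
        for name in index_names:
            series.setdefault(name, [])
        bio = {c: float(row[c]) for c in bio_cols if pd.notna(row[c])}
        participants.append(Participant(
            id=pid, sex=str(row.get("sex", "")),
            chronological_age=float(row["age"]),
            latent_accel=float("nan"), index_series=series,
            biological_ages=bio))
    return Cohort(participants=participants, index_names=index_names)
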