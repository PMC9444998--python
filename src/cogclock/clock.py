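"""Cognitive clocks: cross-validated age-prediction models.

A clock is a regression model predicting an age variable (chronological or
a biological age) from the top-k age-ranked cognitive quantifiers. Model
selection runs a grid search over model family, hyperparameters and k,
scored by stratified 5-fold cross-validation (participants binned by age
into 7 equal-width bins on [10, 90] for stratification). Features are
z-scored with means/SDs learned on the training folds only.

Two feature-ranking conventions are supported: ``"paper"`` ranks the
quantifiers once on the full dataset before cross-validation (optimistic:
the ranking sees the held-out folds), while ``"strict"`` re-ranks inside
each training fold. The default is "paper" for fidelity to the original
protocol; the leakage caveat is documented in the methods note.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression, TheilSenRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR, NuSVR

from .errors import ConfigError, DataError
from .selection import select_quantifiers

log = logging.getLogger(__name__)

ARTIFACT_VERSION = 1

MODEL_FAMILIES = ("linear", "elastic_net", "svr_rbf", "nu_svr_rbf",
                  "random_forest", "knn", "theil_sen")

#: default hyperparameter grids (hyperparameter name -> value list)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "linear": {},
    "elastic_net": {"alpha": [0.01, 0.1, 1.0], "l1_ratio": [0.2, 0.5, 0.8]},
    "svr_rbf": {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1]},
    "nu_svr_rbf": {"nu": [0.25, 0.5, 0.75], "C": [1.0, 10.0, 100.0]},
    "random_forest": {"n_estimators": [200], "max_depth": [3, 5, None]},
    "knn": {"n_neighbors": [1, 3, 5, 7, 9, 13, 17, 21, 25]},
    "theil_sen": {},
}

DEFAULT_AGE_BINS = tuple(np.linspace(10.0, 90.0, 8))


def make_estimator(family: str, params: Mapping[str, Any], seed: int = 0):
    """Instantiate a scikit-learn regressor for one grid point."""
    params = dict(params)
    if family == "linear":
        return LinearRegression(**params)
    if family == "elastic_net":
        return ElasticNet(max_iter=20_000, **params)
    if family == "svr_rbf":
        return SVR(kernel="rbf", **params)
    if family == "nu_svr_rbf":
        return NuSVR(kernel="rbf", **params)
    if family == "random_forest":
        return RandomForestRegressor(random_state=seed, **params)
    if family == "knn":
        return KNeighborsRegressor(**params)
    if family == "theil_sen":
        return TheilSenRegressor(random_state=seed, **params)
    raise ConfigError(f"unknown model family {family!r}; expected one of {MODEL_FAMILIES}")


@dataclass(frozen=True)
class ClockSpec:
    """Search space and protocol for one clock fit."""

    model_families: tuple[str, ...] = ("linear", "svr_rbf", "knn")
    grids: Mapping[str, Mapping[str, list]] | None = None
    top_k_range: tuple[int, ...] = (5, 10, 15, 20)
    n_folds: int = 5
    age_bins: tuple[float, ...] = DEFAULT_AGE_BINS
    objective: str = "mean_EV"  # "mean_EV" | "mean_MAE"
    ranking_mode: str = "paper"  # "paper" | "strict"
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if any(k < 1 for k in self.top_k_range):
            raise ConfigError("top_k values must be >= 1")
        edges = np.asarray(self.age_bins, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigError("age_bins edges must be strictly increasing")
        if self.objective not in ("mean_EV", "mean_MAE"):
            raise ConfigError(f"unknown objective {self.objective!r}")
        if self.ranking_mode not in ("paper", "strict"):
            raise ConfigError(f"unknown ranking_mode {self.ranking_mode!r}")
        for fam in self.model_families:
            if fam not in MODEL_FAMILIES:
                raise ConfigError(f"unknown model family {fam!r}; "
                                  f"expected one of {MODEL_FAMILIES}")

    def grid_for(self, family: str) -> list[dict[str, Any]]:
        grid = (self.grids or DEFAULT_GRIDS).get(family, DEFAULT_GRIDS.get(family, {}))
        if not grid:
            return [{}]
        names = sorted(grid)
        return [dict(zip(names, combo)) for combo in product(*(grid[n] for n in names))]


def stratified_folds(ages: Sequence[float], n_folds: int = 5,
                     bin_edges: Sequence[float] = DEFAULT_AGE_BINS,
                     seed: int = 0) -> np.ndarray:
    """Age-stratified fold labels in 0..n_folds-1.

    Participants are binned by age (ages outside the edge range are clamped
    into the boundary bins, with a log entry), the members of each bin are
    shuffled, and all participants are dealt round-robin through a seeded
    permutation of the folds. This guarantees overall fold sizes differing
    by at most 1 and, within every age bin, per-fold counts differing by at
    most 1 — even for bins smaller than the number of folds.
    """
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if n < n_folds:
        raise DataError(f"need at least n_folds={n_folds} participants, got {n}")
    edges = np.asarray(bin_edges, dtype=float)
    outside = (ages < edges[0]) | (ages > edges[-1])
    if outside.any():
        log.info("%d age(s) outside [%g, %g] clamped into boundary bins",
                 int(outside.sum()), edges[0], edges[-1])
    bins = np.clip(np.digitize(ages, edges[1:-1]), 0, edges.size - 2)

    rng = np.random.default_rng(seed)
    fold_order = rng.permutation(n_folds)
    labels = np.empty(n, dtype=int)
    counter = 0
    for b in range(edges.size - 1):
        members = np.flatnonzero(bins == b)
        rng.shuffle(members)
        for idx in members:
            labels[idx] = fold_order[counter % n_folds]
            counter += 1
    return labels


def evaluate_metrics(y_true: Sequence[float], y_pred: Sequence[float]
                     ) -> tuple[float, float, float]:
    """(EV, MAE, MedAE) for one prediction vector.

    EV = 1 - Var(y_true - y_pred) / Var(y_true) — the shift-invariant
    explained-variance score. Returns NaN EV when Var(y_true) = 0.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise DataError("evaluate_metrics requires equal-length non-empty vectors")
    err = y_true - y_pred
    var_t = float(np.var(y_true))
    ev = float("nan") if var_t == 0 else 1.0 - float(np.var(err)) / var_t
    mae = float(np.mean(np.abs(err)))
    medae = float(np.median(np.abs(err)))
    return ev, mae, medae


@dataclass
class Standardization:
    """Per-quantifier z-scoring parameters learned on training rows only."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Standardization":
        means = X.mean(axis=0).to_numpy()
        sds = X.std(axis=0, ddof=1).to_numpy()
        keep = sds > 0
        if not keep.all():
            dropped = [c for c, k in zip(X.columns, keep) if not k]
            log.info("dropping %d zero-variance column(s): %s", len(dropped), dropped)
        return cls(columns=[c for c, k in zip(X.columns, keep) if k],
                   means=means[keep], sds=sds[keep])

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise DataError(f"missing quantifier column(s): {missing}")
        return (X[self.columns].to_numpy(dtype=float) - self.means) / self.sds


@dataclass
class ClockCVResult:
    """Cross-validation outcome for one (family, params, top_k) grid point."""

    family: str
    params: dict[str, Any]
    top_k: int
    fold_ev: np.ndarray
    fold_mae: np.ndarray
    fold_medae: np.ndarray
    folds: np.ndarray = field(repr=False, default=None)

    @property
    def mean_ev(self) -> float:
        return float(np.mean(self.fold_ev))

    @property
    def sd_ev(self) -> float:
        return float(np.std(self.fold_ev, ddof=1))

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.fold_mae))

    @property
    def sd_mae(self) -> float:
        return float(np.std(self.fold_mae, ddof=1))

    @property
    def mean_medae(self) -> float:
        return float(np.mean(self.fold_medae))


def _complete_rows(matrix: pd.DataFrame, columns: Sequence[str],
                   age: np.ndarray) -> np.ndarray:
    X = matrix[list(columns)].to_numpy(dtype=float)
    keep = np.all(np.isfinite(X), axis=1) & np.isfinite(age)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d row(s) with NA quantifiers or age", dropped)
    return keep


def cross_validate(spec: ClockSpec, matrix: pd.DataFrame,
                   ranked_quantifiers: Sequence[str],
                   age: Sequence[float]) -> list[ClockCVResult]:
    """Grid search over (family, hyperparameters, top_k) with stratified CV.

    Standardization is fit on training folds only. In "strict" ranking
    mode the quantifier ranking itself is recomputed on each training fold.
    """
    spec.validate()
    age = np.asarray(age, dtype=float)
    if len(matrix) != age.size:
        raise DataError("matrix rows and age vector are misaligned")
    ranked = [q for q in ranked_quantifiers if q in matrix.columns]
    if not ranked:
        raise DataError("no ranked quantifiers present in the matrix")

    keep = _complete_rows(matrix, ranked, age)
    matrix = matrix.loc[keep]
    age = age[keep]
    folds = stratified_folds(age, spec.n_folds, spec.age_bins, spec.seed)

    # per-fold rankings for strict mode, computed once
    fold_rankings: dict[int, list[str]] = {}
    if spec.ranking_mode == "strict":
        for f in range(spec.n_folds):
            train = folds != f
            sel = select_quantifiers(matrix.loc[train, ranked], age[train])
            fold_rankings[f] = list(sel.sort_values("rank")["quantifier"])

    results: list[ClockCVResult] = []
    for family in spec.model_families:
        for params in spec.grid_for(family):
            for k in spec.top_k_range:
                if k > len(ranked):
                    log.info("skipping top_k=%d (> %d available quantifiers)",
                             k, len(ranked))
                    continue
                evs, maes, medaes = [], [], []
                for f in range(spec.n_folds):
                    train = folds != f
                    cols = (fold_rankings[f] if spec.ranking_mode == "strict"
                            else ranked)[:k]
                    std = Standardization.fit(matrix.loc[train, cols])
                    est = make_estimator(family, params, seed=spec.seed)
                    est.fit(std.transform(matrix.loc[train]), age[train])
                    pred = est.predict(std.transform(matrix.loc[~train]))
                    ev, mae, medae = evaluate_metrics(age[~train], pred)
                    evs.append(ev)
                    maes.append(mae)
                    medaes.append(medae)
                results.append(ClockCVResult(
                    family=family, params=dict(params), top_k=k,
                    fold_ev=np.array(evs), fold_mae=np.array(maes),
                    fold_medae=np.array(medaes), folds=folds))
    if not results:
        raise DataError("grid search produced no results "
                        "(all top_k values exceed the available quantifiers?)")
    return results


def select_optimal(results: Sequence[ClockCVResult],
                   objective: str = "mean_EV") -> ClockCVResult:
    """Deterministic winner: max mean EV (default) or min mean MAE.

    Ties break toward smaller top_k, then fewer/smaller hyperparameters,
    then family name.
    """
    if not results:
        raise DataError("select_optimal requires a non-empty result list")
    if objective not in ("mean_EV", "mean_MAE"):
        raise ConfigError(f"unknown objective {objective!r}")

    def key(r: ClockCVResult):
        score = -r.mean_ev if objective == "mean_EV" else r.mean_mae
        complexity = sorted((name, repr(v)) for name, v in r.params.items())
        return (score, r.top_k, len(complexity), complexity, r.family)

    return min(results, key=key)


@dataclass
class FittedClock:
    """A trained cognitive clock: selection + standardization + model."""

    family: str
    params: dict[str, Any]
    columns: list[str]
    standardization: Standardization
    estimator: Any
    target_name: str = "age"
    seed: int = 0
    version: int = ARTIFACT_VERSION

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        """One prediction per row; rows with NA in any selected column -> NaN."""
        missing = [c for c in self.columns if c not in matrix.columns]
        if missing:
            raise DataError(f"missing quantifier column(s): {missing}")
        X = matrix[self.columns].to_numpy(dtype=float)
        complete = np.all(np.isfinite(X), axis=1)
        out = np.full(len(matrix), np.nan)
        if complete.any():
            out[complete] = self.estimator.predict(
                self.standardization.transform(matrix.loc[complete]))
        if (~complete).any():
            log.info("%d row(s) with incomplete quantifiers predicted as NA",
                     int((~complete).sum()))
        return pd.Series(out, index=matrix.index, name=f"predicted_{self.target_name}")

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"artifact": "cogclock.FittedClock",
                         "version": self.version, "clock": self}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "FittedClock":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("artifact") != "cogclock.FittedClock":
            raise DataError(f"{path}: not a cognitive-clock artifact")
        if payload.get("version") != ARTIFACT_VERSION:
            raise DataError(f"{path}: unsupported artifact version "
                            f"{payload.get('version')}")
        return payload["clock"]


def fit_final(winner: ClockCVResult, matrix: pd.DataFrame,
              ranked_quantifiers: Sequence[str], age: Sequence[float],
              target_name: str = "age", seed: int = 0) -> FittedClock:
    """Refit the winning grid point on all complete rows."""
    age = np.asarray(age, dtype=float)
    ranked = [q for q in ranked_quantifiers if q in matrix.columns]
    cols = ranked[:winner.top_k]
    keep = _complete_rows(matrix, cols, age)
    std = Standardization.fit(matrix.loc[keep, cols])
    est = make_estimator(winner.family, winner.params, seed=seed)
    est.fit(std.transform(matrix.loc[keep]), age[keep])
    return FittedClock(family=winner.family, params=dict(winner.params),
                       columns=cols, standardization=std, estimator=est,
                       target_name=target_name, seed=seed)


def predict_age(clock: FittedClock, matrix: pd.DataFrame) -> pd.Series:
    return clock.predict(matrix)


def results_to_frame(results: Sequence[ClockCVResult]) -> pd.DataFrame:
    """Flatten CV results (one aggregate row per grid point)."""
    rows = []
    for r in results:
        row = {"family": r.family, "params": repr(dict(sorted(r.params.items()))),
               "top_k": r.top_k,
               "mean_ev": r.mean_ev, "sd_ev": r.sd_ev,
               "mean_mae": r.mean_mae, "sd_mae": r.sd_mae,
               "mean_medae": r.mean_medae}
        for f, (ev, mae, medae) in enumerate(zip(r.fold_ev, r.fold_mae, r.fold_medae)):
            row[f"ev_fold{f}"] = ev
            row[f"mae_fold{f}"] = mae
            row[f"medae_fold{f}"] = medae
        rows.append(row)
    return pd.DataFrame(rows)
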