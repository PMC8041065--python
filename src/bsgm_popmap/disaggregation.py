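"""Top-down RF-informed dasymetric population disaggregation.

A random-forest regressor is trained at the subnational-unit level on log
population density against unit-mean covariates, with mtry tuning and
iterative elimination of covariates whose out-of-bag (OOB) permutation
importance — percent increase in MSE, averaged across trees — is non-positive.
The fitted forest predicts a pixel-level density surface whose values act as
unit-relative weights redistributing each unit's population count to pixels,
so pixel values always sum back to the unit count. Each year's model is fit
independently.

The forest is a bagged ensemble of CART regression trees with
package-managed bootstrap resampling, which exposes the per-tree OOB samples
the permutation importance is defined on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.tree import DecisionTreeRegressor

from .covariates import distance_to_nearest_edge, unit_mean
from .scenario import ScenarioBundle

logger = logging.getLogger(__name__)

__all__ = [
    "RFConfig",
    "DensityForest",
    "build_training_table",
    "select_covariates",
    "predict_density_surface",
    "dasymetric_redistribute",
    "extract_importances",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters.

    ``n_trees`` defaults to 500; ``mtry`` (covariates examined per split) is
    tuned over a geometric grid around p/3 when left None; ``min_retained``
    floors the iterative covariate elimination.
    """

    n_trees: int = 500
    mtry: int | None = None
    seed: int = 0
    min_retained: int = 3

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class DensityForest:
    """Bagged regression forest with per-tree OOB permutation importance.

    Per tree: a bootstrap sample trains a CART regressor considering ``mtry``
    covariates per split; the tree's out-of-bag rows give its baseline MSE
    and, with one covariate's OOB values permuted, the permuted MSE. The
    covariate's Per.Inc.MSE is the percent increase averaged across trees.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None, seed: int = 0):
        self.n_trees = int(n_trees)
        self.mtry = mtry
        self.seed = int(seed)
        self.trees_: list[DecisionTreeRegressor] = []
        self.oob_masks_: list[np.ndarray] = []
        self.feature_names_: list[str] = []

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "DensityForest":
        Xv = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = Xv.shape
        self.feature_names_ = list(X.columns)
        mtry = self.mtry if self.mtry is not None else max(1, p // 3)
        mtry = int(min(max(mtry, 1), p))
        root = np.random.SeedSequence([self.seed, 29])
        rng = np.random.default_rng(root)
        self.trees_, self.oob_masks_ = [], []
        self._X, self._y = Xv, y
        for t in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=5,  # standard regression-forest node size
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xv[idx], y[idx])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        return self

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_].to_numpy(dtype=float)
        preds = np.zeros(len(X))
        for tree in self.trees_:
            preds += tree.predict(X)
        return preds / len(self.trees_)

    def oob_prediction(self) -> np.ndarray:
        """OOB-averaged prediction per training row (NaN if never OOB)."""
        n = len(self._y)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if oob.any():
                total[oob] += tree.predict(self._X[oob])
                count[oob] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(count > 0, total / count, np.nan)

    def oob_mse(self) -> float:
        pred = self.oob_prediction()
        ok = ~np.isnan(pred)
        return float(np.mean((pred[ok] - self._y[ok]) ** 2))

    def per_inc_mse(self) -> pd.Series:
        """Percent increase in OOB MSE under per-covariate permutation.

        Per-tree MSE differences (permuted minus baseline, on the tree's OOB
        rows) are averaged across trees and expressed as a percentage of the
        mean baseline OOB MSE. Normalising by the pooled baseline rather than
        each tree's own keeps the estimate unbiased for uninformative
        covariates (a per-tree ratio correlates the denominator with the
        difference). Trees with fewer than 2 OOB rows are skipped.
        """
        p = len(self.feature_names_)
        diff_sums = np.zeros(p)
        base_sum = 0.0
        n_used = 0
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 31]))
        for tree, oob in zip(self.trees_, self.oob_masks_):
            n_oob = int(oob.sum())
            if n_oob < 2:
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            base = np.mean((tree.predict(Xo) - yo) ** 2)
            perm = rng.permutation(n_oob)
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                diff_sums[j] += np.mean((tree.predict(Xp) - yo) ** 2) - base
            base_sum += base
            n_used += 1
        if n_used == 0:
            return pd.Series(np.zeros(p), index=self.feature_names_, name="per_inc_mse")
        denom = base_sum / n_used
        if denom <= 0:
            denom = 1.0
        vals = 100.0 * (diff_sums / n_used) / denom
        return pd.Series(vals, index=self.feature_names_, name="per_inc_mse")


def tune_mtry(X: pd.DataFrame, y: np.ndarray, config: RFConfig, n_trees: int = 100) -> int:
    """Pick mtry on a geometric grid around p/3 by OOB MSE.

    Starting from m0 = max(1, p//3), candidates m0*2^k (k = -2..2, clipped to
    [1, p]) are scored with a small forest; a candidate displaces m0 only if
    it improves OOB MSE by at least 5%, mirroring the stepwise tuning logic
    of the standard tuning routine.
    """
    p = X.shape[1]
    m0 = max(1, p // 3)
    cands = sorted({int(np.clip(m0 * 2.0**k, 1, p)) for k in (-2, -1, 0, 1, 2)})
    scores = {}
    for m in cands:
        f = DensityForest(n_trees=n_trees, mtry=m, seed=config.seed).fit(X, y)
        scores[m] = f.oob_mse()
    best = min(scores, key=lambda m: (scores[m], m))
    if best != m0 and scores[best] > 0.95 * scores[m0]:
        best = m0  # improvement under the 5% threshold: keep the default
    return best


def build_training_table(
    bundle: ScenarioBundle,
    covariate_grids: dict[str, np.ndarray],
    year: int,
) -> pd.DataFrame:
    """Unit-level training table for one year's population-density model.

    Response ``log_density`` is the natural log of the unit's population
    count divided by its land-pixel area; covariates are the unit means of
    the supplied pixel grids. Zero-population units are excluded (and
    logged); an all-zero year raises.
    """
    unit_map = bundle.unit_map
    water = bundle.water_mask
    units = np.unique(unit_map[unit_map > 0])
    land_pixels = pd.Series(
        ndimage.sum_labels((~water).astype(float), unit_map, index=units),
        index=pd.Index(units, name="unit_id"),
    )
    pop = (
        bundle.population.loc[bundle.population.year == year]
        .set_index("unit_id")["population"]
        .reindex(units)
        .fillna(0.0)
    )
    table = pd.DataFrame(index=pd.Index(units, name="unit_id"))
    for name, grid in covariate_grids.items():
        table[name] = unit_mean(grid, unit_map, mask=water)
    keep = (pop > 0) & (land_pixels > 0)
    dropped = list(table.index[~keep])
    if dropped:
        logger.info("year %d: excluding zero-population units %s", year, dropped)
    if not keep.any():
        raise ValueError(f"no unit has positive population in year {year}")
    table = table.loc[keep]
    table.insert(0, "log_density", np.log(pop[keep] / land_pixels[keep]))
    return table.reset_index()


def population_covariate_grids(
    bundle: ScenarioBundle,
    bs_extent_year: np.ndarray,
    year: int,
) -> dict[str, np.ndarray]:
    """Pixel covariate stack for one year's density model: the year-specific
    BS DTE (BSGMi-derived for interim years, observed at the epochs), the
    historical t0 BS DTE, the coarse annual product's DTE, that year's LAN,
    and the static fields."""
    grids = {
        "dte_bs_year": distance_to_nearest_edge(bs_extent_year),
        "dte_bs_t0": distance_to_nearest_edge(bundle.observed_bs_t0),
    }
    if year in bundle.coarse_annual_bs and bundle.coarse_annual_bs[year].any():
        grids["dte_bs_coarse"] = distance_to_nearest_edge(bundle.coarse_annual_bs[year])
    if year in bundle.lan_series:
        grids["lan"] = bundle.lan_series[year]
    grids.update(bundle.static_covariates)
    return grids


def select_covariates(
    table: pd.DataFrame, config: RFConfig = RFConfig()
) -> tuple[list[str], DensityForest]:
    """Iterative covariate elimination on OOB permutation importance.

    Repeatedly fit the forest and drop every covariate whose Per.Inc.MSE is
    <= 0, until none is dropped or only ``min_retained`` covariates remain
    (the least negative survive). Returns the retained names and final fit.
    """
    names = [c for c in table.columns if c not in ("log_density", "unit_id")]
    if len(names) < 2:
        raise ValueError("need at least 2 covariates for selection")
    if len(names) < config.min_retained:
        raise ValueError(
            f"fewer covariates ({len(names)}) than min_retained ({config.min_retained})"
        )
    y = table["log_density"].to_numpy()
    while True:
        X = table[names]
        mtry = config.mtry if config.mtry is not None else tune_mtry(X, y, config)
        forest = DensityForest(n_trees=config.n_trees, mtry=mtry, seed=config.seed).fit(X, y)
        imp = forest.per_inc_mse()
        bad = list(imp.index[imp <= 0])
        if not bad or len(names) <= config.min_retained:
            return names, forest
        n_drop = min(len(bad), len(names) - config.min_retained)
        names = [n for n in names if n not in set(imp[bad].sort_values().index[:n_drop])]


def predict_density_surface(
    model: DensityForest,
    covariate_grids: dict[str, np.ndarray],
    water_mask: np.ndarray,
) -> np.ndarray:
    """Pixel density weights: back-transformed (exp) forest predictions over
    land, zero on water."""
    missing = [n for n in model.feature_names_ if n not in covariate_grids]
    if missing:
        raise ValueError(f"covariate grids missing for: {missing}")
    shape = next(iter(covariate_grids.values())).shape
    X = np.column_stack([np.asarray(covariate_grids[n], float).ravel() for n in model.feature_names_])
    dens = np.exp(model.predict(X)).reshape(shape)
    dens[np.asarray(water_mask).astype(bool)] = 0.0
    return dens


def dasymetric_redistribute(
    weights: np.ndarray,
    unit_map: np.ndarray,
    counts: pd.Series | dict[int, float],
) -> np.ndarray:
    """Redistribute unit counts over pixels proportionally to weights.

    pixel value = count_unit * w / sum_unit(w). A populated unit whose
    weights sum to zero falls back to a uniform split over its pixels
    (logged), so mass is always conserved exactly.
    """
    labels = np.asarray(unit_map)
    w = np.asarray(weights, dtype=float)
    out = np.zeros_like(w)
    counts = pd.Series(counts, dtype=float)
    for u, count in counts.items():
        sel = labels == int(u)
        if not sel.any():
            if count:
                raise ValueError(f"unit {u} has a count but no pixels")
            continue
        total = w[sel].sum()
        if total > 0:
            out[sel] = count * w[sel] / total
        else:
            if count:
                logger.info("unit %s has zero total weight; uniform fallback", u)
            out[sel] = count / sel.sum()
    return out


def extract_importances(model: DensityForest, country_id: int, year: int) -> pd.DataFrame:
    """ImportanceRecord rows: one per retained covariate with its OOB
    permutation Per.Inc.MSE."""
    imp = model.per_inc_mse()
    return pd.DataFrame(
        {
            "country_id": country_id,
            "year": year,
            "covariate": imp.index,
            "per_inc_mse": imp.to_numpy(),
        }
    )
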