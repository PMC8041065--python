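"""BSGMi spatial allocation.

A random forest trained on the observed period's transitions predicts each
candidate pixel's probability of a non-BS-to-BS transition; annual
lights-at-night difference weights modulate that period probability into
year-specific surfaces; and each unit-year's transition demand is allocated
to its highest-probability remaining candidates. Because the model is
interpolative, only pixels observed to have transitioned over the whole
period are ever allocated, so the produced annual series starts at the t0
extent, ends bitwise at the t1 extent, and is pixelwise monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .covariates import CovariateConfig, lan_weight, transition_covariate_stack
from .demand import CurveKind, build_demand_table
from .scenario import ScenarioBundle

logger = logging.getLogger(__name__)

__all__ = [
    "BsgmiConfig",
    "build_transition_training_table",
    "fit_transition_rf",
    "annual_probability",
    "allocate_year",
    "run_bsgmi",
]


@dataclass(frozen=True)
class BsgmiConfig:
    """Knobs of the interpolation run.

    ``n_trees`` sizes the transition forest; ``curve`` picks the demand
    interpolant (the validated logistic form or the early exponential
    variant).
    """

    n_trees: int = 500
    curve: CurveKind = "logistic"
    seed: int = 0
    covariates: CovariateConfig = CovariateConfig()


def build_transition_training_table(
    bundle: ScenarioBundle, config: BsgmiConfig = BsgmiConfig()
) -> pd.DataFrame:
    """One row per sampled pixel: transition label and t0 covariates.

    Positives are all pixels that transitioned between the epochs; negatives
    are an equal-size seeded random sample of land pixels that stayed non-BS
    (class balance on large grids). Water and already-settled t0 pixels are
    excluded.
    """
    t0 = bundle.observed_bs_t0.astype(bool)
    t1 = bundle.observed_bs_t1.astype(bool)
    land = ~bundle.water_mask
    transitioned = t1 & ~t0 & land
    persistent = ~t1 & ~t0 & land

    stack = transition_covariate_stack(t0, bundle.static_covariates, config.covariates)
    pos_idx = np.flatnonzero(transitioned)
    neg_pool = np.flatnonzero(persistent)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_neg = min(pos_idx.size, neg_pool.size) if pos_idx.size else neg_pool.size
    neg_idx = rng.choice(neg_pool, size=n_neg, replace=False) if n_neg else np.array([], int)

    idx = np.concatenate([pos_idx, neg_idx])
    table = pd.DataFrame({name: grid.ravel()[idx] for name, grid in stack.items()})
    table.insert(0, "label", np.concatenate([np.ones(pos_idx.size, int), np.zeros(neg_idx.size, int)]))
    table["pixel_index"] = idx
    return table


def fit_transition_rf(
    table: pd.DataFrame, n_trees: int = 500, seed: int = 0
) -> RandomForestClassifier:
    """Fit the transition-probability forest on a labelled pixel table.

    The forest is used as a probability machine: predicted probability is the
    fraction of trees voting "transition". Both classes must be present.
    """
    labels = table["label"].to_numpy()
    if np.unique(labels).size < 2:
        raise ValueError("training table is single-class; cannot fit transition model")
    X = table.drop(columns=["label", "pixel_index"], errors="ignore")
    model = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=int(seed), n_jobs=1
    )
    model.fit(X.to_numpy(), labels)
    model.feature_names_ = list(X.columns)
    return model


def predict_period_probability(
    model: RandomForestClassifier, stack: dict[str, np.ndarray]
) -> np.ndarray:
    """Period-level transition probability for every pixel of the grid."""
    names = model.feature_names_
    shape = stack[names[0]].shape
    X = np.column_stack([stack[n].ravel() for n in names])
    proba = model.predict_proba(X)[:, list(model.classes_).index(1)]
    return proba.reshape(shape)


def annual_probability(
    period_prob: np.ndarray, lan_w: np.ndarray, candidate_mask: np.ndarray
) -> np.ndarray:
    """Year-specific surface: period probability x LAN weight on candidates,
    zero elsewhere."""
    out = np.asarray(period_prob, dtype=float) * np.asarray(lan_w, dtype=float)
    out[~np.asarray(candidate_mask).astype(bool)] = 0.0
    return out


def allocate_year(
    surface: np.ndarray,
    candidate_mask: np.ndarray,
    unit_map: np.ndarray,
    unit_id: int,
    n_transitions: int,
    seed: int = 0,
) -> np.ndarray:
    """Select the unit's ``n_transitions`` highest-probability candidates.

    Deterministic given the seed: ties are broken by a seeded permutation of
    pixel order (then index), so equal-probability candidates are chosen
    reproducibly but without positional bias. If demand exceeds the remaining
    candidates, all candidates are taken and the caller carries the
    shortfall.
    """
    if n_transitions < 0:
        raise ValueError("demand must be nonnegative")
    sel = np.flatnonzero((np.asarray(unit_map) == unit_id) & np.asarray(candidate_mask).astype(bool))
    chosen = np.zeros(np.asarray(candidate_mask).shape, dtype=bool)
    if n_transitions == 0 or sel.size == 0:
        return chosen
    k = min(int(n_transitions), sel.size)
    probs = np.asarray(surface, dtype=float).ravel()[sel]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13, int(unit_id)]))
    tiebreak = rng.permutation(sel.size)
    order = np.lexsort((sel, tiebreak, -probs))
    chosen.flat[sel[order[:k]]] = True
    return chosen


def run_bsgmi(
    bundle: ScenarioBundle,
    config: BsgmiConfig = BsgmiConfig(),
    epoch_observations: pd.DataFrame | None = None,
) -> dict[int, np.ndarray]:
    """Interpolate annual BS extents between the two observed epochs.

    Demand side: unit BS population at the epochs (by default the unit's
    population count, i.e. the population found spatially coincident with the
    settled area) and BS pixel counts give growth-curve/spline interpolants
    whose implied-area increments weight the temporal disaggregation of each
    unit's observed transition total. Supply ``epoch_observations`` (columns
    unit_id, year, bs_population, bs_pixels) to override.

    Allocation side: period RF probabilities x annual LAN weights, allocated
    top-k per unit-year among not-yet-transitioned candidate pixels, with any
    shortfall carried to the next year. The final year absorbs every
    remaining candidate, so the series ends bitwise at the observed t1
    extent.

    Returns a dict year -> uint8 grid, monotone nondecreasing over years.
    """
    years = bundle.years
    t0_year, t1_year = years[0], years[-1]
    t0 = bundle.observed_bs_t0.astype(bool)
    t1 = bundle.observed_bs_t1.astype(bool)
    if ((t0 & ~t1)).any():
        raise ValueError("observed t0 extent must be a subset of the t1 extent")

    unit_map = bundle.unit_map
    units = np.unique(unit_map[unit_map > 0])
    transition_mask = t1 & ~t0

    totals = {
        int(u): int((transition_mask & (unit_map == u)).sum()) for u in units
    }

    if epoch_observations is None:
        pop = bundle.population
        rows = []
        for u in units:
            for year, extent in ((t0_year, t0), (t1_year, t1)):
                count = pop.loc[(pop.unit_id == u) & (pop.year == year), "population"]
                bs_pix = int((extent & (unit_map == u)).sum())
                rows.append(
                    {
                        "unit_id": int(u),
                        "year": int(year),
                        "bs_population": float(count.iloc[0]) if len(count) else 0.0,
                        "bs_pixels": bs_pix,
                    }
                )
        epoch_observations = pd.DataFrame.from_records(rows)

    demand = build_demand_table(epoch_observations, years, totals, curve=config.curve)

    if transition_mask.any():
        table = build_transition_training_table(bundle, config)
        model = fit_transition_rf(table, n_trees=config.n_trees, seed=config.seed)
        stack = transition_covariate_stack(t0, bundle.static_covariates, config.covariates)
        period_prob = predict_period_probability(model, stack)
    else:
        period_prob = np.zeros_like(t0, dtype=float)

    series: dict[int, np.ndarray] = {t0_year: t0.astype(np.uint8)}
    current = t0.copy()
    candidates = transition_mask.copy()
    carry = {int(u): 0 for u in units}
    for year in years[1:]:
        lan_w = (
            lan_weight(bundle.lan_series[year], bundle.lan_series[year - 1], unit_map)
            if year in bundle.lan_series and (year - 1) in bundle.lan_series
            else np.ones_like(period_prob)
        )
        surface = annual_probability(period_prob, lan_w, candidates)
        is_last = year == t1_year
        for u in units:
            u = int(u)
            row = demand.loc[(demand.unit_id == u) & (demand.year == year), "n_transitions"]
            want = (int(row.iloc[0]) if len(row) else 0) + carry[u]
            if is_last:  # conservation: final year absorbs any remainder
                want = int((candidates & (unit_map == u)).sum())
            avail = int((candidates & (unit_map == u)).sum())
            if want > avail:
                logger.info(
                    "unit %d year %d: demand %d exceeds %d candidates; carrying shortfall",
                    u, year, want, avail,
                )
                carry[u] = want - avail
                want = avail
            else:
                carry[u] = 0
            chosen = allocate_year(surface, candidates, unit_map, u, want, seed=config.seed)
            current |= chosen
            candidates &= ~chosen
        series[year] = current.astype(np.uint8)
    return series
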