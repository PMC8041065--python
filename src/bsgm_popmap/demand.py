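"""BSGMi demand quantification.

Between two observed built-settlement (BS) epochs, interpolate each unit's BS
population (logistic or exponential growth curves) and BS population density
(natural cubic splines), convert the implied BS area series into per-year
transition-demand weights, and disaggregate the observed period transition
count into integer annual counts that sum exactly to the observed total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "UnitDemandSeries",
    "fit_growth_curve",
    "interpolate_density_spline",
    "demand_weights",
    "disaggregate_transitions",
    "build_demand_table",
]

CurveKind = Literal["logistic", "exponential"]


@dataclass
class UnitDemandSeries:
    """Interpolated annual BS population / density / implied area for a unit.

    ``implied_bs_area = bs_population / bs_density``; its positive annual
    increments carry the unit's transition demand.
    """

    unit_id: int
    years: list[int]
    bs_population: np.ndarray
    bs_density: np.ndarray

    @property
    def implied_bs_area(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            area = np.where(self.bs_density > 0, self.bs_population / self.bs_density, 0.0)
        return area

    def __post_init__(self) -> None:
        n = len(self.years)
        self.bs_population = np.asarray(self.bs_population, dtype=float)
        self.bs_density = np.asarray(self.bs_density, dtype=float)
        if self.bs_population.shape != (n,) or self.bs_density.shape != (n,):
            raise ValueError("series lengths must match years")
        if np.any(self.bs_population < 0):
            raise ValueError("bs_population must be nonnegative")
        if np.any((self.bs_population > 0) & (self.bs_density <= 0)):
            raise ValueError("bs_density must be positive wherever bs_population > 0")


def _two_point_exponential(t0: float, v0: float, t1: float, v1: float) -> Callable[[np.ndarray], np.ndarray]:
    r = np.log(v1 / v0) / (t1 - t0)

    def curve(t):
        return v0 * np.exp(r * (np.asarray(t, dtype=float) - t0))

    return curve


def _two_point_logistic(
    t0: float, v0: float, t1: float, v1: float, capacity: float
) -> Callable[[np.ndarray], np.ndarray]:
    # K/(1+exp(-(a+b t))) through both points, solved in the logit of v/K
    if capacity <= max(v0, v1):
        raise ValueError("capacity must exceed both endpoint values")
    z0 = np.log(v0 / (capacity - v0))
    z1 = np.log(v1 / (capacity - v1))
    b = (z1 - z0) / (t1 - t0)
    a = z0 - b * t0

    def curve(t):
        return capacity / (1.0 + np.exp(-(a + b * np.asarray(t, dtype=float))))

    return curve


def fit_growth_curve(
    points: Sequence[tuple[float, float]],
    kind: CurveKind = "logistic",
    capacity: float | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit a unit-specific growth/decay curve through observed (year, value)
    points.

    ``exponential`` uses the two-point closed form r = ln(v1/v0)/(t1-t0);
    ``logistic`` needs a carrying capacity (default twice the larger
    endpoint) since two observations cannot identify three parameters. With
    more than two points the two-point rule is applied piecewise between
    consecutive observations, so the curve passes through every point
    exactly. Values must be positive for these multiplicative forms.
    """
    pts = sorted((float(t), float(v)) for t, v in points)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    ts = [p[0] for p in pts]
    if len(set(ts)) != len(ts):
        raise ValueError("duplicate years in growth-curve points")
    if any(v <= 0 for _, v in pts):
        raise ValueError("growth curves require strictly positive values")

    if kind == "exponential":
        segs = [
            _two_point_exponential(*pts[i], *pts[i + 1]) for i in range(len(pts) - 1)
        ]
    elif kind == "logistic":
        if capacity is None:
            capacity = 2.0 * max(v for _, v in pts)
        segs = [
            _two_point_logistic(*pts[i], *pts[i + 1], capacity)
            for i in range(len(pts) - 1)
        ]
    else:
        raise ValueError(f"unknown curve kind {kind!r}")

    bounds = ts[1:-1]

    def curve(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(bounds, t, side="right")
        flat = np.atleast_1d(t)
        out = np.empty_like(flat)
        for i, seg in enumerate(segs):
            sel = np.atleast_1d(idx) == i
            if sel.any():
                out[sel] = seg(flat[sel])
        return out if t.ndim else float(out[0])

    return curve


def interpolate_density_spline(
    points: Sequence[tuple[float, float]]
) -> Callable[[np.ndarray], np.ndarray]:
    """Natural cubic spline (zero second derivative at both ends) through the
    supplied (year, value) knots; exact at the knots. Two points degenerate
    to the linear interpolant."""
    pts = sorted((float(t), float(v)) for t, v in points)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    ts = np.array([p[0] for p in pts])
    vs = np.array([p[1] for p in pts])
    if np.any(np.diff(ts) <= 0):
        raise ValueError("years must be strictly increasing without duplicates")
    if len(pts) == 2:
        def linear(t):
            return np.interp(np.asarray(t, dtype=float), ts, vs)

        return linear
    return CubicSpline(ts, vs, bc_type="natural")


def demand_weights(series: UnitDemandSeries) -> np.ndarray:
    """Per-year transition-demand weights from implied-BS-area increments.

    w_t = max(0, A_t - A_{t-1}) for each interim step (clamping prevents an
    interpolative model from removing settlement), normalised to sum to 1;
    if no increment is positive, the fallback is uniform weights over the
    interim years.
    """
    area = series.implied_bs_area
    inc = np.maximum(np.diff(area), 0.0)
    total = inc.sum()
    if total <= 0:
        return np.full(inc.shape, 1.0 / inc.size)
    return inc / total


def disaggregate_transitions(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` transitions over years.

    Integer counts that sum exactly to ``total``; each year gets the floor of
    its quota total*w, and leftover units go to the largest fractional
    remainders (ties to earlier years).
    """
    if total < 0:
        raise ValueError("total transitions must be nonnegative")
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    quota = total * w
    counts = np.floor(quota).astype(int)
    short = int(total - counts.sum())
    if short > 0:
        remainders = quota - counts
        order = np.argsort(-remainders, kind="stable")
        counts[order[:short]] += 1
    return counts


def interpolate_unit_series(
    unit_id: int,
    years: Sequence[int],
    epochs: Sequence[tuple[int, float, float]],
    curve: CurveKind = "logistic",
    capacity: float | None = None,
) -> UnitDemandSeries:
    """Interpolate a unit's annual BS population and density between observed
    epochs ``(year, bs_population, bs_pixels)``.

    Population follows the requested growth curve; density (population per BS
    pixel) follows a natural cubic spline. Endpoints reproduce the observed
    values exactly. Units with no settlement at either epoch get a flat zero
    series (their demand falls back to uniform weights).
    """
    years = list(years)
    pop_pts = [(y, p) for y, p, _ in epochs]
    dens_pts = [(y, (p / a) if a > 0 else 0.0) for y, p, a in epochs]
    if any(p <= 0 for _, p in pop_pts) or any(d <= 0 for _, d in dens_pts):
        # degenerate unit: no positive population/density to interpolate
        return UnitDemandSeries(
            unit_id=unit_id,
            years=years,
            bs_population=np.zeros(len(years)),
            bs_density=np.ones(len(years)),
        )
    pop_curve = fit_growth_curve(pop_pts, kind=curve, capacity=capacity)
    dens_curve = interpolate_density_spline(dens_pts)
    t = np.asarray(years, dtype=float)
    dens = np.maximum(np.asarray(dens_curve(t), dtype=float), 1e-12)
    pop = np.asarray(pop_curve(t), dtype=float)
    return UnitDemandSeries(unit_id=unit_id, years=years, bs_population=pop, bs_density=dens)


def build_demand_table(
    observations: pd.DataFrame,
    years: Sequence[int],
    transition_totals: dict[int, int],
    curve: CurveKind = "logistic",
) -> pd.DataFrame:
    """Temporally disaggregate each unit's observed period transition count.

    ``observations`` has columns unit_id, year, bs_population, bs_pixels with
    one row per unit per observed epoch. Returns a TransitionDemand table
    (unit_id, year, n_transitions) over the interim steps: the row for year t
    counts transitions occurring in the step ending at t. Per unit the counts
    sum exactly to ``transition_totals[unit_id]``.
    """
    years = list(years)
    rows = []
    for unit_id, grp in observations.groupby("unit_id"):
        epochs = [
            (int(r.year), float(r.bs_population), float(r.bs_pixels))
            for r in grp.sort_values("year").itertuples()
        ]
        series = interpolate_unit_series(int(unit_id), years, epochs, curve=curve)
        w = demand_weights(series)
        counts = disaggregate_transitions(int(transition_totals.get(int(unit_id), 0)), w)
        for year, n in zip(years[1:], counts):
            rows.append({"unit_id": int(unit_id), "year": int(year), "n_transitions": int(n)})
    return pd.DataFrame.from_records(rows)
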