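"""Raster covariate derivation.

Continuizes binary settlement layers into the covariates the random-forest
models consume: unsigned Euclidean distance to the nearest class edge (DTE),
the proportion of class pixels within a disc of given pixel radius, per-unit
means, and the unit-rescaled lights-at-night (LAN) annual-difference weights
that modulate transition probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CovariateConfig",
    "distance_to_nearest_edge",
    "proportion_in_radius",
    "unit_mean",
    "lan_weight",
]

DEFAULT_RADII = (1, 5, 10, 15)


@dataclass(frozen=True)
class CovariateConfig:
    """Configuration of the covariate stack.

    ``proportion_radii`` are disc radii in pixel units; distances are
    Euclidean between pixel centers. ``signed_dte`` is kept as a flag but the
    unsigned convention (0 inside the class) is the default and only
    implemented variant.
    """

    proportion_radii: tuple[int, ...] = DEFAULT_RADII
    signed_dte: bool = False

    def __post_init__(self) -> None:
        if any(int(r) != r or r < 1 for r in self.proportion_radii):
            raise ValueError("proportion radii must be strictly positive integers")
        if self.signed_dte:
            raise NotImplementedError("only the unsigned DTE convention is implemented")


def distance_to_nearest_edge(mask: np.ndarray) -> np.ndarray:
    """Unsigned Euclidean distance (pixel units) to the nearest 1-pixel.

    Zero on the support of the mask. Raises on an empty mask: the distance is
    undefined, signalling a unit/country with no settlement.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("mask has no 1-pixels; distance to nearest edge undefined")
    return ndimage.distance_transform_edt(~m).astype(np.float64)


def _disc_kernel(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx <= r * r).astype(np.float64)


def proportion_in_radius(mask: np.ndarray, radius: int) -> np.ndarray:
    """Fraction of in-grid pixels within Euclidean distance ``radius`` whose
    mask value is 1; the center pixel is part of its own neighbourhood and
    edge pixels use the truncated disc."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    m = np.asarray(mask).astype(np.float64)
    kernel = _disc_kernel(radius)
    ones = ndimage.convolve(np.ones_like(m), kernel, mode="constant", cval=0.0)
    hits = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    return hits / ones


def unit_mean(
    grid: np.ndarray, unit_map: np.ndarray, mask: np.ndarray | None = None
) -> pd.Series:
    """Arithmetic mean of ``grid`` per unit, over unmasked pixels.

    ``unit_map`` holds positive integer labels (0 = no unit / water). If
    ``mask`` is given, True pixels are excluded. A unit with zero unmasked
    pixels raises.
    """
    labels = np.asarray(unit_map)
    g = np.asarray(grid, dtype=np.float64)
    valid = labels > 0
    if mask is not None:
        valid &= ~np.asarray(mask).astype(bool)
    units = np.unique(labels[labels > 0])
    counts = ndimage.sum_labels(valid.astype(float), labels, index=units)
    if np.any(counts == 0):
        empty = units[counts == 0]
        raise ValueError(f"unit(s) {empty.tolist()} have no unmasked pixels")
    sums = ndimage.sum_labels(np.where(valid, g, 0.0), labels, index=units)
    return pd.Series(sums / counts, index=pd.Index(units, name="unit_id"), name="mean")


def lan_weight(
    lan_curr: np.ndarray, lan_prev: np.ndarray, unit_map: np.ndarray
) -> np.ndarray:
    """Unit-rescaled annual LAN difference in [0, 1].

    The raw signal is d = lan_curr - lan_prev; within each unit it is min-max
    rescaled so the pixel with the greatest radiance increase gets weight 1
    and the smallest gets 0. A degenerate unit (constant d) gets a uniform,
    uninformative weight of 0.5 so it neither zeroes out nor saturates the
    probability product. Pixels outside any unit get 0.
    """
    d = np.asarray(lan_curr, dtype=np.float64) - np.asarray(lan_prev, dtype=np.float64)
    labels = np.asarray(unit_map)
    out = np.zeros_like(d)
    for u in np.unique(labels[labels > 0]):
        sel = labels == u
        lo, hi = d[sel].min(), d[sel].max()
        if hi > lo:
            out[sel] = (d[sel] - lo) / (hi - lo)
        else:
            out[sel] = 0.5
    return out


def transition_covariate_stack(
    bs_t0: np.ndarray,
    static_covariates: dict[str, np.ndarray],
    config: CovariateConfig = CovariateConfig(),
) -> dict[str, np.ndarray]:
    """Covariate layers used by the transition-probability random forest:
    DTE of the t0 BS extent, proportion-in-radius layers, and the static
    fields relevant to settlement suitability."""
    stack: dict[str, np.ndarray] = {"dte_bs_t0": distance_to_nearest_edge(bs_t0)}
    for r in config.proportion_radii:
        stack[f"prop_bs_r{r}"] = proportion_in_radius(bs_t0, r)
    for name in ("elevation", "slope", "dist_protected"):
        if name in static_covariates:
            stack[name] = np.asarray(static_covariates[name], dtype=np.float64)
    return stack
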