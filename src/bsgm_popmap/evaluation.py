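"""Accuracy scoring of interpolated settlement series against withheld truth."""

from __future__ import annotations

import numpy as np

from .allocation import BsgmiConfig, run_bsgmi
from .scenario import ScenarioConfig, generate_scenario

__all__ = ["bsgmi_interpolation_accuracy"]


def bsgmi_interpolation_accuracy(
    seed: int,
    scenario: ScenarioConfig | None = None,
    n_trees: int = 500,
) -> float:
    """Median interim-year pixel accuracy (percent) of BSGMi on one scenario.

    Generates a seeded scenario, hands BSGMi only the endpoint extents, and
    scores each interim year's interpolated extent against the withheld true
    extent as the fraction of pixels whose BS/non-BS state matches; returns
    the median over interim years, in percent.
    """
    cfg = scenario if scenario is not None else ScenarioConfig()
    cfg = ScenarioConfig(**{**vars(cfg), "seed": int(seed)})
    bundle, truth = generate_scenario(cfg)
    series = run_bsgmi(bundle, BsgmiConfig(seed=int(seed), n_trees=n_trees))
    interim = bundle.years[1:-1]
    accs = [float((series[y] == truth.extent(y)).mean()) for y in interim]
    return 100.0 * float(np.median(accs))
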