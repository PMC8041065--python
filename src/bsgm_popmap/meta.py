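"""Weighted Importance Rank (WIR) meta-analysis of covariate importance.

Per-model permutation importances (Per.Inc.MSE) are not comparable across
independently fitted forests, so each model's covariates are ranked by
descending importance and the rank is divided by the model's covariate count:
WIR = rank / n, in (0, 1], lower = more important, the least important
covariate scoring exactly 1. Distributions of WIR are compared across years
or regions with Kruskal-Wallis omnibus tests, Dunn post hoc contrasts under
Holm correction, and per-model WIR differences between covariate pairs are
tested against a zero median with one-sample Wilcoxon signed-rank tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastSpec",
    "compute_wir",
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_one_sample",
    "holm_adjust",
    "wir_difference_table",
    "summarize_boxplots",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A WIR-difference contrast ``first minus second`` (positive differences
    mean the first covariate was *less* important), grouped by region or
    year, tested at level alpha."""

    first: str
    second: str
    grouping: str = "region"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def compute_wir(records: pd.DataFrame) -> pd.DataFrame:
    """Rank one model's importances and attach WIR = rank / n.

    ``records`` holds one model's ImportanceRecord rows (column
    ``per_inc_mse``). Ranks are descending in importance, ties averaged, so
    the most important covariate gets 1/n and the least important exactly 1.
    """
    if len(records) == 0:
        raise ValueError("empty importance table")
    out = records.copy()
    ranks = stats.rankdata(-out["per_inc_mse"].to_numpy(), method="average")
    out["rank"] = ranks
    out["n_covariates"] = len(out)
    out["wir"] = ranks / len(out)
    return out


def compute_wir_by_model(
    records: pd.DataFrame, model_keys: tuple[str, ...] = ("country_id", "year")
) -> pd.DataFrame:
    """Apply :func:`compute_wir` within each model (country-year) of a pooled
    importance table."""
    return (
        records.groupby(list(model_keys), group_keys=False)[records.columns]
        .apply(compute_wir)
        .reset_index(drop=True)
    )


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Kruskal-Wallis omnibus test: (H, df, p).

    Tie-corrected rank statistic; df = k - 1; p from the chi-square upper
    tail. Requires >= 2 groups and errors if all values are identical (the
    statistic is undefined).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.all(values == values[0]):
        raise ValueError("all values identical; Kruskal-Wallis statistic undefined")
    h, p = stats.kruskal(*samples)
    return float(h), int(labels.size - 1), float(p)


def dunn_posthoc(values, groups) -> pd.DataFrame:
    """Dunn's post hoc pairwise z tests on mean ranks, Holm-adjusted.

    For groups i, j with mean ranks Ri, Rj over the pooled ranking of N
    observations, z = (Ri - Rj) / sqrt(S * (1/ni + 1/nj)) where
    S = N(N+1)/12 - sum(t^3 - t) / (12 (N-1)) corrects for ties. Runs
    unconditionally; gate on the omnibus p for strict post hoc use.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    sizes = {g: int((groups == g).sum()) for g in labels}
    if any(n < 1 for n in sizes.values()):
        raise ValueError("every group needs at least one observation")
    n = values.size
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    s2 = n * (n + 1) / 12.0 - (tie_term / (12.0 * (n - 1)) if n > 1 else 0.0)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(s2 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame.from_records(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    return table


def _exact_signed_rank_p(ranks_pos_sum: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic under uniform sign
    flips, by convolution over the (doubled, hence integer) midranks."""
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    v2 = int(round(2 * ranks_pos_sum))
    mean2 = total / 2.0
    dev = abs(v2 - mean2)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - mean2) >= dev - 1e-9].sum())


def wilcoxon_one_sample(diffs, mu: float = 0.0, exact_max_n: int = 25) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of median(diffs) = mu.

    Zeros (after the mu shift) are discarded; absolute values are midranked.
    The null distribution is enumerated exactly (convolution over midranks,
    which handles ties) for n <= ``exact_max_n``, else the normal
    approximation with continuity and tie correction is used. Returns
    (V, two-sided p) with V the positive-rank sum.
    """
    d = np.asarray(diffs, dtype=float) - mu
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test uninformative")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(v, ranks)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        dev = abs(v - mean)
        z = max(dev - 0.5, 0.0) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(z)
    return v, float(min(p, 1.0))


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjustment: sort ascending, scale the i-th smallest by
    (m - i), take the running maximum, cap at 1, restore input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def wir_difference_table(
    wir_records: pd.DataFrame,
    contrast: ContrastSpec,
    model_keys: tuple[str, ...] = ("country_id", "year"),
) -> pd.DataFrame:
    """Per-model WIR differences ``first - second`` for one contrast.

    Models missing either covariate are skipped. Positive differences mean
    the first covariate of the pair was less important than the second
    (higher WIR = lower importance); the ``sign_convention`` column records
    this. Grouping columns (e.g. region) present in the input are carried
    through.
    """
    wide = wir_records.pivot_table(
        index=[k for k in (*model_keys, "region") if k in wir_records.columns],
        columns="covariate",
        values="wir",
    )
    missing = [c for c in (contrast.first, contrast.second) if c not in wide.columns]
    if missing:
        raise ValueError(f"contrast covariate(s) {missing} absent from every model")
    both = wide.dropna(subset=[contrast.first, contrast.second])
    out = both.reset_index()[[c for c in both.index.names]]
    out["difference"] = (both[contrast.first] - both[contrast.second]).to_numpy()
    out.attrs["sign_convention"] = "positive = first covariate less important than second"
    out.attrs["contrast"] = (contrast.first, contrast.second)
    return out


def contrast_tests(
    wir_records: pd.DataFrame, contrasts: list[ContrastSpec]
) -> pd.DataFrame:
    """One-sample Wilcoxon tests of each contrast's WIR differences against a
    zero median, per group, Holm-corrected within each contrast."""
    rows = []
    for spec in contrasts:
        try:
            diffs = wir_difference_table(wir_records, spec)
        except ValueError:
            # a contrast covariate retained in no model: nothing to test
            continue
        group_col = spec.grouping if spec.grouping in diffs.columns else None
        groups = diffs[group_col].unique() if group_col else [None]
        stats_rows = []
        for g in groups:
            d = diffs["difference"] if g is None else diffs.loc[diffs[group_col] == g, "difference"]
            d = d.to_numpy()
            if (d != 0).sum() == 0:
                continue
            v, p = wilcoxon_one_sample(d)
            stats_rows.append(
                {
                    "contrast": f"{spec.first} minus {spec.second}",
                    "group": g if g is not None else "all",
                    "n_models": d.size,
                    "median_difference": float(np.median(d)),
                    "V": v,
                    "p_raw": p,
                }
            )
        if stats_rows:
            sub = pd.DataFrame.from_records(stats_rows)
            sub["p_holm"] = holm_adjust(sub["p_raw"].to_numpy())
            sub["significant"] = sub["p_holm"] < spec.alpha
            rows.append(sub)
    if not rows:
        raise ValueError("no testable contrast produced any differences")
    return pd.concat(rows, ignore_index=True)


def summarize_boxplots(
    wir_records: pd.DataFrame, by: str, value_col: str = "wir"
) -> pd.DataFrame:
    """Boxplot summary per group: median, quartiles (linear interpolation,
    type 7), IQR, and whiskers at the most extreme data points within
    1.5 * IQR of the box."""
    rows = []
    for g, grp in wir_records.groupby(by):
        x = grp[value_col].to_numpy(dtype=float)
        if x.size == 0:
            continue
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        rows.append(
            {
                by: g,
                "n": x.size,
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": iqr,
                "whisker_low": lo,
                "whisker_high": hi,
            }
        )
    if not rows:
        raise ValueError("no nonempty groups")
    return pd.DataFrame.from_records(rows)
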