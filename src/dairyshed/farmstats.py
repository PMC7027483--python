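"""Farm-neighbourhood statistics and farm-type comparisons.

Zonal statistics of the forest-carbon layers are taken within circular
buffers (default 5 km) around farm locations: per-farm means over the
valid forest pixels whose centres fall inside the buffer. Farm indicators
are then rank-correlated (Spearman) with those neighbourhood statistics,
and farm types are compared pairwise with Wilcoxon rank-sum tests under
Holm multiple-testing correction, summarised by a compact letter display.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .raster import RasterLayer, crs_is_projected

#: indicator-indicator collinearity threshold flagged in correlation output
COLLINEARITY_RHO = 0.7


def neighbourhood_stats(
    farms: pd.DataFrame,
    layers: Mapping[str, RasterLayer],
    radius_m: float = 5000.0,
) -> pd.DataFrame:
    """Per-farm means of each layer within the circular neighbourhood.

    ``farms`` needs ``x``/``y`` columns in a projected CRS. A farm with no
    valid pixel of a layer within the radius gets NaN for that layer; the
    ``n_forest_pixels`` column counts valid pixels of the first layer.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    out = pd.DataFrame(index=farms.index)
    first = True
    for name, layer in layers.items():
        if not crs_is_projected(layer.grid.crs):
            raise ValueError("neighbourhood statistics require a projected CRS")
        xs, ys = layer.grid.pixel_centers(layer.shape)
        valid = layer.valid_mask
        px, py, pv = xs[valid], ys[valid], layer.values[valid]
        means = np.full(len(farms), np.nan)
        counts = np.zeros(len(farms), dtype=int)
        for i, (fx, fy) in enumerate(zip(farms["x"].to_numpy(), farms["y"].to_numpy())):
            inside = (px - fx) ** 2 + (py - fy) ** 2 <= radius_m**2
            counts[i] = inside.sum()
            if counts[i]:
                means[i] = pv[inside].mean()
        out[name] = means
        if first:
            out["n_forest_pixels"] = counts
            first = False
    return out


def indicator_correlations(
    survey: pd.DataFrame,
    nstats: pd.DataFrame,
    indicators: list[str] | None = None,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman correlations of farm indicators with neighbourhood layers.

    Returns a tidy frame (indicator, layer, rho, p, n); constant columns
    give NaN rho. Indicator pairs with |rho| >= 0.7 between themselves are
    flagged in the ``collinear_with`` column.
    """
    if indicators is None:
        indicators = [
            c
            for c in survey.columns
            if survey[c].dtype.kind in "fi" and c not in ("x", "y")
        ]
    layer_cols = [c for c in nstats.columns if c != "n_forest_pixels"]

    collinear: dict[str, list[str]] = {i: [] for i in indicators}
    for a, b in combinations(indicators, 2):
        pair = survey[[a, b]].dropna()
        if len(pair) >= min_pairs:
            rho, _ = stats.spearmanr(pair[a], pair[b])
            if np.isfinite(rho) and abs(rho) >= COLLINEARITY_RHO:
                collinear[a].append(b)
                collinear[b].append(a)

    rows = []
    for ind in indicators:
        for lay in layer_cols:
            pair = pd.concat([survey[ind], nstats[lay]], axis=1).dropna()
            n = len(pair)
            if n < min_pairs:
                rho, p = np.nan, np.nan
            else:
                with np.errstate(invalid="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore", stats.ConstantInputWarning)
                    rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
                if not np.isfinite(rho):
                    rho, p = np.nan, np.nan
            rows.append(
                {
                    "indicator": ind,
                    "layer": lay,
                    "rho": rho,
                    "p": p,
                    "n": n,
                    "collinear_with": ",".join(collinear[ind]),
                }
            )
    return pd.DataFrame(rows)


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment; never decreases a p-value."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def compact_letter_display(
    groups: list[str], significant: Mapping[tuple[str, str], bool]
) -> dict[str, str]:
    """Assign letters so groups share a letter iff not significantly different.

    Greedy insertion: each group joins every existing letter class it is
    compatible with (no significant difference to any member), opening a
    new class when none fits.
    """
    classes: list[list[str]] = []

    def differs(a, b):
        return significant.get((a, b), significant.get((b, a), False))

    for g in groups:
        placed = False
        for cls in classes:
            if not any(differs(g, other) for other in cls):
                cls.append(g)
                placed = True
        if not placed:
            classes.append([g])
    letters = {g: "" for g in groups}
    for i, cls in enumerate(classes):
        ch = chr(ord("a") + i)
        for g in cls:
            letters[g] += ch
    return letters


def farm_type_tests(
    survey: pd.DataFrame,
    nstats: pd.DataFrame,
    variables: list[str] | None = None,
    type_column: str = "farm_type",
    alpha: float = 0.05,
    min_group: int = 5,
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests between farm types, Holm-adjusted.

    Tests every variable (defaulting to all neighbourhood layers) across
    all pairs of farm types with >= ``min_group`` farms; smaller types are
    excluded with a warning column. Mid-ranks with normal approximation
    and tie correction are used for n > 20, the exact distribution
    otherwise. Returns the pairwise table plus per-variable compact letter
    groupings.
    """
    data = pd.concat([survey[[type_column]], nstats], axis=1)
    if variables is None:
        variables = [c for c in nstats.columns if c != "n_forest_pixels"]

    sizes = data[type_column].value_counts()
    kept = [t for t in sizes.index if sizes[t] >= min_group]
    if len(kept) < 2:
        raise ValueError("need at least 2 farm types with enough farms")
    kept = sorted(kept)

    rows = []
    for var in variables:
        pvals, pairs = [], []
        for a, b in combinations(kept, 2):
            xa = data.loc[data[type_column] == a, var].dropna()
            xb = data.loc[data[type_column] == b, var].dropna()
            method = "exact" if (len(xa) <= 20 and len(xb) <= 20 and
                                 len(np.unique(np.concatenate([xa, xb]))) == len(xa) + len(xb)) \
                else "asymptotic"
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            pvals.append(res.pvalue)
            pairs.append((a, b, res.statistic, len(xa), len(xb)))
        adj = holm_adjust(np.array(pvals))
        sig = {}
        for (a, b, u, na, nb), p_raw, p_adj in zip(pairs, pvals, adj):
            sig[(a, b)] = p_adj < alpha
            rows.append(
                {
                    "variable": var,
                    "type_a": a,
                    "type_b": b,
                    "statistic": float(u),
                    "n_a": na,
                    "n_b": nb,
                    "p": p_raw,
                    "p_holm": p_adj,
                    "significant": p_adj < alpha,
                }
            )
        letters = compact_letter_display(kept, sig)
        for r in rows[-len(pairs):]:
            r["letters_a"] = letters[r["type_a"]]
            r["letters_b"] = letters[r["type_b"]]
    return pd.DataFrame(rows)
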