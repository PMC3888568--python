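"""Factor grid, distribution summaries, and variance-based sensitivity.

The mortality pipeline evaluates the total annual excess deaths y for every
combination of six discrete factors: emission scenario (2 levels),
calibration method (2), heat wave definition (4), population projection
(4), attributable-risk set (9), and projection year (3) — a complete
balanced 2×2×4×4×9×3 = 1,728-cell grid.

On such a grid the first-order (main-effect) sensitivity index of factor
x_i is the ANOVA quantity

    S_i = V(E[y | x_i]) / V(y),

the variance over the levels of x_i of the conditional mean of y, divided
by the total (population) variance of y. Higher-order terms are pooled into
a single interaction residual 1 − Σ S_i, which is exactly zero when y is
additive in the factors. Population variances are used throughout so the
decomposition is exactly additive on balanced grids.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

GRID_FACTORS = ["rcp", "calibration", "hwd", "pop_scenario", "ar_set", "year"]
RESPONSE = "total_excess_deaths"


def build_grid(
    estimates: pd.DataFrame,
    factors: dict[str, list] | None = None,
    response: str = RESPONSE,
) -> pd.DataFrame:
    """Validate a factor grid of scenario estimates.

    ``factors`` maps factor name → expected levels (inferred from the data
    when omitted). Raises with the list of absent cells if any combination
    is missing or duplicated; returns the grid sorted by factor columns.
    """
    if factors is None:
        factors = {f: sorted(estimates[f].unique().tolist()) for f in GRID_FACTORS}
    names = list(factors)
    counts = estimates.groupby(names, sort=True).size()
    expected = list(itertools.product(*(factors[f] for f in names)))
    missing = [cell for cell in expected if cell not in counts.index]
    if missing:
        raise ValueError(f"missing grid cells ({len(missing)}): {missing[:10]} ...")
    if (counts > 1).any() or len(estimates) != len(expected):
        raise ValueError("grid has duplicated cells")
    if estimates[response].isna().any():
        raise ValueError("grid contains missing responses")
    return estimates.sort_values(names).reset_index(drop=True)


def summarize_distribution(
    values, ci: float = 0.95, thresholds: tuple[float, ...] = ()
) -> dict:
    """Mean, sample SD, empirical CI, and cumulative probabilities.

    The CI bounds are the empirical (1−ci)/2 and 1−(1−ci)/2 quantiles
    (linear interpolation); ``thresholds`` adds P(y < t) for each t.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    alpha = (1.0 - ci) / 2.0
    out = {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "ci_lo": float(np.quantile(v, alpha)),
        "ci_hi": float(np.quantile(v, 1.0 - alpha)),
    }
    out["cumulative"] = {float(t): float((v < t).mean()) for t in thresholds}
    return out


def variance_decomposition(
    grid: pd.DataFrame,
    factors: list[str] | None = None,
    response: str = RESPONSE,
) -> pd.DataFrame:
    """First-order sensitivity indices on a balanced complete grid.

    Returns one row per factor (``factor, s_i, variance``) plus a final
    ``interactions`` row holding the residual 1 − Σ S_i. With zero total
    variance all indices are reported as 0 with a warning.
    """
    factors = GRID_FACTORS if factors is None else list(factors)
    y = grid[response].to_numpy(dtype=float)
    total_var = float(y.var())  # population variance
    rows = []
    if total_var == 0.0:
        warnings.warn("zero total variance; all sensitivity indices set to 0", stacklevel=2)
        for f in factors:
            rows.append({"factor": f, "s_i": 0.0, "variance": 0.0})
        rows.append({"factor": "interactions", "s_i": 0.0, "variance": 0.0})
        return pd.DataFrame(rows)
    for f in factors:
        level_means = grid.groupby(f)[response].mean()
        # balanced grid: every level weighs equally
        v = float(level_means.to_numpy().var())
        rows.append({"factor": f, "s_i": v / total_var, "variance": v})
    s_sum = sum(r["s_i"] for r in rows)
    rows.append(
        {
            "factor": "interactions",
            "s_i": 1.0 - s_sum,
            "variance": total_var * (1.0 - s_sum),
        }
    )
    return pd.DataFrame(rows)
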