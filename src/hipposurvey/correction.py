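"""Correction factors and observer-by-photo survey-effort optimization.

A raw photo count underestimates a school because part of the animals is
submerged or missed.  Two multiplicative correction factors are computed
as inverse per-unit detection rates:

* factor 1 — denominator is the school total estimated for that unit's
  flight: corrects a count to the animals present during the flight;
* factor 2 — denominator is the whole-population total (by default the
  maximum of the flight totals): additionally absorbs animals roaming in
  and out of the surveyed pool.

The effort optimization asks how many observers and photos a survey needs:
for each cell (o observers, p photos) it repeatedly samples o observers
and p photos, takes the best (maximum) detection rate among the o x p
units — the operational rule "keep the highest count" — and scores the
cell by the mean deviation of that best rate from 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rates import compute_rates

__all__ = [
    "factor_from_detection",
    "correction_factors",
    "compare_factors",
    "ErrorMatrix",
    "combination_simulation",
    "recommend_design",
    "plot_error_matrix",
]

_Z95 = 1.959963984540054


def factor_from_detection(detection: float) -> float:
    """Correction factor implied by a mean detection fraction (1/DR)."""
    if detection <= 0:
        raise ValueError("detection must be > 0")
    return 1.0 / detection


def _per_unit_factors(rates: pd.DataFrame, population_total: float):
    """Per-unit factor-1 and factor-2 values; zero-count units dropped."""
    nonzero = rates["tot_num"] > 0
    sub = rates[nonzero]
    f1 = (sub["est_pop"] / sub["tot_num"]).to_numpy(float)
    f2 = (population_total / sub["tot_num"]).to_numpy(float)
    return f1, f2, int((~nonzero).sum()), sub


def correction_factors(units: pd.DataFrame,
                       population_total: float | None = None) -> pd.DataFrame:
    """Mean correction factors 1 and 2 with 95% CIs, by observer group.

    ``population_total`` defaults to the maximum est_pop in the table (the
    largest flight total); pass a census value to override.  Units with a
    zero count are excluded (their factor is undefined) and counted in the
    ``n_excluded`` column.
    """
    rates = units if "dr" in units else compute_rates(units)
    if population_total is None:
        population_total = float(rates["est_pop"].max())
    groups = {
        "all": rates,
        "experienced": rates[rates["experienced"] == 0],
        "inexperienced": rates[rates["experienced"] == 1],
    }
    rows = []
    for gname, sub in groups.items():
        if len(sub) == 0:
            raise ValueError(f"observer group {gname!r} is empty")
        f1, f2, n_excluded, _ = _per_unit_factors(sub, population_total)
        for kind, vals in ((1, f1), (2, f2)):
            m = float(np.mean(vals))
            # CI undefined for a single unit
            se = (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                  if len(vals) > 1 else np.nan)
            rows.append(
                {
                    "factor": kind,
                    "group": gname,
                    "mean": m,
                    "ci_lo": m - _Z95 * se,
                    "ci_hi": m + _Z95 * se,
                    "n_units": len(vals),
                    "n_excluded": n_excluded,
                }
            )
    return pd.DataFrame(rows)


def compare_factors(units: pd.DataFrame,
                    population_total: float | None = None) -> dict:
    """Welch two-sided t-test between per-unit factor-1 and factor-2 values."""
    rates = units if "dr" in units else compute_rates(units)
    if population_total is None:
        population_total = float(rates["est_pop"].max())
    f1, f2, _, _ = _per_unit_factors(rates, population_total)
    if len(f1) < 2 or len(f2) < 2:
        raise ValueError("need >= 2 units per side for a t-test")
    if np.std(f1) == 0 and np.std(f2) == 0:
        return {"statistic": np.nan, "df": np.nan, "pvalue": np.nan,
                "degenerate": True}
    res = stats.ttest_ind(f1, f2, equal_var=False)
    return {
        "statistic": float(res.statistic),
        "df": float(res.df),
        "pvalue": float(res.pvalue),
        "degenerate": False,
    }


@dataclass
class ErrorMatrix:
    """Resampled error surface over (observers, photos) effort cells."""

    table: pd.DataFrame  # columns: n_observers, n_photos, mean_error,
    #                      sd_error, mean_best_dr, correction_factor, reps
    metric: str
    reps: int

    def cell(self, n_observers: int, n_photos: int) -> dict:
        row = self.table[
            (self.table["n_observers"] == n_observers)
            & (self.table["n_photos"] == n_photos)
        ]
        if row.empty:
            raise KeyError((n_observers, n_photos))
        return row.iloc[0].to_dict()

    def pivot(self, value: str = "mean_error") -> pd.DataFrame:
        return self.table.pivot(index="n_observers", columns="n_photos",
                                values=value)


def combination_simulation(units: pd.DataFrame,
                           max_observers: int = 3,
                           max_photos: int = 10,
                           reps: int = 100,
                           metric: str = "abs_dev",
                           rng: np.random.Generator | int | None = None
                           ) -> ErrorMatrix:
    """Best-of-combination resampling over the observer x photo grid.

    For every cell (o, p) and every replicate: draw o observers and p
    photos without replacement, collect the o x p unit detection rates and
    keep the maximum.  Cell error is the mean over replicates of
    ``|1 - best DR|`` (``metric='abs_dev'``) or ``1 - mean(best DR)``
    (``metric='one_minus_mean'``).  Also reports the implied correction
    factor 1 / mean(best DR) per cell.
    """
    rates = units if "dr" in units else compute_rates(units)
    gen = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    if metric not in ("abs_dev", "one_minus_mean"):
        raise ValueError(f"unknown metric {metric!r}")
    observers = np.sort(rates["observer_id"].unique())
    photos = np.sort(rates["photo_id"].unique())
    if max_observers > len(observers) or max_photos > len(photos):
        raise ValueError("requested grid exceeds the observer/photo pool")
    dr = rates.pivot_table(index="observer_id", columns="photo_id",
                           values="dr")
    if dr.isna().any().any():
        raise ValueError("every observer must have reviewed every photo")
    drm = dr.loc[observers, photos].to_numpy()

    rows = []
    for o in range(1, max_observers + 1):
        for p in range(1, max_photos + 1):
            best = np.empty(reps)
            for r in range(reps):
                oi = gen.choice(len(observers), size=o, replace=False)
                pi = gen.choice(len(photos), size=p, replace=False)
                best[r] = drm[np.ix_(oi, pi)].max()
            err = np.abs(1.0 - best)
            mean_best = float(np.mean(best))
            mean_err = (float(np.mean(err)) if metric == "abs_dev"
                        else float(1.0 - mean_best))
            rows.append(
                {
                    "n_observers": o,
                    "n_photos": p,
                    "mean_error": mean_err,
                    "sd_error": float(np.std(err, ddof=1)),
                    "mean_best_dr": mean_best,
                    "correction_factor": (1.0 / mean_best
                                          if mean_best > 0 else np.inf),
                    "reps": reps,
                }
            )
    return ErrorMatrix(pd.DataFrame(rows), metric=metric, reps=reps)


def recommend_design(matrix: ErrorMatrix,
                     error_threshold: float = 0.05,
                     w_observer: float = 1.0,
                     w_photo: float = 1.0) -> tuple[int, int] | None:
    """Cheapest effort cell meeting the error threshold.

    Cost is ``w_observer * o + w_photo * p``; ties prefer fewer observers
    (an extra trained observer is usually harder to find than an extra
    photo).  Returns ``None`` when no cell qualifies.
    """
    tab = matrix.table
    if tab.empty:
        raise ValueError("empty error matrix")
    ok = tab[tab["mean_error"] <= error_threshold].copy()
    if ok.empty:
        return None
    ok["cost"] = w_observer * ok["n_observers"] + w_photo * ok["n_photos"]
    ok = ok.sort_values(["cost", "n_observers", "n_photos"])
    best = ok.iloc[0]
    return int(best["n_observers"]), int(best["n_photos"])


def plot_error_matrix(matrix: ErrorMatrix, path=None, ax=None):
    """Heat map of the error surface (percent)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    piv = matrix.pivot() * 100.0
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    im = ax.imshow(piv.to_numpy(), origin="lower", aspect="auto",
                   cmap="viridis",
                   extent=(0.5, piv.columns.max() + 0.5,
                           0.5, piv.index.max() + 0.5))
    ax.set_xlabel("photos reviewed")
    ax.set_ylabel("observers")
    ax.figure.colorbar(im, ax=ax, label="mean error (%)")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
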