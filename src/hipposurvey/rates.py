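"""Per-unit detection rates and certainty levels, and observer summaries.

For each experimental unit (one photo reviewed by one observer):

* detection rate  DR = tot.num / est.pop — the observer's total count
  (definite + possible marks) over the school total estimated for that
  flight.  DR can exceed 1 when an observer over-counts.
* level of certainty  LC = def.obs / tot.num — the definite fraction of
  the observer's marks; undefined when the observer counted nothing.

Summaries report per-observer and per-experience-group means with normal
approximation 95% confidence intervals, the presentation used for
observer-effect tables in aerial-count studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_rates",
    "summarize_by_observer",
    "group_means",
    "review_time_stats",
]

_Z95 = 1.959963984540054


def compute_rates(units: pd.DataFrame) -> pd.DataFrame:
    """Append tot_num, DR and LC columns to the unit table.

    LC is NaN for units with tot_num = 0 (kept in the table, excluded from
    LC aggregation downstream).  est_pop must be positive everywhere.
    """
    units = units.copy()
    for col in ("n_definite", "n_possible", "est_pop"):
        if (units[col] < 0).any():
            raise ValueError(f"{col} must be non-negative")
    if (units["est_pop"] <= 0).any():
        raise ValueError("est_pop must be > 0 for every unit")
    units["tot_num"] = units["n_definite"] + units["n_possible"]
    units["dr"] = units["tot_num"] / units["est_pop"]
    with np.errstate(invalid="ignore", divide="ignore"):
        units["lc"] = np.where(
            units["tot_num"] > 0,
            units["n_definite"] / units["tot_num"],
            np.nan,
        )
    return units


def _mean_ci(x: np.ndarray) -> dict:
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    n = len(x)
    out = {"mean": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
           "min": np.nan, "max": np.nan, "n": n}
    if n == 0:
        return out
    m = float(np.mean(x))
    out.update(mean=m, min=float(np.min(x)), max=float(np.max(x)))
    if n >= 2:
        se = float(np.std(x, ddof=1) / np.sqrt(n))
        out.update(ci_lo=m - _Z95 * se, ci_hi=m + _Z95 * se)
    return out


def summarize_by_observer(rates: pd.DataFrame,
                          bootstrap: int = 0,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Observer-level summary of DR and LC (Table-of-observers analogue).

    One row per observer: experience flag, total animals counted, mean DR
    and LC with 95% CI (normal approximation by default; set
    ``bootstrap`` > 0 for a percentile bootstrap), and min/max.  Units with
    tot_num = 0 contribute DR = 0 but are excluded from LC statistics.
    """
    if "dr" not in rates:
        rates = compute_rates(rates)
    rows = []
    for obs_id, grp in rates.groupby("observer_id"):
        dr = _mean_ci(grp["dr"].to_numpy())
        lc = _mean_ci(grp["lc"].to_numpy())
        row = {
            "observer_id": obs_id,
            "experienced": int(grp["experienced"].iloc[0]),
            "n_units": len(grp),
            "total_counted": int(grp["tot_num"].sum()),
        }
        for name, d in (("dr", dr), ("lc", lc)):
            row.update({f"{name}_{k}": v for k, v in d.items() if k != "n"})
        if bootstrap > 0:
            gen = rng or np.random.default_rng(0)
            for name in ("dr", "lc"):
                x = grp[name].dropna().to_numpy()
                if len(x) >= 2:
                    means = [
                        np.mean(gen.choice(x, size=len(x), replace=True))
                        for _ in range(bootstrap)
                    ]
                    row[f"{name}_ci_lo"] = float(np.percentile(means, 2.5))
                    row[f"{name}_ci_hi"] = float(np.percentile(means, 97.5))
        rows.append(row)
    return pd.DataFrame(rows)


def group_means(rates: pd.DataFrame) -> pd.DataFrame:
    """Experience-group DR/LC means, unit-weighted and observer-weighted.

    The unit-weighted mean pools all units of a group; the
    observer-weighted mean averages the per-observer means, giving each
    observer equal weight regardless of unit count.  Both are reported
    because group-level summaries in the literature rarely say which one
    they are.
    """
    if "dr" not in rates:
        rates = compute_rates(rates)
    per_obs = summarize_by_observer(rates)
    rows = []
    groups = {"all": rates, "experienced": rates[rates["experienced"] == 0],
              "inexperienced": rates[rates["experienced"] == 1]}
    for name, sub in groups.items():
        if len(sub) == 0:
            continue
        obs_sub = per_obs[per_obs["observer_id"].isin(sub["observer_id"])]
        d = _mean_ci(sub["dr"].to_numpy())
        l = _mean_ci(sub["lc"].to_numpy())
        rows.append(
            {
                "group": name,
                "n_units": len(sub),
                "n_observers": sub["observer_id"].nunique(),
                "dr_mean": d["mean"], "dr_ci_lo": d["ci_lo"],
                "dr_ci_hi": d["ci_hi"],
                "dr_mean_by_observer": float(obs_sub["dr_mean"].mean()),
                "lc_mean": l["mean"], "lc_ci_lo": l["ci_lo"],
                "lc_ci_hi": l["ci_hi"],
                "lc_mean_by_observer": float(obs_sub["lc_mean"].mean()),
            }
        )
    return pd.DataFrame(rows)


def review_time_stats(seconds) -> dict:
    """Mean and SD (n-1) of per-photo review times, plus rounded values."""
    x = np.asarray(seconds, float)
    if len(x) < 2:
        raise ValueError("need >= 2 review times")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return {
        "mean": mean,
        "sd": sd,
        "mean_rounded": int(round(mean)),
        "sd_rounded": int(round(sd)),
        "n": len(x),
    }
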