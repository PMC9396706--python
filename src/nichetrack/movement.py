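"""Track-based movement metrics: hourly speeds, trip distances, seasonal
summaries and observed-vs-model regressions.

Hourly movement distance is only computed from pairs of successive fixes
whose time gap falls in a configured window (default the closed interval
30-60 min), which screens out duty-cycle gaps.  Seasonal speed summaries are
computed over per-animal means — the animal, not the step, is the sampling
unit — with a normal-approximation 95% CI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .geo import haversine_km
from .nsd import day_of_year

__all__ = ["hourly_speeds", "trip_distance", "summarize_speeds",
           "regress_observed_vs_model"]


def hourly_speeds(traj: pd.DataFrame,
                  interval_window: tuple[float, float] = (0.5, 1.0),
                  season: str | None = None) -> pd.DataFrame:
    """Per-step speeds (km/h) for steps whose duration lies in the closed
    ``interval_window`` (hours).  Speed = great-circle step length / gap."""
    ts = pd.to_datetime(traj["timestamp"])
    dt_h = ts.diff().dt.total_seconds().to_numpy() / 3600.0
    if np.any(dt_h[1:] <= 0):
        raise ValueError("timestamps must be strictly increasing")
    lon = traj["lon"].to_numpy(float)
    lat = traj["lat"].to_numpy(float)
    step = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    gap = dt_h[1:]
    lo, hi = interval_window
    keep = (gap >= lo) & (gap <= hi)
    t_mid = day_of_year(traj["timestamp"])[1:]
    out = pd.DataFrame({
        "t": t_mid[keep],
        "timestamp": ts.to_numpy()[1:][keep],
        "speed_kmh": step[keep] / gap[keep],
    })
    if "animal_id" in traj.columns:
        out.insert(0, "animal_id", traj["animal_id"].to_numpy()[1:][keep])
    if season is not None:
        out["season"] = season
    return out


def trip_distance(traj: pd.DataFrame, start: float, end: float) -> float:
    """Cumulative great-circle path length (km) over fixes with day-of-year
    in [start, end] — the along-track migration trip distance."""
    if start >= end:
        raise ValueError("start must be before end")
    t = day_of_year(traj["timestamp"])
    sel = (t >= start) & (t <= end)
    lon = traj["lon"].to_numpy(float)[sel]
    lat = traj["lat"].to_numpy(float)[sel]
    if lon.size < 2:
        import warnings
        warnings.warn("fewer than two fixes in the trip interval; distance 0")
        return 0.0
    return float(np.sum(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])))


def summarize_speeds(samples: pd.DataFrame) -> pd.DataFrame:
    """Season-level speed summary across animals.

    ``samples`` has columns ``animal_id, season, speed_kmh`` (any number of
    steps per animal).  Per season: the mean of per-animal mean speeds, its
    normal 95% CI across animals, and n (animals).  CI is NaN-flagged when
    only one animal contributes.
    """
    per_animal = (samples.groupby(["season", "animal_id"], sort=True)["speed_kmh"]
                  .mean().rename("mean_speed").reset_index())
    rows = []
    for season, grp in per_animal.groupby("season", sort=True):
        vals = grp["mean_speed"].to_numpy()
        n = vals.size
        mean = float(np.mean(vals))
        if n >= 2:
            se = float(np.std(vals, ddof=1)) / np.sqrt(n)
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
        else:
            lo = hi = np.nan
        rows.append({"season": season, "mean_kmh": mean, "ci_lo": lo,
                     "ci_hi": hi, "n_animals": n})
    return pd.DataFrame(rows)


def ci_overlap(summary: pd.DataFrame, season_a: str, season_b: str) -> bool:
    """Whether the 95% CIs of two seasons overlap."""
    s = summary.set_index("season")
    a, b = s.loc[season_a], s.loc[season_b]
    if np.isnan(a["ci_lo"]) or np.isnan(b["ci_lo"]):
        raise ValueError("CI undefined for a season with one animal")
    return bool(a["ci_lo"] <= b["ci_hi"] and b["ci_lo"] <= a["ci_hi"])


def regress_observed_vs_model(x, y) -> dict:
    """OLS of an observed migration metric on its model-based surrogate.

    Returns slope (beta), intercept, and R^2.  Requires >= 3 pairs and
    non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the model metric: slope undefined")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "n": int(x.size)}
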