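"""Seeded synthetic data generators.

The generators emulate the study system the package is built for: a migratory
waterbird that winters in a subtropical coastal range, breeds in a northern
temperate range ~1000-2300 km away, and is tracked by satellite transmitters
that duty-cycle (bursts of hourly fixes every two days for most of the year,
every ten days in late summer) and report positions with Argos-class-dependent
error.  Climate rasters are drawn so that seasonal temperature and
precipitation distributions are strongly separated while wind speed is nearly
identical between seasons — the structure the niche-overlap analysis is meant
to detect.

Trajectories are plain :class:`pandas.DataFrame` objects with columns
``animal_id, timestamp, lon, lat, lc_class`` and, for synthetic tracks,
``true_lon, true_lat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import aeqd_inverse
from .nsd import double_sigmoid, single_sigmoid

BASE_YEAR = 2001  # arbitrary non-leap year anchoring day-of-year to timestamps

#: Default isotropic measurement error SD (km) per Argos location class.
ARGOS_CLASS_SD_KM = {"LC3": 0.25, "LC2": 0.5, "LC1": 1.5, "LC0": 5.0}

#: Default class mix of a mid-quality Argos transmitter.
ARGOS_CLASS_PROBS = {"LC3": 0.2, "LC2": 0.3, "LC1": 0.3, "LC0": 0.2}


@dataclass(frozen=True)
class SamplingBlock:
    """Duty-cycle block: a burst of hourly fixes of length ``burst_hours``
    starting every ``every_hours``, active between ``start_day`` and
    ``end_day`` (day of year, inclusive)."""

    every_hours: float
    burst_hours: int
    start_day: int
    end_day: int


#: Burst of 6 hourly fixes every 48 h from January to mid-June and October to
#: December, every 240 h (10 days) from mid-June through September.
DEFAULT_SAMPLING = (
    SamplingBlock(48.0, 6, 1, 166),
    SamplingBlock(240.0, 6, 167, 273),
    SamplingBlock(48.0, 6, 274, 365),
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic migratory trajectory."""

    winter_centre: tuple[float, float] = (-90.5, 32.5)   # lon, lat (deg)
    summer_centre: tuple[float, float] = (-97.0, 47.0)
    #: day-of-year (onset, end); None disables that migration (resident range)
    spring_window: tuple[int, int] | None = (110, 140)
    autumn_window: tuple[int, int] | None = (270, 300)
    step_sd_km: float = 4.0          # within-range daily movement scale
    attraction_days: float = 2.0     # relaxation time toward the range centre
    migration_speed_km_day: float = 150.0
    sampling: tuple[SamplingBlock, ...] = DEFAULT_SAMPLING
    argos_class_probs: dict[str, float] = field(
        default_factory=lambda: dict(ARGOS_CLASS_PROBS))
    argos_class_sd_km: dict[str, float] = field(
        default_factory=lambda: dict(ARGOS_CLASS_SD_KM))
    seed: int = 0
    animal_id: str = "sim01"

    def __post_init__(self):
        for w in (self.spring_window, self.autumn_window):
            if w is not None and not (1 <= w[0] < w[1] <= 365):
                raise ValueError(f"migration window {w} outside [1, 365]")
        if (self.spring_window is not None and self.autumn_window is not None
                and self.spring_window[1] > self.autumn_window[0]):
            raise ValueError("spring and autumn windows overlap")
        if self.autumn_window is not None and self.spring_window is None:
            raise ValueError("autumn migration requires a spring window")
        if abs(sum(self.argos_class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("argos_class_probs must sum to 1")
        if any(sd < 0 for sd in self.argos_class_sd_km.values()):
            raise ValueError("argos class SDs must be >= 0")
        if self.step_sd_km < 0:
            raise ValueError("step_sd_km must be >= 0")


def _fix_times_hours(sampling) -> np.ndarray:
    """Hours since Jan 1 00:00 of every scheduled fix."""
    times = []
    for blk in sampling:
        t0 = (blk.start_day - 1) * 24.0
        t_end = blk.end_day * 24.0
        burst = t0
        while burst < t_end:
            for h in range(blk.burst_hours):
                t = burst + h
                if t < t_end:
                    times.append(t)
            burst += blk.every_hours
    times = np.unique(np.asarray(times, dtype=float))
    return times


def _target_centre_km(t_days: float, cfg: SimConfig, d_vec: np.ndarray) -> np.ndarray:
    """Attraction-centre position (planar km, origin at winter centre) at time t.

    From the spring onset the centre travels toward the summer range at
    ``migration_speed_km_day``; from the autumn onset it travels back.
    Outside the travel legs it sits on the seasonal range.
    """
    dist = float(np.hypot(*d_vec))
    if dist == 0 or cfg.spring_window is None:
        return np.zeros(2)
    unit = d_vec / dist
    s0 = cfg.spring_window[0]
    if t_days < s0 - 1:
        return np.zeros(2)
    progress = min(dist, (t_days - (s0 - 1)) * cfg.migration_speed_km_day)
    if cfg.autumn_window is not None:
        a0 = cfg.autumn_window[0]
        if t_days >= a0 - 1:
            reached = min(dist, (a0 - s0) * cfg.migration_speed_km_day)
            progress = max(0.0, reached - (t_days - (a0 - 1)) * cfg.migration_speed_km_day)
    return unit * progress


def simulate_migratory_path(config: SimConfig) -> pd.DataFrame:
    """Simulate the true positions of one migratory annual cycle.

    The bird performs a Gaussian random walk relaxing (time scale
    ``attraction_days``) toward an attraction centre that sits on the winter
    range, moves to the summer range during the spring window at the
    configured speed, and returns during the autumn window.  Fixes are emitted
    on the duty-cycle schedule.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    t_hours = _fix_times_hours(config.sampling)
    if t_hours.size == 0:
        raise ValueError("sampling schedule produced no fixes")
    from .geo import aeqd_forward

    dx, dy = aeqd_forward(
        config.summer_centre[0], config.summer_centre[1],
        config.winter_centre[0], config.winter_centre[1],
    )
    d_vec = np.array([float(dx), float(dy)])

    pos = np.zeros(2)
    xs = np.empty(t_hours.size)
    ys = np.empty(t_hours.size)
    t_prev = t_hours[0] / 24.0
    for i, th in enumerate(t_hours):
        t_days = th / 24.0
        dt = t_days - t_prev
        centre = _target_centre_km(t_days, config, d_vec)
        if dt > 0 and (config.step_sd_km > 0 or config.attraction_days > 0):
            rho = np.exp(-dt / config.attraction_days) if config.attraction_days > 0 else 0.0
            sd = config.step_sd_km * np.sqrt(dt)
            pos = centre + rho * (pos - centre) + rng.normal(0.0, sd, size=2)
        else:
            pos = centre + (pos - centre)
        if config.step_sd_km == 0:
            pos = centre
        xs[i], ys[i] = pos
        t_prev = t_days

    lon, lat = aeqd_inverse(xs, ys, config.winter_centre[0], config.winter_centre[1])
    start = pd.Timestamp(f"{BASE_YEAR}-01-01", tz="UTC")
    ts = start + pd.to_timedelta(t_hours, unit="h")
    return pd.DataFrame(
        {
            "animal_id": config.animal_id,
            "timestamp": ts,
            "lon": lon,
            "lat": lat,
            "lc_class": pd.NA,
            "true_lon": lon,
            "true_lat": lat,
        }
    )


def corrupt_with_argos_error(traj: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Assign Argos location classes and add class-dependent isotropic
    Gaussian position error (in a local planar frame per fix)."""
    if "true_lon" not in traj.columns:
        raise ValueError("trajectory has no true positions to corrupt")
    classes = sorted(config.argos_class_probs)
    probs = np.array([config.argos_class_probs[c] for c in classes])
    for c in classes:
        if c not in config.argos_class_sd_km:
            raise ValueError(f"no measurement SD configured for class {c!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(traj)
    draw = rng.choice(len(classes), size=n, p=probs)
    sds = np.array([config.argos_class_sd_km[c] for c in classes])[draw]
    ex = rng.normal(0.0, 1.0, size=n) * sds
    ey = rng.normal(0.0, 1.0, size=n) * sds
    out = traj.copy()
    lon = traj["true_lon"].to_numpy(float)
    lat = traj["true_lat"].to_numpy(float)
    new_lon = np.empty(n)
    new_lat = np.empty(n)
    for i in range(n):
        new_lon[i], new_lat[i] = aeqd_inverse(ex[i], ey[i], lon[i], lat[i])
    out["lon"] = new_lon
    out["lat"] = new_lat
    out["lc_class"] = np.array(classes, dtype=object)[draw]
    return out


def simulate_nsd_series(
    params: dict,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    animal_id: str = "sim01",
) -> pd.DataFrame:
    """Evaluate a single or double logistic NSD curve at ``times`` (day of
    year) and add optional Gaussian noise.

    ``params`` holds either ``delta, theta, phi`` (single, spring-only rise)
    or ``delta, theta_s, theta_a, phi_s, phi_a`` (rise-then-return annual
    curve).  Returns a frame with columns ``t`` and ``nsd_km2``.
    """
    times = np.asarray(times, dtype=float)
    if "theta_s" in params:
        for k in ("phi_s", "phi_a"):
            if params[k] <= 0:
                raise ValueError(f"{k} must be > 0")
        y = double_sigmoid(times, params["delta"], params["theta_s"],
                           params["theta_a"], params["phi_s"], params["phi_a"])
    else:
        if params["phi"] <= 0:
            raise ValueError("phi must be > 0")
        y = single_sigmoid(times, params["delta"], params["theta"], params["phi"])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=times.shape)
    return pd.DataFrame({"t": times, "nsd_km2": y, "animal_id": animal_id})


# ---------------------------------------------------------------------------
# climate rasters
# ---------------------------------------------------------------------------

CLIMATE_VARS = ("tmin", "tmax", "precip", "wind")


@dataclass
class ClimateRaster:
    """Regular lon/lat grid of seasonal climate normals.

    ``values`` maps each of tmin/tmax (degC), precip (mm), wind (m/s) to a
    2-D array indexed [row, col] with row 0 at the southern edge.
    """

    west: float
    south: float
    cell_size: float
    values: dict[str, np.ndarray]
    season: str = ""

    def __post_init__(self):
        shapes = {v.shape for v in self.values.values()}
        if len(shapes) != 1:
            raise ValueError("climate variables on inconsistent grids")
        if np.any(self.values["tmin"] > self.values["tmax"]):
            raise ValueError("tmin exceeds tmax in some cells")
        if np.any(self.values["precip"] < 0) or np.any(self.values["wind"] < 0):
            raise ValueError("precipitation and wind must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.values.values())).shape

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        nrow, ncol = self.shape
        return (self.west, self.south,
                self.west + ncol * self.cell_size,
                self.south + nrow * self.cell_size)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        nrow, ncol = self.shape
        lon = self.west + (np.arange(ncol) + 0.5) * self.cell_size
        lat = self.south + (np.arange(nrow) + 0.5) * self.cell_size
        return lon, lat

    def table(self) -> pd.DataFrame:
        """All cells as an environment table (one row per cell)."""
        out = {v: self.values[v].ravel() for v in CLIMATE_VARS}
        df = pd.DataFrame(out)
        df["season"] = self.season
        return df


@dataclass(frozen=True)
class ClimateConfig:
    """Per-season Gaussian means/SDs for each climate variable.

    Defaults encode the analysis's study conditions: winter (subtropical
    coast, Nov-Feb normals) and summer (northern temperate plains, Jun-Aug
    normals) temperature and precipitation strongly separated, wind speed
    nearly identical (winter 3.33 +/- 0.4 m/s, summer 3.26 +/- 0.34 m/s).
    """

    winter: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "tmin": (4.0, 1.0), "tmax": (16.0, 1.0),
        "precip": (130.0, 12.0), "wind": (3.33, 0.4)})
    summer: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "tmin": (12.0, 1.0), "tmax": (27.0, 1.0),
        "precip": (65.0, 8.0), "wind": (3.26, 0.34)})
    winter_bbox: tuple[float, float, float, float] = (-94.0, 29.0, -88.0, 34.0)
    summer_bbox: tuple[float, float, float, float] = (-100.0, 44.0, -94.0, 49.0)
    cell_size: float = 0.1

    def __post_init__(self):
        for season in (self.winter, self.summer):
            for var, (_, sd) in season.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {var}")


def _draw_raster(rng, bbox, cell_size, spec, season) -> ClimateRaster:
    west, south, east, north = bbox
    ncol = int(round((east - west) / cell_size))
    nrow = int(round((north - south) / cell_size))
    vals = {}
    for var in CLIMATE_VARS:
        mean, sd = spec[var]
        x = rng.normal(mean, sd, size=(nrow, ncol))
        if var in ("precip", "wind"):
            # truncate at zero by redrawing from the positive tail
            bad = x < 0
            while np.any(bad):
                x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = x < 0
        vals[var] = x
    # enforce tmin <= tmax cellwise (independent draws can rarely cross)
    lo = np.minimum(vals["tmin"], vals["tmax"])
    hi = np.maximum(vals["tmin"], vals["tmax"])
    vals["tmin"], vals["tmax"] = lo, hi
    return ClimateRaster(west=west, south=south, cell_size=cell_size,
                         values=vals, season=season)


def simulate_climate_fields(
    config: ClimateConfig | None = None, seed: int = 0
) -> tuple[ClimateRaster, ClimateRaster]:
    """Draw (winter_raster, summer_raster) from the configured per-season
    Gaussians; precipitation and wind truncated at zero."""
    config = config or ClimateConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    winter = _draw_raster(rng, config.winter_bbox, config.cell_size,
                          config.winter, "winter")
    summer = _draw_raster(rng, config.summer_bbox, config.cell_size,
                          config.summer, "summer")
    return winter, summer


def identical_climate_config() -> ClimateConfig:
    """Both seasons drawn from the winter generator — the no-separation
    control used to check that overlap indices approach 1."""
    base = ClimateConfig()
    return replace(base, summer=dict(base.winter))
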