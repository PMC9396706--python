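"""Net-squared-displacement (NSD) migration phenology models.

NSD is the squared distance (km^2) between a location and the first location
of the trajectory.  Within a seasonal range NSD is stationary; it rises
rapidly through spring migration, plateaus on the summer range, and falls
back through autumn.  Two logistic-family models describe this:

* single sigmoid (one-way, spring only)::

      NSD(t) = delta / (1 + exp((theta - t) / phi))

* double sigmoid (annual, rise then return)::

      NSD(t) = delta / (1 + exp((theta_s - t) / phi_s))
             - delta / (1 + exp((theta_a - t) / phi_a))

with ``delta`` the plateau (km^2), ``theta_*`` the spring/autumn midpoints
(day of year when half the plateau is reached) and ``phi_*`` the logistic
time scales (days).  The annual curve subtracts the autumn limb so that it
rises to ``delta`` and returns toward zero; ``sqrt(delta)`` is a surrogate of
migration distance and ``2*phi`` of migration duration (the time between the
1/4 and 3/4 displacement quantiles up to the factor ln 3).

Both models are exposed as scikit-learn style regressors fitted by
trust-region nonlinear least squares with analytic Jacobians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .geo import aeqd_forward

__all__ = [
    "single_sigmoid", "double_sigmoid", "project_to_plane", "compute_nsd",
    "SingleSigmoidNSD", "DoubleSigmoidNSD", "fit_single_sigmoid",
    "fit_double_sigmoid", "derive_migration_metrics", "segment_timing",
    "MigrationTiming", "thin_daily", "day_of_year",
]


def single_sigmoid(t, delta, theta, phi):
    """Evaluate the one-way logistic NSD curve (km^2)."""
    t = np.asarray(t, dtype=float)
    return delta * expit((t - theta) / phi)


def double_sigmoid(t, delta, theta_s, theta_a, phi_s, phi_a):
    """Evaluate the annual rise-then-return NSD curve (km^2)."""
    t = np.asarray(t, dtype=float)
    return delta * (expit((t - theta_s) / phi_s) - expit((t - theta_a) / phi_a))


def day_of_year(timestamps: pd.Series) -> np.ndarray:
    """Fractional day of year (1.0 = Jan 1 00:00) relative to the year of the
    first timestamp, so a track is monotone in time even past Dec 31."""
    ts = pd.to_datetime(timestamps)
    origin = pd.Timestamp(year=ts.iloc[0].year, month=1, day=1, tz=ts.iloc[0].tz)
    return 1.0 + (ts - origin).dt.total_seconds().to_numpy() / 86400.0


def project_to_plane(traj: pd.DataFrame, origin: tuple[float, float] | None = None
                     ) -> pd.DataFrame:
    """Add planar coordinates ``x_km, y_km`` (azimuthal equidistant about
    ``origin``, default the first fix) to a trajectory frame."""
    out = traj.copy()
    if origin is None:
        origin = (float(traj["lon"].iloc[0]), float(traj["lat"].iloc[0]))
    x, y = aeqd_forward(out["lon"].to_numpy(float), out["lat"].to_numpy(float),
                        origin[0], origin[1])
    out["x_km"] = x
    out["y_km"] = y
    return out


def compute_nsd(traj: pd.DataFrame) -> pd.DataFrame:
    """NSD series (``t`` day of year, ``nsd_km2``) of a trajectory, measured
    from its first fix through the distance-true projection at that fix."""
    if len(traj) < 2:
        raise ValueError("need at least two fixes to compute an NSD series")
    planar = project_to_plane(traj)
    nsd = planar["x_km"].to_numpy() ** 2 + planar["y_km"].to_numpy() ** 2
    out = pd.DataFrame({"t": day_of_year(traj["timestamp"]), "nsd_km2": nsd})
    if "animal_id" in traj.columns:
        out["animal_id"] = traj["animal_id"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _interp_crossing(t, y, level, rising=True):
    """First time the series crosses ``level`` (linear interpolation);
    searches left-to-right on the rising limb, right-to-left on the falling.
    Returns None when no crossing exists."""
    idx = range(1, len(y)) if rising else range(len(y) - 1, 0, -1)
    for i in idx:
        lo, hi = (y[i - 1], y[i]) if rising else (y[i], y[i - 1])
        if lo < level <= hi:
            t0, t1 = (t[i - 1], t[i]) if rising else (t[i], t[i - 1])
            if hi == lo:
                return 0.5 * (t0 + t1)
            return t0 + (level - lo) / (hi - lo) * (t1 - t0)
    return None


_LN3 = np.log(3.0)


def _phi_from_quartiles(t, y, delta0, rising=True, fallback=5.0):
    t25 = _interp_crossing(t, y, 0.25 * delta0, rising)
    t75 = _interp_crossing(t, y, 0.75 * delta0, rising)
    if t25 is None or t75 is None:
        return fallback
    return max(abs(t75 - t25) / (2.0 * _LN3), 1e-2)


def _se_from_jacobian(jac, resid, n_params):
    """Asymptotic parameter SEs: sqrt(diag((J'J)^-1) * s2)."""
    n = resid.size
    dof = max(n - n_params, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
    return se, np.sqrt(s2)


class _SigmoidBase(RegressorMixin, BaseEstimator):
    """Shared NLS machinery of the sigmoid NSD regressors."""

    def __init__(self, init=None, phi_bounds=(1e-3, 100.0), max_nfev=2000):
        self.init = init
        self.phi_bounds = phi_bounds
        self.max_nfev = max_nfev

    def _validate_ty(self, X, y):
        t = np.asarray(X, dtype=float).squeeze()
        if t.ndim == 0:
            t = t.reshape(1)
        if t.ndim != 1:
            raise ValueError("X must be a 1-D array of day-of-year times")
        yv = np.asarray(y, dtype=float)
        if yv.shape != t.shape:
            raise ValueError("X and y lengths differ")
        if np.any(np.diff(t) <= 0):
            order = np.argsort(t)
            t, yv = t[order], yv[order]
        return t, yv

    def _mark_failed(self, names):
        for name in names:
            setattr(self, name + "_", np.nan)
        self.se_ = {n: np.nan for n in names}
        self.resid_sd_ = np.nan
        self.converged_ = False
        return self

    def predict(self, X):
        check_is_fitted(self, "converged_")
        t = np.asarray(X, dtype=float)
        return self._curve(t)

    def score_series(self, series: pd.DataFrame):
        """Convenience: fit on an NSD frame with columns ``t, nsd_km2``."""
        return self.fit(series["t"].to_numpy(), series["nsd_km2"].to_numpy())


class SingleSigmoidNSD(_SigmoidBase):
    """One-way logistic NSD model for tracks covering spring migration only.

    Fitted attributes: ``delta_`` (km^2), ``theta_`` (day), ``phi_`` (day),
    ``se_`` (dict of asymptotic SEs), ``resid_sd_``, ``converged_``.
    """

    _names = ("delta", "theta", "phi")

    def fit(self, X, y):
        t, yv = self._validate_ty(X, y)
        ymax = float(np.max(yv)) if yv.size else 0.0
        if yv.size < 4 or ymax <= 0 or np.ptp(yv) == 0:
            return self._mark_failed(self._names)
        scale = ymax
        ys = yv / scale
        if self.init is not None:
            d0 = self.init.get("delta", ymax) / scale
            th0 = self.init.get("theta")
            if th0 is None:
                th0 = _interp_crossing(t, ys, d0 / 2.0) or float(t[len(t) // 2])
            ph0 = self.init.get("phi", 5.0)
        else:
            d0 = 1.0
            th0 = _interp_crossing(t, ys, d0 / 2.0)
            if th0 is None:
                th0 = float(t[int(np.argmax(ys >= d0 / 2))])
            ph0 = _phi_from_quartiles(t, ys, d0)
        lo_p, hi_p = self.phi_bounds
        ph0 = float(np.clip(ph0, lo_p, hi_p))
        span = t[-1] - t[0]

        def resid(p):
            d, th, ph = p
            return d * expit((t - th) / ph) - ys

        def jac(p):
            d, th, ph = p
            s = expit((t - th) / ph)
            ds = s * (1.0 - s)
            return np.column_stack([s, -d * ds / ph, -d * ds * (t - th) / ph ** 2])

        sol = least_squares(
            resid, x0=[d0, th0, ph0], jac=jac, method="trf",
            bounds=([1e-12, t[0] - span - 365.0, lo_p],
                    [np.inf, t[-1] + span + 365.0, hi_p]),
            max_nfev=self.max_nfev, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        d, th, ph = sol.x
        self.delta_ = d * scale
        self.theta_ = th
        self.phi_ = ph
        se, rsd = _se_from_jacobian(sol.jac, sol.fun, 3)
        self.se_ = {"delta": se[0] * scale, "theta": se[1], "phi": se[2]}
        self.resid_sd_ = rsd * scale
        # a fit whose plateau is far above the data never reached it: flag
        self.converged_ = bool(sol.success and self.delta_ <= 4.0 * ymax
                               and t[0] - span <= th <= t[-1] + span)
        self.n_obs_ = yv.size
        return self

    def _curve(self, t):
        return single_sigmoid(t, self.delta_, self.theta_, self.phi_)


class DoubleSigmoidNSD(_SigmoidBase):
    """Annual rise-then-return NSD model (spring and autumn limbs).

    Fitted attributes: ``delta_``, ``theta_s_``, ``theta_a_``, ``phi_s_``,
    ``phi_a_``, plus ``se_``, ``resid_sd_``, ``converged_``.
    """

    _names = ("delta", "theta_s", "theta_a", "phi_s", "phi_a")

    def fit(self, X, y):
        t, yv = self._validate_ty(X, y)
        ymax = float(np.max(yv)) if yv.size else 0.0
        if yv.size < 6 or ymax <= 0 or np.ptp(yv) == 0:
            return self._mark_failed(self._names)
        scale = ymax
        ys = yv / scale
        lo_p, hi_p = self.phi_bounds
        if self.init is not None:
            d0 = self.init.get("delta", ymax) / scale
            ths0 = self.init["theta_s"]
            tha0 = self.init["theta_a"]
            phs0 = self.init.get("phi_s", 5.0)
            pha0 = self.init.get("phi_a", 5.0)
        else:
            d0 = 1.0
            ths0 = _interp_crossing(t, ys, 0.5, rising=True)
            tha0 = _interp_crossing(t, ys, 0.5, rising=False)
            if ths0 is None or tha0 is None or tha0 <= ths0:
                return self._mark_failed(self._names)
            phs0 = _phi_from_quartiles(t, ys, d0, rising=True)
            pha0 = _phi_from_quartiles(t, ys, d0, rising=False)
        phs0 = float(np.clip(phs0, lo_p, hi_p))
        pha0 = float(np.clip(pha0, lo_p, hi_p))
        span = t[-1] - t[0]

        def resid(p):
            d, ths, tha, phs, pha = p
            return (d * (expit((t - ths) / phs) - expit((t - tha) / pha)) - ys)

        def jac(p):
            d, ths, tha, phs, pha = p
            ss = expit((t - ths) / phs)
            sa = expit((t - tha) / pha)
            dss = ss * (1.0 - ss)
            dsa = sa * (1.0 - sa)
            return np.column_stack([
                ss - sa,
                -d * dss / phs,
                d * dsa / pha,
                -d * dss * (t - ths) / phs ** 2,
                d * dsa * (t - tha) / pha ** 2,
            ])

        sol = least_squares(
            resid, x0=[d0, ths0, tha0, phs0, pha0], jac=jac, method="trf",
            bounds=([1e-12, t[0] - span, t[0] - span, lo_p, lo_p],
                    [np.inf, t[-1] + span, t[-1] + span, hi_p, hi_p]),
            max_nfev=self.max_nfev, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        d, ths, tha, phs, pha = sol.x
        self.delta_ = d * scale
        self.theta_s_ = ths
        self.theta_a_ = tha
        self.phi_s_ = phs
        self.phi_a_ = pha
        se, rsd = _se_from_jacobian(sol.jac, sol.fun, 5)
        self.se_ = dict(zip(self._names, [se[0] * scale, *se[1:]]))
        self.resid_sd_ = rsd * scale
        self.converged_ = bool(sol.success and ths < tha
                               and self.delta_ <= 4.0 * ymax)
        self.n_obs_ = yv.size
        return self

    def _curve(self, t):
        return double_sigmoid(t, self.delta_, self.theta_s_, self.theta_a_,
                              self.phi_s_, self.phi_a_)


def fit_single_sigmoid(series: pd.DataFrame, init: dict | None = None
                       ) -> SingleSigmoidNSD:
    """Fit the one-way model to an NSD frame (columns ``t, nsd_km2``)."""
    return SingleSigmoidNSD(init=init).score_series(series)


def fit_double_sigmoid(series: pd.DataFrame, init: dict | None = None
                       ) -> DoubleSigmoidNSD:
    """Fit the annual model to an NSD frame (columns ``t, nsd_km2``)."""
    return DoubleSigmoidNSD(init=init).score_series(series)


# ---------------------------------------------------------------------------
# derived metrics and timing segmentation
# ---------------------------------------------------------------------------

def quantile_crossing(theta: float, phi: float, q: float) -> float:
    """Day on which a logistic limb reaches fraction ``q`` of its plateau:
    t(q) = theta + phi * ln(q / (1 - q))."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return theta + phi * np.log(q / (1.0 - q))


def derive_migration_metrics(fit) -> dict:
    """Model-based migration surrogates from a converged sigmoid fit.

    Returns sqrt(delta) in km (distance surrogate), 2*phi per limb in days
    (duration surrogate) and the analytic quartile span 2*phi*ln 3.
    """
    check_is_fitted(fit, "converged_")
    if not fit.converged_:
        raise ValueError("migration metrics require a converged fit")
    out = {"sqrt_delta_km": float(np.sqrt(fit.delta_))}
    if isinstance(fit, DoubleSigmoidNSD):
        out["two_phi_spring_days"] = 2.0 * fit.phi_s_
        out["two_phi_autumn_days"] = 2.0 * fit.phi_a_
        out["quartile_span_spring_days"] = 2.0 * fit.phi_s_ * _LN3
        out["quartile_span_autumn_days"] = 2.0 * fit.phi_a_ * _LN3
    else:
        out["two_phi_days"] = 2.0 * fit.phi_
        out["quartile_span_days"] = 2.0 * fit.phi_ * _LN3
    return out


@dataclass
class MigrationTiming:
    """Migration dates (day of year) from the fitted NSD curve."""

    spring_departure: float
    spring_arrival: float
    autumn_departure: float | None = None
    autumn_arrival: float | None = None
    censored: bool = False

    @property
    def spring_duration(self) -> float:
        return self.spring_arrival - self.spring_departure

    @property
    def autumn_duration(self) -> float | None:
        if self.autumn_departure is None or self.autumn_arrival is None:
            return None
        return self.autumn_arrival - self.autumn_departure


def segment_timing(fit, frac: float = 0.025,
                   t_span: tuple[float, float] | None = None) -> MigrationTiming:
    """Migration timing from the analytic threshold crossings of a fit.

    Departure/arrival are where a limb crosses ``frac`` and ``1 - frac`` of
    the plateau (the deterministic replacement for eyeballing the NSD series).
    ``t_span`` (observed time range) flags crossings outside the data as
    censored rather than erroring.
    """
    if not 0.0 < frac < 0.5:
        raise ValueError("frac must be in (0, 0.5)")
    check_is_fitted(fit, "converged_")
    if not fit.converged_:
        raise ValueError("timing segmentation requires a converged fit")
    if isinstance(fit, DoubleSigmoidNSD):
        timing = MigrationTiming(
            spring_departure=quantile_crossing(fit.theta_s_, fit.phi_s_, frac),
            spring_arrival=quantile_crossing(fit.theta_s_, fit.phi_s_, 1 - frac),
            autumn_departure=quantile_crossing(fit.theta_a_, fit.phi_a_, frac),
            autumn_arrival=quantile_crossing(fit.theta_a_, fit.phi_a_, 1 - frac),
        )
    else:
        timing = MigrationTiming(
            spring_departure=quantile_crossing(fit.theta_, fit.phi_, frac),
            spring_arrival=quantile_crossing(fit.theta_, fit.phi_, 1 - frac),
        )
    if t_span is not None:
        lo, hi = t_span
        points = [timing.spring_departure, timing.spring_arrival,
                  timing.autumn_departure, timing.autumn_arrival]
        timing.censored = any(p is not None and not lo <= p <= hi for p in points)
    return timing


def thin_daily(traj: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep one randomly chosen fix per calendar day (seeded), the
    down-sampling used before the niche analysis on unevenly sampled tracks."""
    rng = np.random.default_rng(seed)
    ts = pd.to_datetime(traj["timestamp"])
    day = ts.dt.floor("D")
    keep = []
    for _, idx in traj.groupby(day, sort=True).indices.items():
        keep.append(idx[rng.integers(len(idx))])
    return traj.iloc[sorted(keep)].reset_index(drop=True)
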