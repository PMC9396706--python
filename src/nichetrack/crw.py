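"""Continuous-time correlated random walk (CRW) location-error filter.

The movement model is the integrated Ornstein-Uhlenbeck process: velocity is
an OU process with autocorrelation rate ``beta_vel`` (1/h) and noise
intensity ``sigma_vel`` (km h^-3/2); position is its integral.  Each planar
axis is an independent 2-state (position, velocity) linear-Gaussian system
with the exact discrete transition over each (irregular) time step, observed
with isotropic Gaussian error whose SD depends on the Argos location class of
the fix.  Maximum-likelihood fitting uses the Kalman prediction-error
decomposition; error-reduced positions come from the fixed-interval
(Rauch-Tung-Striebel) smoother, optionally at arbitrary requested times.

Working units: km, hours, planar coordinates (project first, e.g. with
:func:`nichetrack.nsd.project_to_plane`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["CRWParams", "CRWFilter", "crw_loglik", "fit_crw",
           "smooth_positions", "simulate_crw_track"]

#: diffuse initial variances: position (km^2) and velocity ((km/h)^2)
_P0_POS = 1.0e4
_P0_VEL = 25.0


@dataclass(frozen=True)
class CRWParams:
    """Parameters of the integrated-OU movement + measurement model."""

    beta_vel: float                       # velocity autocorrelation rate, 1/h
    sigma_vel: float                      # velocity noise intensity, km h^-1.5
    meas_sd: dict[str, float] = field(default_factory=dict)  # km per class

    def __post_init__(self):
        if self.beta_vel <= 0:
            raise ValueError("beta_vel must be > 0")
        if self.sigma_vel < 0:
            raise ValueError("sigma_vel must be >= 0")
        if any(v < 0 for v in self.meas_sd.values()):
            raise ValueError("measurement SDs must be >= 0")


def transition_matrices(beta: float, sigma: float, dt: float):
    """Exact (F, Q) of the integrated-OU over a step of ``dt`` hours."""
    e = math.exp(-beta * dt)
    f01 = (1.0 - e) / beta
    F = np.array([[1.0, f01], [0.0, e]])
    s2 = sigma * sigma
    q_vv = s2 * (1.0 - e * e) / (2.0 * beta)
    q_xv = s2 * (1.0 - e) ** 2 / (2.0 * beta * beta)
    q_xx = s2 / (beta * beta) * (dt - 2.0 * (1.0 - e) / beta
                                 + (1.0 - e * e) / (2.0 * beta))
    Q = np.array([[q_xx, q_xv], [q_xv, q_vv]])
    return F, Q


def _meas_var(classes, meas_sd, n) -> np.ndarray:
    if not isinstance(meas_sd, dict):
        return np.full(n, float(meas_sd) ** 2)
    if classes is None:
        return np.full(n, meas_sd.get(None, 0.0) ** 2)
    out = np.empty(n)
    for i, c in enumerate(classes):
        if c is None or (isinstance(c, float) and np.isnan(c)) or c is pd.NA:
            c = None
        if c not in meas_sd:
            raise ValueError(f"no measurement SD for location class {c!r}")
        out[i] = meas_sd[c] ** 2
    return out


def _filter_axis(t_h, z, rvar, beta, sigma, store=False):
    """Scalar 2x2 Kalman filter along one axis.

    Observations with rvar = inf are treated as missing (pure prediction),
    which is how positions at unobserved times are interpolated.  Returns the
    prediction-error log-likelihood and, when ``store``, the moments needed
    by the RTS smoother.
    """
    n = len(z)
    # initial state: first finite observation as position mean, zero velocity
    first = next(i for i in range(n) if np.isfinite(rvar[i]) or store)
    z0 = z[first] if np.isfinite(z[first]) else 0.0
    mx, mv = z0, 0.0
    pxx, pxv, pvv = _P0_POS, 0.0, _P0_VEL
    ll = 0.0
    if store:
        pred_m = np.empty((n, 2)); pred_P = np.empty((n, 3))
        filt_m = np.empty((n, 2)); filt_P = np.empty((n, 3))
        Fs = np.empty((n, 3))  # (f01, e) per step; slot 2 unused
    for i in range(n):
        if i > 0:
            dt = t_h[i] - t_h[i - 1]
            e = math.exp(-beta * dt)
            f01 = (1.0 - e) / beta
            s2 = sigma * sigma
            q_vv = s2 * (1.0 - e * e) / (2.0 * beta)
            q_xv = s2 * (1.0 - e) ** 2 / (2.0 * beta * beta)
            q_xx = s2 / (beta * beta) * (dt - 2.0 * (1.0 - e) / beta
                                         + (1.0 - e * e) / (2.0 * beta))
            mx = mx + f01 * mv
            mv = e * mv
            nxx = pxx + 2.0 * f01 * pxv + f01 * f01 * pvv + q_xx
            nxv = e * (pxv + f01 * pvv) + q_xv
            nvv = e * e * pvv + q_vv
            pxx, pxv, pvv = nxx, nxv, nvv
        else:
            f01, e = 0.0, 1.0
        if store:
            Fs[i] = (f01, e, 0.0)
            pred_m[i] = (mx, mv); pred_P[i] = (pxx, pxv, pvv)
        if np.isfinite(rvar[i]) and np.isfinite(z[i]):
            S = pxx + rvar[i]
            resid = z[i] - mx
            ll -= 0.5 * (math.log(2.0 * math.pi * S) + resid * resid / S)
            kx = pxx / S
            kv = pxv / S
            mx += kx * resid
            mv += kv * resid
            nxx = pxx - kx * pxx
            nxv = pxv - kx * pxv
            nvv = pvv - kv * pxv
            pxx, pxv, pvv = nxx, nxv, nvv
        if store:
            filt_m[i] = (mx, mv); filt_P[i] = (pxx, pxv, pvv)
    if store:
        return ll, pred_m, pred_P, filt_m, filt_P, Fs
    return ll


def _smooth_axis(pred_m, pred_P, filt_m, filt_P, Fs):
    """RTS backward pass; returns smoothed means (n,2) and covariances (n,3)."""
    n = pred_m.shape[0]
    sm = filt_m.copy()
    sP = filt_P.copy()
    for i in range(n - 2, -1, -1):
        f01, e, _ = Fs[i + 1]
        F = np.array([[1.0, f01], [0.0, e]])
        Pf = np.array([[filt_P[i, 0], filt_P[i, 1]], [filt_P[i, 1], filt_P[i, 2]]])
        Pp = np.array([[pred_P[i + 1, 0], pred_P[i + 1, 1]],
                       [pred_P[i + 1, 1], pred_P[i + 1, 2]]])
        try:
            G = Pf @ F.T @ np.linalg.inv(Pp)
        except np.linalg.LinAlgError:
            continue
        dm = np.array([sm[i + 1, 0] - pred_m[i + 1, 0],
                       sm[i + 1, 1] - pred_m[i + 1, 1]])
        m = np.array([filt_m[i, 0], filt_m[i, 1]]) + G @ dm
        Ps = np.array([[sP[i + 1, 0], sP[i + 1, 1]], [sP[i + 1, 1], sP[i + 1, 2]]])
        P = Pf + G @ (Ps - Pp) @ G.T
        sm[i] = m
        sP[i] = (P[0, 0], P[0, 1], P[1, 1])
    return sm, sP


def _as_arrays(traj: pd.DataFrame):
    t_h = np.asarray(traj["t_h"], dtype=float)
    if np.any(np.diff(t_h) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    x = np.asarray(traj["x_km"], dtype=float)
    y = np.asarray(traj["y_km"], dtype=float)
    classes = traj["lc_class"].tolist() if "lc_class" in traj.columns else None
    return t_h, x, y, classes


def crw_loglik(traj: pd.DataFrame, params: CRWParams) -> float:
    """Exact Gaussian prediction-error log-likelihood of a planar track.

    ``traj`` needs columns ``t_h`` (hours), ``x_km``, ``y_km`` and optionally
    ``lc_class`` mapping into ``params.meas_sd``.
    """
    t_h, x, y, classes = _as_arrays(traj)
    rvar = _meas_var(classes, params.meas_sd, len(t_h))
    return (_filter_axis(t_h, x, rvar, params.beta_vel, params.sigma_vel)
            + _filter_axis(t_h, y, rvar, params.beta_vel, params.sigma_vel))


class CRWFilter(BaseEstimator):
    """Maximum-likelihood CRW fit and smoother for one planar track.

    Parameters
    ----------
    beta0, sigma0 : float
        Optimiser starting values for the velocity autocorrelation rate
        (1/h) and noise intensity (km h^-1.5).
    meas_sd : dict | float | None
        Measurement SD (km) per location class (or a single value).  Held
        fixed by default (Argos accuracy tiers are externally calibrated);
        set ``estimate_meas_sd=True`` to profile a common scale factor.
    min_fixes : int
        Fits with fewer fixes are refused.
    """

    def __init__(self, beta0=0.5, sigma0=2.0, meas_sd=None,
                 estimate_meas_sd=False, min_fixes=10, maxiter=200):
        self.beta0 = beta0
        self.sigma0 = sigma0
        self.meas_sd = meas_sd
        self.estimate_meas_sd = estimate_meas_sd
        self.min_fixes = min_fixes
        self.maxiter = maxiter

    def fit(self, X, y=None):
        """Fit to a planar track frame (columns ``t_h, x_km, y_km[,
        lc_class]``); maximises the likelihood over log(beta), log(sigma)."""
        traj = X
        if len(traj) < self.min_fixes:
            raise ValueError(f"need at least {self.min_fixes} fixes, got {len(traj)}")
        t_h, x, yv, classes = _as_arrays(traj)
        meas_sd = self.meas_sd if self.meas_sd is not None else 0.0
        base_rvar = _meas_var(classes, meas_sd, len(t_h))

        def nll(p):
            beta = math.exp(p[0])
            sigma = math.exp(p[1])
            rvar = base_rvar * (math.exp(2.0 * p[2]) if self.estimate_meas_sd else 1.0)
            ll = (_filter_axis(t_h, x, rvar, beta, sigma)
                  + _filter_axis(t_h, yv, rvar, beta, sigma))
            return -ll if np.isfinite(ll) else 1e12

        p0 = [math.log(self.beta0), math.log(self.sigma0)]
        if self.estimate_meas_sd:
            p0.append(0.0)
        res = minimize(nll, p0, method="L-BFGS-B",
                       options={"maxiter": self.maxiter, "ftol": 1e-10})
        beta = math.exp(res.x[0])
        sigma = math.exp(res.x[1])
        scale = math.exp(res.x[2]) if self.estimate_meas_sd else 1.0
        if isinstance(meas_sd, dict):
            fitted_sd = {k: v * scale for k, v in meas_sd.items()}
        else:
            fitted_sd = {None: float(meas_sd) * scale}
        self.params_ = CRWParams(beta_vel=beta, sigma_vel=sigma, meas_sd=fitted_sd)
        self.log_likelihood_ = -float(res.fun)
        self.converged_ = bool(res.success)
        self.n_obs_ = len(t_h)
        self._t_h = t_h
        self._x = x
        self._y = yv
        self._rvar = base_rvar * scale ** 2
        return self

    def predict(self, times_h=None) -> pd.DataFrame:
        """Smoothed positions (RTS) at ``times_h`` (default: the observation
        times).  Returns ``t_h, pred_x_km, pred_y_km, pred_var_km2`` where the
        variance is the summed positional posterior variance of both axes.
        Requested times outside the track span are extrapolated (their
        variance grows with distance from the data)."""
        check_is_fitted(self, "params_")
        t_obs = self._t_h
        if times_h is None:
            t_all = t_obs
            rvar = self._rvar
        else:
            times_h = np.asarray(times_h, dtype=float)
            t_all = np.union1d(t_obs, times_h)
            rvar = np.full(t_all.size, np.inf)
            pos = np.searchsorted(t_all, t_obs)
            rvar[pos] = self._rvar
        z_x = np.full(t_all.size, np.nan)
        z_y = np.full(t_all.size, np.nan)
        pos = np.searchsorted(t_all, t_obs)
        z_x[pos] = self._x
        z_y[pos] = self._y
        beta, sigma = self.params_.beta_vel, self.params_.sigma_vel
        out_m = {}
        out_v = {}
        for name, z in (("x", z_x), ("y", z_y)):
            _, pm, pP, fm, fP, Fs = _filter_axis(t_all, z, rvar, beta, sigma,
                                                 store=True)
            sm, sP = _smooth_axis(pm, pP, fm, fP, Fs)
            out_m[name] = sm[:, 0]
            out_v[name] = sP[:, 0]
        df = pd.DataFrame({
            "t_h": t_all,
            "pred_x_km": out_m["x"],
            "pred_y_km": out_m["y"],
            "pred_var_km2": np.clip(out_v["x"], 0, None) + np.clip(out_v["y"], 0, None),
        })
        if times_h is not None:
            df = df[np.isin(df["t_h"].to_numpy(), times_h)].reset_index(drop=True)
        return df

    def filter_variances(self) -> pd.DataFrame:
        """Filtered (forward-pass) positional variances at observation times,
        for comparison against the smoothed variances."""
        check_is_fitted(self, "params_")
        beta, sigma = self.params_.beta_vel, self.params_.sigma_vel
        out = {}
        for name, z in (("x", self._x), ("y", self._y)):
            _, pm, pP, fm, fP, Fs = _filter_axis(self._t_h, z, self._rvar,
                                                 beta, sigma, store=True)
            out["filt_var_" + name] = fP[:, 0]
            sm, sP = _smooth_axis(pm, pP, fm, fP, Fs)
            out["smooth_var_" + name] = sP[:, 0]
        out["t_h"] = self._t_h
        return pd.DataFrame(out)


def fit_crw(traj: pd.DataFrame, init: CRWParams | None = None, **kwargs) -> CRWFilter:
    """Functional wrapper: fit a :class:`CRWFilter` to a planar track."""
    if init is not None:
        kwargs.setdefault("beta0", init.beta_vel)
        kwargs.setdefault("sigma0", init.sigma_vel)
        kwargs.setdefault("meas_sd", init.meas_sd)
    return CRWFilter(**kwargs).fit(traj)


def smooth_positions(traj: pd.DataFrame, fit: CRWFilter,
                     times_h=None) -> pd.DataFrame:
    """Functional wrapper around :meth:`CRWFilter.predict`."""
    return fit.predict(times_h)


def simulate_crw_track(params: CRWParams, times_h, seed: int = 0,
                       classes=None) -> pd.DataFrame:
    """Sample a true integrated-OU track at ``times_h`` and observe it with
    the class-dependent measurement error; used for recovery studies."""
    rng = np.random.default_rng(seed)
    times_h = np.asarray(times_h, dtype=float)
    n = times_h.size
    state = np.zeros((2, 2))  # axes x/y rows: (pos, vel)
    # start at stationary velocity
    vsd = params.sigma_vel / math.sqrt(2.0 * params.beta_vel)
    state[:, 1] = rng.normal(0.0, vsd, size=2)
    true = np.empty((n, 2))
    true[0] = state[:, 0]
    for i in range(1, n):
        dt = times_h[i] - times_h[i - 1]
        F, Q = transition_matrices(params.beta_vel, params.sigma_vel, dt)
        L = np.linalg.cholesky(Q + 1e-15 * np.eye(2))
        for ax in range(2):
            state[ax] = F @ state[ax] + L @ rng.normal(size=2)
        true[i] = state[:, 0]
    if classes is None:
        classes = [None] * n
    rvar = _meas_var(None if all(c is None for c in classes) else classes,
                     params.meas_sd, n)
    sd = np.sqrt(rvar)
    obs = true + rng.normal(size=(n, 2)) * sd[:, None]
    return pd.DataFrame({
        "t_h": times_h,
        "x_km": obs[:, 0], "y_km": obs[:, 1],
        "true_x_km": true[:, 0], "true_y_km": true[:, 1],
        "lc_class": classes,
    })
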