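"""Seasonal climatic-niche overlap by PCA ordination.

The procedure compares the climatic conditions occupied in two seasons in the
space of the first two principal components of the pooled (background +
occurrence) climate table:

1. extract climate variables (tmin, tmax, precip, wind) at the thinned
   occurrence locations of each season;
2. PCA on the centred, unit-variance pooled table;
3. for each season, kernel-smooth the occurrence density ``o`` and the
   background environment density ``e`` onto a common R x R grid (default
   100 x 100) of PC1-PC2 cell centres, and form the occupancy ``z = o/e``
   (availability-corrected; ``z = o`` uncorrected), rescaled to max 1;
4. overlap indices on the normalised occupancies ``p`` of the two seasons:
   Schoener's ``D = 1 - 0.5 * sum |p1 - p2|`` and the Hellinger-based
   ``I = 1 - 0.5 * sum (sqrt(p1) - sqrt(p2))^2``, both in [0, 1].

A one-variable analogue (:func:`variable_overlap_1d`) measures the overlap of
two samples of a single variable (e.g. wind speed) as the shared area of
their kernel densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .synthdata import CLIMATE_VARS, ClimateRaster

__all__ = ["extract_climate", "EnvPCA", "NicheGrid", "occupancy_grid",
           "schoener_D", "hellinger_I", "variable_overlap_1d", "NicheOverlap"]


def extract_climate(locations: pd.DataFrame, raster: ClimateRaster,
                    season: str | None = None) -> pd.DataFrame:
    """Nearest-cell lookup of the climate variables at ``locations``
    (columns ``lon, lat``).  All locations must fall inside the raster
    bounding box."""
    lon = locations["lon"].to_numpy(float)
    lat = locations["lat"].to_numpy(float)
    west, south, east, north = raster.bbox
    outside = (lon < west) | (lon >= east) | (lat < south) | (lat >= north)
    if np.any(outside):
        raise ValueError(f"{int(outside.sum())} location(s) outside the raster "
                         f"bounding box {raster.bbox}")
    col = np.floor((lon - west) / raster.cell_size).astype(int)
    row = np.floor((lat - south) / raster.cell_size).astype(int)
    out = pd.DataFrame({v: raster.values[v][row, col] for v in CLIMATE_VARS})
    out["season"] = season if season is not None else raster.season
    return out


class EnvPCA(BaseEstimator):
    """Standardise-then-PCA of a pooled climate table.

    Fitted attributes: ``explained_pct_`` (percent variance per PC, sums to
    100), ``loadings_`` (components x variables), ``columns_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        cols = [c for c in X.columns if c != "season"]
        vals = X[cols].to_numpy(float)
        if vals.shape[0] < 3:
            raise ValueError("need at least 3 rows for a PCA")
        sd = vals.std(axis=0)
        for c, s in zip(cols, sd):
            if s == 0:
                raise ValueError(f"zero-variance column {c!r}")
        self.columns_ = cols
        self._scaler = StandardScaler().fit(vals)
        self._pca = PCA(n_components=self.n_components).fit(
            self._scaler.transform(vals))
        self.explained_pct_ = 100.0 * self._pca.explained_variance_ratio_
        self.loadings_ = self._pca.components_
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "columns_")
        vals = X[self.columns_].to_numpy(float)
        return self._pca.transform(self._scaler.transform(vals))

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# occupancy grids
# ---------------------------------------------------------------------------

def _scott_bandwidth(points: np.ndarray) -> np.ndarray:
    """Scott's rule per axis on the point set being smoothed."""
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1e-6)
    return sd * n ** (-1.0 / 6.0)


def kernel_density_grid(points: np.ndarray, x_centres: np.ndarray,
                        y_centres: np.ndarray, bandwidth: np.ndarray
                        ) -> np.ndarray:
    """Product-Gaussian kernel density of 2-D ``points`` at the grid of cell
    centres; returns an array [ny, nx] (mean of kernels, so it integrates to
    ~1 over the plane)."""
    bx, by = float(bandwidth[0]), float(bandwidth[1])
    if bx <= 0 or by <= 0:
        raise ValueError("bandwidth must be positive")
    n = points.shape[0]
    # separable kernel: density = A @ B with A over y, B over x
    ay = np.exp(-0.5 * ((y_centres[:, None] - points[None, :, 1]) / by) ** 2)
    ax = np.exp(-0.5 * ((x_centres[None, :] - points[:, None, 0]) / bx) ** 2)
    norm = 1.0 / (n * 2.0 * np.pi * bx * by)
    return norm * (ay @ ax)


@dataclass
class NicheGrid:
    """Occupancy of one season's niche on the shared PC1-PC2 grid."""

    x_centres: np.ndarray
    y_centres: np.ndarray
    occ_density: np.ndarray      # o, kernel density of occurrences
    env_density: np.ndarray      # e, kernel density of background climate
    z: np.ndarray                # occupancy, rescaled to max 1
    corrected: bool
    bandwidth_occ: np.ndarray | None = None
    bandwidth_env: np.ndarray | None = None

    def same_geometry(self, other: "NicheGrid") -> bool:
        return (self.z.shape == other.z.shape
                and np.allclose(self.x_centres, other.x_centres)
                and np.allclose(self.y_centres, other.y_centres))


def grid_axes(scores: np.ndarray, R: int = 100, margin: float = 0.1
              ) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre axes covering the pooled score range plus a margin."""
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    pad = (hi - lo) * margin
    lo, hi = lo - pad, hi + pad
    xe = np.linspace(lo[0], hi[0], R + 1)
    ye = np.linspace(lo[1], hi[1], R + 1)
    return 0.5 * (xe[:-1] + xe[1:]), 0.5 * (ye[:-1] + ye[1:])


def occupancy_grid(occ_scores: np.ndarray, bg_scores: np.ndarray,
                   R: int = 100, correction: bool = True,
                   extent_scores: np.ndarray | None = None,
                   margin: float = 0.1, eps_frac: float = 1e-10,
                   occ_mass_mask: float = 0.05,
                   bandwidth=None) -> NicheGrid:
    """Kernel occupancy of one season on the PC1-PC2 grid.

    ``occ_scores``/``bg_scores`` are (n, 2) PC scores of occurrences and of
    the season's background climate; ``extent_scores`` (default: both stacked)
    fixes the grid extent — pass the pooled scores of both seasons so the two
    grids share geometry.  With ``correction`` the occupancy is o/e wherever
    e exceeds ``eps_frac * max(e)``, else plain o; either way rescaled to max
    1.  The support is restricted to the cells holding the top
    ``1 - occ_mass_mask`` of the occurrence kernel mass (the usual 5%
    occupancy-contour threshold): outside it the ratio o/e is kernel-tail
    noise, not estimable occupancy.  Set ``occ_mass_mask=0`` to disable.
    """
    occ_scores = np.asarray(occ_scores, dtype=float)[:, :2]
    bg_scores = np.asarray(bg_scores, dtype=float)[:, :2]
    if occ_scores.shape[0] < 5:
        raise ValueError("need at least 5 occurrences")
    if extent_scores is None:
        extent_scores = np.vstack([occ_scores, bg_scores])
    xc, yc = grid_axes(np.asarray(extent_scores, float)[:, :2], R, margin)
    # one bandwidth (Scott on the occurrences) for both densities: the ratio
    # o/e is only stable when numerator and denominator share a kernel —
    # a fatter occurrence kernel would dominate e in the tails and the
    # corrected occupancy would peak on kernel-tail noise at the support edge
    bw = np.asarray(bandwidth, float) if bandwidth is not None \
        else _scott_bandwidth(occ_scores)
    o = kernel_density_grid(occ_scores, xc, yc, bw)
    e = kernel_density_grid(bg_scores, xc, yc, bw)
    if occ_mass_mask > 0:
        flat = np.sort(o.ravel())[::-1]
        cum = np.cumsum(flat)
        thr = flat[min(np.searchsorted(cum, (1.0 - occ_mass_mask) * flat.sum()),
                       flat.size - 1)]
        support = o >= thr
    else:
        support = np.ones_like(o, dtype=bool)
    if correction:
        eps = eps_frac * e.max()
        keep = support & (e > eps)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(keep, o / np.where(keep, e, 1.0), 0.0)
    else:
        z = np.where(support, o, 0.0)
    zmax = z.max()
    if zmax > 0:
        z = z / zmax
    return NicheGrid(x_centres=xc, y_centres=yc, occ_density=o, env_density=e,
                     z=z, corrected=correction, bandwidth_occ=bw,
                     bandwidth_env=bw)


def _normalised(g: NicheGrid) -> np.ndarray:
    tot = g.z.sum()
    if tot <= 0:
        raise ValueError("occupancy grid is identically zero")
    return g.z / tot


def schoener_D(g1: NicheGrid, g2: NicheGrid) -> float:
    """Schoener's D = 1 - 0.5 * sum |p1 - p2| over normalised occupancies."""
    if not g1.same_geometry(g2):
        raise ValueError("grids have different geometry")
    p1, p2 = _normalised(g1), _normalised(g2)
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def hellinger_I(g1: NicheGrid, g2: NicheGrid) -> float:
    """Warren's I = 1 - 0.5 * sum (sqrt(p1) - sqrt(p2))^2 (Hellinger-based)."""
    if not g1.same_geometry(g2):
        raise ValueError("grids have different geometry")
    p1, p2 = _normalised(g1), _normalised(g2)
    return float(1.0 - 0.5 * ((np.sqrt(p1) - np.sqrt(p2)) ** 2).sum())


def variable_overlap_1d(values1, values2, n_grid: int = 512) -> float:
    """Shared area of the kernel densities of two 1-D samples, in [0, 1]."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.size < 5 or v2.size < 5:
        raise ValueError("need at least 5 values per season")
    s1, s2 = v1.std(ddof=1), v2.std(ddof=1)
    if s1 == 0 and s2 == 0:
        if v1[0] == v2[0]:
            import warnings
            warnings.warn("both samples degenerate at the same value")
            return 1.0
        return 0.0
    b1 = (s1 if s1 > 0 else 1e-6) * v1.size ** (-0.2)
    b2 = (s2 if s2 > 0 else 1e-6) * v2.size ** (-0.2)
    lo = min(v1.min() - 4 * b1, v2.min() - 4 * b2)
    hi = max(v1.max() + 4 * b1, v2.max() + 4 * b2)
    grid = np.linspace(lo, hi, n_grid)
    dx = grid[1] - grid[0]

    def dens(v, b):
        d = np.exp(-0.5 * ((grid[:, None] - v[None, :]) / b) ** 2).sum(axis=1)
        d /= d.sum() * dx
        return d

    d1, d2 = dens(v1, b1), dens(v2, b2)
    return float(np.minimum(d1, d2).sum() * dx)


class NicheOverlap(BaseEstimator):
    """End-to-end two-season niche-overlap analysis.

    ``fit`` takes the occurrence and background climate tables of the two
    seasons (columns tmin, tmax, precip, wind), runs the pooled PCA, builds
    the two occupancy grids on a shared PC1-PC2 grid, and stores ``D_`` and
    ``I_``.
    """

    def __init__(self, R: int = 100, correction: bool = True,
                 margin: float = 0.1, eps_frac: float = 1e-10,
                 occ_mass_mask: float = 0.05):
        self.R = R
        self.correction = correction
        self.margin = margin
        self.eps_frac = eps_frac
        self.occ_mass_mask = occ_mass_mask

    def fit(self, occ1: pd.DataFrame, occ2: pd.DataFrame,
            bg1: pd.DataFrame, bg2: pd.DataFrame):
        for name, df in (("occ1", occ1), ("occ2", occ2)):
            if len(df) < 5:
                raise ValueError(f"{name}: need at least 5 occurrence rows")
        pooled = pd.concat([bg1, bg2, occ1, occ2], ignore_index=True)
        self.pca_ = EnvPCA(n_components=None).fit(pooled)
        self.explained_pct_ = self.pca_.explained_pct_
        scores = {
            "occ1": self.pca_.transform(occ1)[:, :2],
            "occ2": self.pca_.transform(occ2)[:, :2],
            "bg1": self.pca_.transform(bg1)[:, :2],
            "bg2": self.pca_.transform(bg2)[:, :2],
        }
        extent = np.vstack(list(scores.values()))
        kw = dict(R=self.R, correction=self.correction, margin=self.margin,
                  eps_frac=self.eps_frac, occ_mass_mask=self.occ_mass_mask,
                  extent_scores=extent)
        self.grid1_ = occupancy_grid(scores["occ1"], scores["bg1"], **kw)
        self.grid2_ = occupancy_grid(scores["occ2"], scores["bg2"], **kw)
        self.D_ = schoener_D(self.grid1_, self.grid2_)
        self.I_ = hellinger_I(self.grid1_, self.grid2_)
        return self

    def report(self) -> dict:
        check_is_fitted(self, "D_")
        return {
            "schoener_D": self.D_,
            "hellinger_I": self.I_,
            "explained_pct": [float(v) for v in self.explained_pct_],
            "R": self.R,
            "correction": self.correction,
            "bandwidth_occ_season1": [float(v) for v in self.grid1_.bandwidth_occ],
            "bandwidth_occ_season2": [float(v) for v in self.grid2_.bandwidth_occ],
        }
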