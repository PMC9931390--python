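"""Spheroid fitness landscapes over a drug × bacteria grid.

End-point spheroid areas on a 12-dose × 8-bacteria-level plate are
normalized in two steps (growth relative to time zero, then plate
min / second-max scaling), a bivariate quartic ("poly44": all monomials
x^m y^n with m+n <= 4, 15 coefficients) is fitted by ordinary least
squares in [0,1]-scaled dilution-index coordinates, and the EC50 front —
the level set where the fitted surface equals 0.5 — is extracted by
marching squares plus per-row root bracketing.  Fronts from two strains
are compared by their per-row crossing-dose shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from skimage import measure

__all__ = [
    "SpheroidGrid",
    "SpheroidLandscapeModel",
    "SurfaceResults",
    "EC50Front",
    "normalize_spheroids",
    "fit_poly44",
    "extract_front",
    "compare_fronts",
]

_POLY_TERMS = [(m, n) for total in range(5) for m in range(total + 1)
               for n in [total - m]]  # 15 monomials, m+n <= 4


@dataclass
class SpheroidGrid:
    """End-point and time-zero areas on a doses × bacteria grid.

    Arrays are laid out ``[bacteria_level, dose]`` with axis labels in
    ``doses_um`` (column j) and ``bacteria_levels`` (row i).  ``normalized``
    is populated by :func:`normalize_spheroids`.
    """

    area_end: np.ndarray
    area_t0: np.ndarray
    doses_um: np.ndarray | None = None
    bacteria_levels: np.ndarray | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.area_end = np.asarray(self.area_end, dtype=float)
        self.area_t0 = np.asarray(self.area_t0, dtype=float)
        if self.area_end.shape != self.area_t0.shape:
            raise ValueError("area_end and area_t0 shapes differ")
        if self.area_end.ndim != 2 or min(self.area_end.shape) < 2:
            raise ValueError("grid must be at least 2x2")
        if np.any(self.area_t0 <= 0):
            raise ValueError("area_t0 must be positive everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.area_end.shape


def normalize_spheroids(grid: SpheroidGrid) -> np.ndarray:
    """Two-step plate normalization of spheroid areas.

    (1) growth ratio ``v = area_end / area_t0`` per well; (2) plate
    scaling ``(v - min) / (secondmax - min)``.  The minimum maps to 0, the
    second-largest value to 1; the plate maximum may exceed 1 and is kept.
    """
    v = grid.area_end / grid.area_t0
    flat = np.sort(v.ravel())
    vmin, second = flat[0], flat[-2]
    if second - vmin <= 0:
        raise ValueError("degenerate plate: second-largest equals minimum")
    grid.normalized = (v - vmin) / (second - vmin)
    return grid.normalized


def _design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x**m * y**n for m, n in _POLY_TERMS])


class SpheroidLandscapeModel:
    """Least-squares poly44 surface for a normalized spheroid grid.

    Axes are dilution indices rescaled to [0, 1]: x = dose index (0 = the
    zero-drug column, increasing toward higher drug), y = bacteria-level
    index.  Serial dilutions are uniform in log concentration, so index
    space is effectively a log-dose axis.
    """

    def __init__(self, grid: SpheroidGrid):
        if grid.normalized is None:
            normalize_spheroids(grid)
        self.grid = grid
        n_rows, n_cols = grid.shape
        self._x = np.linspace(0.0, 1.0, n_cols)
        self._y = np.linspace(0.0, 1.0, n_rows)

    def fit(self) -> "SurfaceResults":
        z = self.grid.normalized
        mask = np.isfinite(z)
        if mask.sum() < len(_POLY_TERMS):
            raise ValueError("need >= 15 wells for a determined poly44 fit")
        xx, yy = np.meshgrid(self._x, self._y)
        X = _design(xx[mask], yy[mask])
        if np.linalg.matrix_rank(X) < len(_POLY_TERMS):
            raise ValueError("rank-deficient design (degenerate grid geometry)")
        coef, _, _, _ = np.linalg.lstsq(X, z[mask], rcond=None)
        rss = float(np.sum((X @ coef - z[mask]) ** 2))
        return SurfaceResults(self, coef, rss)


@dataclass
class SurfaceResults:
    """Fitted poly44 coefficients; EC50 front extraction hangs off this."""

    model: SpheroidLandscapeModel = field(repr=False)
    coefficients: np.ndarray
    rss: float

    def predict(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shape = np.broadcast_shapes(x.shape, y.shape)
        xb, yb = np.broadcast_to(x, shape).ravel(), np.broadcast_to(y, shape).ravel()
        return (_design(xb, yb) @ self.coefficients).reshape(shape)

    def ec50_front(self, level: float = 0.5) -> "EC50Front":
        return extract_front(self, level)

    def summary(self) -> str:
        terms = ", ".join(f"x^{m}y^{n}:{c:+.3g}" for (m, n), c
                          in zip(_POLY_TERMS, self.coefficients))
        return (f"poly44 surface fit (RSS {self.rss:.3g})\n{terms}")


@dataclass
class EC50Front:
    """Level set of the fitted surface at the mid-response value.

    ``polyline``: list of (N_i, 2) arrays of (x, y) points per contour
    segment.  ``crossings``: per bacteria row, the x (dose index in [0,1])
    where the surface crosses the level, NaN when there is no crossing.
    """

    level: float
    polyline: list
    crossings: np.ndarray
    y_rows: np.ndarray

    @property
    def empty(self) -> bool:
        return len(self.polyline) == 0 and not np.any(np.isfinite(self.crossings))


def fit_poly44(grid: SpheroidGrid) -> SurfaceResults:
    """OLS poly44 fit on the [0,1]-index grid (see model class)."""
    return SpheroidLandscapeModel(grid).fit()


def extract_front(fit: SurfaceResults, level: float = 0.5, n_grid: int = 500) -> EC50Front:
    """EC50 front by marching squares, refined to |f - level| < 1e-3.

    The surface is evaluated on an ``n_grid`` × ``n_grid`` lattice over
    [0,1]², contoured with marching squares, and each contour point is
    corrected by one Newton step along the gradient.  Per-bacteria-row
    crossing doses are additionally found by 1-D root bracketing; an empty
    front is a valid result.
    """
    u = np.linspace(0.0, 1.0, n_grid)
    Z = fit.predict(u[None, :], u[:, None])  # rows = y, cols = x
    contours = measure.find_contours(Z, level)
    h = 1.0 / (n_grid - 1)
    polyline = []
    for c in contours:
        pts = np.column_stack([c[:, 1] * h, c[:, 0] * h])  # (x, y)
        polyline.append(_newton_refine(fit, pts, level))

    y_rows = fit.model._y
    crossings = np.full(len(y_rows), np.nan)
    for i, y in enumerate(y_rows):
        f = lambda x: fit.predict(np.array(x), np.array(y)) - level
        vals = np.array([float(f(x)) for x in u])
        sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if len(sign_change):
            j = sign_change[0]
            crossings[i] = optimize.brentq(lambda x: float(f(x)), u[j], u[j + 1],
                                           xtol=1e-10)
    return EC50Front(level, polyline, crossings, np.asarray(y_rows))


def _newton_refine(fit: SurfaceResults, pts: np.ndarray, level: float,
                   eps: float = 1e-6) -> np.ndarray:
    f = fit.predict(pts[:, 0], pts[:, 1]) - level
    gx = (fit.predict(pts[:, 0] + eps, pts[:, 1]) -
          fit.predict(pts[:, 0] - eps, pts[:, 1])) / (2 * eps)
    gy = (fit.predict(pts[:, 0], pts[:, 1] + eps) -
          fit.predict(pts[:, 0], pts[:, 1] - eps)) / (2 * eps)
    g2 = np.maximum(gx**2 + gy**2, 1e-30)
    out = pts - (f / g2)[:, None] * np.column_stack([gx, gy])
    return out


def compare_fronts(a: EC50Front, b: EC50Front) -> dict:
    """Per-row signed crossing-dose shifts ``b - a`` with a sign test.

    Shifts are in dose-index (log-dose) units; rows where either front has
    no crossing are excluded.  Positive shifts mean strain ``b`` requires
    more drug for the same mid-response (e.g. a faster degrader).
    """
    if len(a.y_rows) != len(b.y_rows) or not np.allclose(a.y_rows, b.y_rows):
        raise ValueError("fronts must share the bacteria axis")
    ok = np.isfinite(a.crossings) & np.isfinite(b.crossings)
    if not ok.any():
        raise ValueError("no bacteria rows with crossings in both fronts")
    shifts = b.crossings[ok] - a.crossings[ok]
    nonzero = shifts[shifts != 0]
    if len(nonzero):
        p = stats.binomtest(int((nonzero > 0).sum()), len(nonzero), 0.5).pvalue
    else:
        p = 1.0
    return {"rows": np.asarray(a.y_rows)[ok], "shifts": shifts,
            "mean_shift": float(shifts.mean()), "sign_test_p": float(p)}
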