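"""Quantile-quantile calibration between two single-cell measurement scales.

Two instruments observing the same per-cell quantity ``Y`` on affine scales,

    high-content:     Y = m  * X_C + d
    high-throughput:  Y = m' * X_T + d',

produce samples whose distributions belong to the same location-scale
family.  Consequently the QQ plot of the high-throughput observable
``X_T`` against the high-content observable ``X_C`` follows a straight
line with slope ``m/m'`` and intercept ``(d - d')/m'``.  Fitting that
line by least squares yields an asymptotically unbiased estimate of the
affine link, which then translates measurements from one scale to the
other.

Before the quantiles can be compared, the native observables must be put
on comparable scales:

* microscopy fluorescence intensities are logarithmized (flow cytometers
  log-amplify the fluorescence channel), and
* microscopy cell volumes are converted to cross-section areas assuming a
  spherical detached cell, ``X = (36 pi)^(1/3) * V^(2/3)`` (forward
  scatter is roughly proportional to the cell cross-section).

Microscopy misses cells dimmer than its detection limit; these cells are
present in the flow sample.  :func:`scan_cutoff` removes them by cutting
the flow sample at a threshold ``Z`` chosen to minimize a penalized QQ
residual, where the penalty discourages dropping large population
fractions.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "CalibrationMap",
    "CutoffScan",
    "log_intensity",
    "sphere_cross_section",
    "sphere_volume",
    "sample_quantiles",
    "fit_qq",
    "penalty_factor",
    "scan_cutoff",
    "translate",
]

#: (36 pi)^(1/3); prefactor of the sphere volume -> cross-section transform.
SPHERE_CONST = (36.0 * np.pi) ** (1.0 / 3.0)


@dataclasses.dataclass(frozen=True)
class CalibrationMap:
    """Affine link between the high-content and high-throughput scales.

    ``slope`` estimates m/m', ``intercept`` estimates (d - d')/m' so that
    ``x_t = slope * x_c + intercept``.
    """

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    chi2: float
    trim: float
    n_quantiles: int

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")
        if not (0 < self.trim <= 1):
            raise ValueError("trim must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class CutoffScan:
    """Result of scanning the dim-cell cut-off Z over a grid.

    ``objective`` is the penalized residual X^2 = chi2 * (1 + (n+1) p^n) / 2
    where p is the dropped fraction of the flow sample; ``z_star`` is the
    global minimizer (smallest Z on ties).
    """

    grid: np.ndarray
    chi2: np.ndarray
    p: np.ndarray
    objective: np.ndarray
    n_penalty: int
    z_star: float


def log_intensity(i_micro) -> np.ndarray:
    """Natural log of microscopy fluorescence intensities (must be > 0)."""
    i = np.asarray(i_micro, dtype=float)
    bad = np.flatnonzero(~(i > 0))
    if bad.size:
        raise ValueError(
            f"non-positive intensity at record(s) {bad[:5].tolist()}"
            f"{'...' if bad.size > 5 else ''}; cannot logarithmize"
        )
    return np.log(i)


def sphere_cross_section(volume) -> np.ndarray:
    """Volume (um^3) -> cross-section scale observable (36 pi)^(1/3) V^(2/3).

    Detached cells in suspension are approximately spherical, so the
    cross-section seen by the forward-scatter detector is a fixed power of
    the volume.  Any constant factor (e.g. the factor 4 between surface
    area and great-circle area) is absorbed by the calibration slope.
    """
    v = np.asarray(volume, dtype=float)
    if np.any(~(v > 0)):
        raise ValueError("volumes must be positive")
    return SPHERE_CONST * v ** (2.0 / 3.0)


def sphere_volume(cross_section) -> np.ndarray:
    """Inverse of :func:`sphere_cross_section`: V = (X^3 / (36 pi))^(1/2)."""
    x = np.asarray(cross_section, dtype=float)
    if np.any(~(x > 0)):
        raise ValueError("cross-section values must be positive")
    return np.sqrt(x**3 / (36.0 * np.pi))


def sample_quantiles(values, n: int) -> np.ndarray:
    """N equally spaced empirical quantiles at plotting positions (i-0.5)/N.

    Uses the inverted-CDF (order statistic) convention, so when ``n``
    equals the sample size the result is exactly the sorted sample.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to form quantiles")
    if n < 2:
        raise ValueError("need at least two quantiles")
    p = (np.arange(1, n + 1) - 0.5) / n
    s = np.sort(v)
    idx = np.clip(np.ceil(p * v.size).astype(np.intp) - 1, 0, v.size - 1)
    return s[idx]


def _trim_slice(n: int, trim: float) -> slice:
    k = int(np.floor((1.0 - trim) / 2.0 * n))
    return slice(k, n - k)


def _ols(x: np.ndarray, y: np.ndarray):
    n = x.size
    xbar = x.mean()
    ybar = y.mean()
    dx = x - xbar
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("degenerate abscissa: zero variance after trimming")
    slope = float(dx @ (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - slope * x - intercept
    chi2 = float(resid @ resid)
    dof = max(n - 2, 1)
    s2 = chi2 / dof
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    return slope, intercept, chi2, se_slope, se_intercept


def fit_qq(
    xc_q,
    xt_q,
    trim: float = 0.66,
    n_boot: int = 200,
    seed: int = 0,
) -> CalibrationMap:
    """Trimmed least-squares regression of the QQ plot X_T versus X_C.

    Parameters
    ----------
    xc_q, xt_q
        Matching quantile vectors of the high-content and high-throughput
        comparable observables (same length N).
    trim
        Central fraction of points (by rank, symmetric about the median)
        used for the regression; border quantiles are the least reliable
        and are dropped.
    n_boot
        Number of bootstrap resamples used for the standard errors.
        Neighbouring order statistics are strongly correlated, so the
        naive OLS standard errors of a QQ regression are far too small;
        the bootstrap treats each quantile vector as an N-sample from its
        distribution and resamples it.  ``n_boot=0`` falls back to the
        (optimistic) OLS errors.
    """
    x = np.asarray(xc_q, dtype=float)
    y = np.asarray(xt_q, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("quantile vectors must be 1-d and of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 quantile points")
    sl = _trim_slice(n, trim)
    if sl.stop - sl.start < 3:
        raise ValueError("fewer than 3 points remain after trimming")
    slope, intercept, chi2, se_slope, se_intercept = _ols(x[sl], y[sl])
    if n_boot:
        rng = np.random.default_rng(seed)
        ix = rng.integers(0, n, size=(n_boot, n))
        iy = rng.integers(0, n, size=(n_boot, n))
        xb = np.sort(x[ix], axis=1)[:, sl]
        yb = np.sort(y[iy], axis=1)[:, sl]
        xbar = xb.mean(axis=1, keepdims=True)
        ybar = yb.mean(axis=1, keepdims=True)
        dx = xb - xbar
        sxx = np.einsum("ij,ij->i", dx, dx)
        sxy = np.einsum("ij,ij->i", dx, yb - ybar)
        ok = sxx > 0
        slopes = sxy[ok] / sxx[ok]
        intercepts = ybar[ok, 0] - slopes * xbar[ok, 0]
        se_slope = float(np.std(slopes, ddof=1))
        se_intercept = float(np.std(intercepts, ddof=1))
    return CalibrationMap(
        slope=slope,
        intercept=intercept,
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        chi2=chi2,
        trim=trim,
        n_quantiles=n,
    )


def penalty_factor(p, n: int = 2) -> np.ndarray:
    """Penalty weight (n+1) p^n applied to the dropped fraction p.

    The prefactor n+1 makes the expectation over p ~ Uniform(0, 1) equal
    to one, so the penalty has the same magnitude as the residual term it
    is added to.
    """
    return (n + 1) * np.asarray(p, dtype=float) ** n


def scan_cutoff(
    xf,
    xm,
    grid=None,
    n_penalty: int = 2,
    trim: float = 1.0,
    min_retained: int = 10,
) -> CutoffScan:
    """Choose the flow-sample cut-off Z that best matches the microscopy sample.

    For each candidate Z only flow values ``xf > Z`` are retained; the
    microscopy quantiles are regressed against the retained flow quantiles
    and the absolute residual chi2 recorded.  The objective

        X^2 = chi2/2 + chi2 * (n+1) p^n / 2

    penalizes dropping a large fraction p of the flow population.  The
    global minimizer is returned (smallest Z on ties); grid points leaving
    fewer than ``min_retained`` values are excluded with a warning.

    The scan sums *all* squared QQ residuals (``trim=1.0``): the border
    quantiles carry most of the signal that locates the detection limit,
    so trimming them away here would flatten the minimum.  The inner-66%
    restriction belongs to the final calibration fit, after Z is chosen.
    """
    xf = np.asarray(xf, dtype=float)
    xm = np.asarray(xm, dtype=float)
    n_c = xm.size
    if grid is None:
        lo, hi = np.quantile(xf, [0.0, 0.6])
        grid = np.linspace(lo, hi, 101)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < xf.min() or grid.max() > xf.max():
            raise ValueError("grid must lie within the observed range of xf")
    xm_q = sample_quantiles(xm, n_c)
    chi2 = np.full(grid.size, np.nan)
    p = np.full(grid.size, np.nan)
    obj = np.full(grid.size, np.inf)
    for k, z in enumerate(grid):
        kept = xf[xf > z]
        if kept.size < min_retained:
            warnings.warn(
                f"cut-off Z={z:g} leaves {kept.size} < {min_retained} values; excluded",
                stacklevel=2,
            )
            continue
        xt_q = sample_quantiles(kept, n_c)
        m = fit_qq(xm_q, xt_q, trim=trim, n_boot=0)
        chi2[k] = m.chi2
        p[k] = 1.0 - kept.size / xf.size
        obj[k] = 0.5 * m.chi2 * (1.0 + penalty_factor(p[k], n_penalty))
    if not np.isfinite(obj).any():
        raise ValueError("no grid point retained enough values")
    z_star = float(grid[int(np.argmin(obj))])  # argmin -> first = smallest Z
    return CutoffScan(
        grid=grid, chi2=chi2, p=p, objective=obj, n_penalty=n_penalty, z_star=z_star
    )


def translate(values, cmap: CalibrationMap, direction: str = "c_to_t") -> np.ndarray:
    """Map values between scales: c_to_t applies x -> slope*x + intercept."""
    v = np.asarray(values, dtype=float)
    if direction == "c_to_t":
        return cmap.slope * v + cmap.intercept
    if direction == "t_to_c":
        return (v - cmap.intercept) / cmap.slope
    raise ValueError("direction must be 'c_to_t' or 't_to_c'")
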