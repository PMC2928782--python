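"""Import/export rate extraction from FRAP time courses.

A GFP-tagged shuttling protein (the motivating system is STAT5B-GFP in
unstimulated fibroblasts) cycles between nucleus and cytoplasm.  At
steady state the import and export currents are equal.  Bleaching the
nuclear pool at t=0 perturbs only the *labeled* concentrations, which
then relax according to the linear two-compartment system

    d/dt (c_cyt0, c_nuc0)^T = M (c_cyt0, c_nuc0)^T,

    M = K * [[-a_imp/V_cyt,  a_exp/V_cyt],
             [ a_imp/V_nuc, -a_exp/V_nuc]],

where a_imp = j/c_cyt and a_exp = j/c_nuc are the transport rates
normalized by the pump-capacity proxy K (1, nuclear surface area,
nuclear volume or cytoplasmic volume).  M always has eigenvalue 0
(conservation of total labeled material, V_cyt c_cyt0 + V_nuc c_nuc0 =
const) and a relaxation eigenvalue

    lambda_2 = K (a_imp/V_cyt + a_exp/V_nuc).

Measured signals are proportional to the labeled concentrations with a
possibly time-dependent scaling f(t) and continuous acquisition
bleaching e^(-eps t).  Both cancel in the compositional variables

    cyt = V_cyt S_cyt / (V_cyt S_cyt + V_nuc S_nuc),   nuc = 1 - cyt,

so the contrast y(t) = cyt * V_nuc/V_cyt - nuc * V_cyt/V_nuc is a clean
single exponential a0 e^(-a1 t) + a2 with a1 = lambda_2, from which the
rates follow:

    a_imp = a1 / [K (1/V_cyt + (c_cyt/c_nuc) / V_nuc)]
    a_exp = a1 / [K (1/V_nuc + (c_nuc/c_cyt) / V_cyt)].

Any fixed linear combination of cyt and nuc decays with the same a1;
only a0 and a2 depend on the prefactor convention, which is therefore
immaterial for rate extraction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FrapTrace",
    "RelaxationFit",
    "TransportRates",
    "CompartmentStats",
    "K_MODES",
    "resolve_k",
    "transport_matrix",
    "normalize_signals",
    "fit_relaxation",
    "fit_trace",
    "extract_rates",
    "propagate_errors",
    "cytoplasmic_concentration",
    "compartment_stats",
]

#: recognized pump-capacity normalizations
K_MODES = ("none", "area", "v_nuc", "v_cyt")


def resolve_k(
    k_mode: str, V_cyt: float, V_nuc: float, A_nuc: float | None = None
) -> float:
    """Numeric value of the normalization quantity K for a given mode.

    If the nuclear surface area is not supplied for mode ``area`` it is
    derived from the nuclear volume assuming a spherical nucleus.
    """
    if k_mode == "none":
        return 1.0
    if k_mode == "area":
        if A_nuc is None:
            A_nuc = (36.0 * np.pi) ** (1.0 / 3.0) * V_nuc ** (2.0 / 3.0)
        return float(A_nuc)
    if k_mode == "v_nuc":
        return float(V_nuc)
    if k_mode == "v_cyt":
        return float(V_cyt)
    raise ValueError(f"unknown K mode {k_mode!r}; expected one of {K_MODES}")


def transport_matrix(
    alpha_imp: float,
    alpha_exp: float,
    V_cyt: float,
    V_nuc: float,
    K: float = 1.0,
) -> np.ndarray:
    """The 2x2 generator M of the labeled-pool relaxation dynamics."""
    return K * np.array(
        [
            [-alpha_imp / V_cyt, alpha_exp / V_cyt],
            [alpha_imp / V_nuc, -alpha_exp / V_nuc],
        ]
    )


@dataclasses.dataclass
class FrapTrace:
    """One cell's FRAP time course plus geometry and prebleach context.

    ``bleach_index`` is the first post-bleach frame; times are seconds,
    volumes um^3, concentrations uM, signals arbitrary units.
    """

    t: np.ndarray
    S_cyt: np.ndarray
    S_nuc: np.ndarray
    V_cyt: float
    V_nuc: float
    c_cyt: float
    c_nuc: float
    bleach_index: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.S_cyt = np.asarray(self.S_cyt, dtype=float)
        self.S_nuc = np.asarray(self.S_nuc, dtype=float)
        if not (self.t.shape == self.S_cyt.shape == self.S_nuc.shape):
            raise ValueError("t, S_cyt, S_nuc must have matching shapes")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("V_cyt", "V_nuc", "c_cyt", "c_nuc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if np.any(self.S_cyt < 0) or np.any(self.S_nuc < 0):
            raise ValueError("signals must be non-negative")
        if not (0 <= self.bleach_index < self.t.size):
            raise ValueError("bleach_index out of range")


@dataclasses.dataclass
class RelaxationFit:
    """Exponential fit y = a0 exp(-a1 t) + a2 of the compositional contrast."""

    a0: float
    a1: float
    a2: float
    cov: np.ndarray | None
    chi2: float
    flags: tuple[str, ...] = ()

    @property
    def var_a1(self) -> float:
        return float(self.cov[1, 1]) if self.cov is not None else 0.0


@dataclasses.dataclass
class TransportRates:
    """Per-cell normalized import/export rates with provenance for errors."""

    alpha_imp: float
    alpha_exp: float
    k_mode: str
    K: float
    a1: float
    var_a1: float
    V_cyt: float
    V_nuc: float
    c_cyt: float
    c_nuc: float
    A_nuc: float | None = None
    sigma_imp: float | None = None
    sigma_exp: float | None = None


@dataclasses.dataclass
class CompartmentStats:
    """Population summaries of the compartment ratios f_V and f_c."""

    f_v_mean: float
    f_v_se: float
    f_c_mean: float
    f_c_se: float
    cor_fv_v: float
    cor_fv_v_se: float
    cor_fc_c: float
    cor_fc_c_se: float
    n: int


def normalize_signals(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Compositional variables cyt(t), nuc(t) with cyt + nuc = 1.

    Invariant under any common positive rescaling of both signals, hence
    under acquisition bleaching and time-dependent signal scaling.
    """
    wc = trace.V_cyt * trace.S_cyt
    wn = trace.V_nuc * trace.S_nuc
    tot = wc + wn
    if np.any(tot <= 0):
        raise ValueError("zero total signal at some frame")
    cyt = wc / tot
    return cyt, 1.0 - cyt


def fit_relaxation(
    cyt,
    nuc,
    V_cyt: float,
    V_nuc: float,
    t,
    bleach_index: int = 0,
) -> RelaxationFit:
    """Fit y(t) = cyt*Vn/Vc - nuc*Vc/Vn to a0 exp(-a1 t) + a2 post-bleach.

    Time is re-zeroed at the bleach frame; prebleach frames do not enter
    the fit.  Unweighted nonlinear least squares with data-driven starts
    (a2 from the tail, a0 from the initial offset, a1 from the time to
    half recovery).
    """
    cyt = np.asarray(cyt, dtype=float)
    nuc = np.asarray(nuc, dtype=float)
    t = np.asarray(t, dtype=float)
    y = cyt * (V_nuc / V_cyt) - nuc * (V_cyt / V_nuc)
    tau = t[bleach_index:] - t[bleach_index]
    yp = y[bleach_index:]
    if yp.size < 5:
        raise ValueError("need at least 5 post-bleach frames")

    scale = max(np.ptp(yp), 1e-300)
    if np.ptp(yp) < 1e-12 * (1.0 + abs(yp.mean())):
        return RelaxationFit(
            a0=0.0, a1=np.nan, a2=float(yp.mean()), cov=None, chi2=0.0,
            flags=("no_recovery",),
        )

    n_tail = max(1, yp.size // 10)
    a2_0 = float(yp[-n_tail:].mean())
    a0_0 = float(yp[0] - a2_0)
    half = np.flatnonzero(np.abs(yp - a2_0) <= 0.5 * abs(a0_0))
    if half.size and half[0] > 0:
        a1_0 = np.log(2.0) / tau[half[0]]
    else:
        a1_0 = 3.0 / tau[-1]

    def model(tt, a0, a1, a2):
        return a0 * np.exp(-a1 * tt) + a2

    try:
        popt, pcov = curve_fit(
            model, tau, yp, p0=(a0_0, a1_0, a2_0), maxfev=20000
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"relaxation fit failed to converge (starts a0={a0_0:g}, "
            f"a1={a1_0:g}, a2={a2_0:g}): {err}"
        ) from err
    resid = yp - model(tau, *popt)
    flags = []
    if popt[1] <= 0:
        flags.append("nonpositive_rate")
    if abs(popt[0]) < 1e-10 * scale:
        flags.append("no_recovery")
    return RelaxationFit(
        a0=float(popt[0]),
        a1=float(popt[1]),
        a2=float(popt[2]),
        cov=pcov,
        chi2=float(resid @ resid),
        flags=tuple(flags),
    )


def fit_trace(trace: FrapTrace) -> RelaxationFit:
    """Convenience: normalize a trace's signals and fit the relaxation."""
    cyt, nuc = normalize_signals(trace)
    return fit_relaxation(
        cyt, nuc, trace.V_cyt, trace.V_nuc, trace.t, trace.bleach_index
    )


def _denominators(K, V_cyt, V_nuc, c_cyt, c_nuc):
    d_imp = K * (1.0 / V_cyt + (c_cyt / c_nuc) / V_nuc)
    d_exp = K * (1.0 / V_nuc + (c_nuc / c_cyt) / V_cyt)
    return d_imp, d_exp


def extract_rates(
    fit: RelaxationFit,
    V_cyt: float,
    V_nuc: float,
    c_cyt: float,
    c_nuc: float,
    k_mode: str = "none",
    A_nuc: float | None = None,
) -> TransportRates:
    """Normalized rates from the fitted relaxation rate a1.

    a_imp = a1 / [K (1/V_cyt + (c_cyt/c_nuc)/V_nuc)] and the analogous
    export expression; these satisfy the steady-state equal-currents
    identity a_imp * c_cyt = a_exp * c_nuc exactly.
    """
    if not fit.a1 > 0:
        raise ValueError("relaxation rate a1 must be positive to extract rates")
    for name, v in (("V_cyt", V_cyt), ("V_nuc", V_nuc),
                    ("c_cyt", c_cyt), ("c_nuc", c_nuc)):
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    K = resolve_k(k_mode, V_cyt, V_nuc, A_nuc)
    d_imp, d_exp = _denominators(K, V_cyt, V_nuc, c_cyt, c_nuc)
    return TransportRates(
        alpha_imp=fit.a1 / d_imp,
        alpha_exp=fit.a1 / d_exp,
        k_mode=k_mode,
        K=K,
        a1=fit.a1,
        var_a1=fit.var_a1,
        V_cyt=V_cyt,
        V_nuc=V_nuc,
        c_cyt=c_cyt,
        c_nuc=c_nuc,
        A_nuc=A_nuc,
    )


def _alpha_gradients(rates: TransportRates):
    """Analytic partials of (a_imp, a_exp) w.r.t. (a1, V_cyt, V_nuc, c_cyt,
    c_nuc, A_nuc), accounting for K's dependence on the geometry."""
    a1 = rates.a1
    Vc, Vn = rates.V_cyt, rates.V_nuc
    cc, cn = rates.c_cyt, rates.c_nuc
    K = rates.K
    mode = rates.k_mode
    dK_dVc = 1.0 if mode == "v_cyt" else 0.0
    dK_dVn = 1.0 if mode == "v_nuc" else 0.0
    # for mode "area" with derived A ~ Vn^(2/3), A is treated as the
    # independent error-carrying quantity, not Vn
    dK_dA = 1.0 if mode == "area" else 0.0

    grads = {}
    for which in ("imp", "exp"):
        if which == "imp":
            B = 1.0 / Vc + (cc / cn) / Vn
            dB = {
                "V_cyt": -1.0 / Vc**2,
                "V_nuc": -(cc / cn) / Vn**2,
                "c_cyt": 1.0 / (cn * Vn),
                "c_nuc": -cc / (cn**2 * Vn),
            }
        else:
            B = 1.0 / Vn + (cn / cc) / Vc
            dB = {
                "V_cyt": -(cn / cc) / Vc**2,
                "V_nuc": -1.0 / Vn**2,
                "c_cyt": -cn / (cc**2 * Vc),
                "c_nuc": 1.0 / (cc * Vc),
            }
        D = K * B
        alpha = a1 / D
        g = {"a1": 1.0 / D}
        for name in ("V_cyt", "V_nuc", "c_cyt", "c_nuc"):
            dK = dK_dVc if name == "V_cyt" else dK_dVn if name == "V_nuc" else 0.0
            dD = K * dB[name] + dK * B
            g[name] = -alpha * dD / D
        g["A_nuc"] = -alpha * (dK_dA * B) / D
        grads[which] = g
    return grads


def propagate_errors(
    rates: TransportRates,
    rel_err_conc: float = 0.10,
    rel_err_vol: float = 0.10,
    fit_cov: np.ndarray | None = None,
) -> tuple[float, float]:
    """First-order Gaussian propagation of input uncertainties to the rates.

    Concentrations and volumes (and the nuclear area under mode ``area``)
    carry independent relative errors; the a1 variance from the fit
    covariance is included although it is typically subdominant.  Returns
    (sigma_imp, sigma_exp) and records them on ``rates``.
    """
    var_a1 = float(fit_cov[1, 1]) if fit_cov is not None else rates.var_a1
    sig = {
        "a1": np.sqrt(max(var_a1, 0.0)),
        "V_cyt": rel_err_vol * rates.V_cyt,
        "V_nuc": rel_err_vol * rates.V_nuc,
        "c_cyt": rel_err_conc * rates.c_cyt,
        "c_nuc": rel_err_conc * rates.c_nuc,
        "A_nuc": rel_err_vol * rates.K if rates.k_mode == "area" else 0.0,
    }
    grads = _alpha_gradients(rates)
    out = []
    for which in ("imp", "exp"):
        g = grads[which]
        out.append(float(np.sqrt(sum((g[k] * sig[k]) ** 2 for k in g))))
    rates.sigma_imp, rates.sigma_exp = out
    return out[0], out[1]


def cytoplasmic_concentration(V_cell, c_cell, V_nuc, c_nuc) -> np.ndarray:
    """c_cyt = (V_cell c_cell - V_nuc c_nuc) / (V_cell - V_nuc).

    Whole-cell and nuclear means are what microscopy measures directly;
    the cytoplasmic concentration follows from mass balance.  A negative
    result signals inconsistent measurements and is flagged with a
    warning rather than silently clipped.
    """
    V_cell = np.asarray(V_cell, dtype=float)
    c_cell = np.asarray(c_cell, dtype=float)
    V_nuc = np.asarray(V_nuc, dtype=float)
    c_nuc = np.asarray(c_nuc, dtype=float)
    if np.any(V_cell <= V_nuc) or np.any(V_nuc <= 0):
        raise ValueError("require V_cell > V_nuc > 0")
    c_cyt = (V_cell * c_cell - V_nuc * c_nuc) / (V_cell - V_nuc)
    if np.any(c_cyt < 0):
        warnings.warn(
            "negative cytoplasmic concentration: whole-cell and nuclear "
            "measurements are inconsistent",
            stacklevel=2,
        )
    return c_cyt


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def compartment_stats(
    cells: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> CompartmentStats:
    """Means and correlations of the compartment ratios across cells.

    ``cells`` needs columns V_cell, V_nuc, c_cell, c_nuc.  f_V =
    V_cyt/V_nuc and f_c = c_cyt/c_nuc are averaged with standard errors
    of the mean; Pearson correlations of f_V with V_cell and f_c with
    c_cell get bootstrap standard errors.  Degenerate (constant) inputs
    yield NaN correlations.
    """
    if len(cells) < 3:
        raise ValueError("need at least 3 cells")
    V_cell = np.asarray(cells["V_cell"], dtype=float)
    V_nuc = np.asarray(cells["V_nuc"], dtype=float)
    c_cell = np.asarray(cells["c_cell"], dtype=float)
    c_nuc = np.asarray(cells["c_nuc"], dtype=float)
    V_cyt = V_cell - V_nuc
    c_cyt = cytoplasmic_concentration(V_cell, c_cell, V_nuc, c_nuc)
    f_v = V_cyt / V_nuc
    f_c = c_cyt / c_nuc
    n = f_v.size

    def sem(x):
        s = np.std(x, ddof=1)
        return float(s / np.sqrt(n))

    rng = np.random.default_rng(seed)
    boot_fv = np.full(n_boot, np.nan)
    boot_fc = np.full(n_boot, np.nan)
    for b in range(n_boot):
        i = rng.integers(0, n, n)
        boot_fv[b] = _pearson(f_v[i], V_cell[i])
        boot_fc[b] = _pearson(f_c[i], c_cell[i])

    def boot_se(x):
        x = x[np.isfinite(x)]
        return float(np.std(x, ddof=1)) if x.size > 1 else np.nan

    return CompartmentStats(
        f_v_mean=float(f_v.mean()),
        f_v_se=sem(f_v),
        f_c_mean=float(f_c.mean()),
        f_c_se=sem(f_c),
        cor_fv_v=_pearson(f_v, V_cell),
        cor_fv_v_se=boot_se(boot_fv),
        cor_fc_c=_pearson(f_c, c_cell),
        cor_fc_c_se=boot_se(boot_fc),
        n=n,
    )
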