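"""Synthetic single-cell data with known ground truth.

Every downstream stage of the calibration/FRAP/transport pipeline is
testable without wet-lab data: this module draws paired microscopy and
flow-cytometry samples from the same underlying cell population,
simulates FRAP traces from the closed-form solution of the
two-compartment transport ODE, and generates Michaelis-Menten current
observations across heterogeneous cells.

The paired-population generator emulates what matters to the calibration
method and nothing more:

* lognormal cell-volume and expression distributions,
* a known affine link between the comparable measurement scales (flow
  forward scatter vs. microscopy cross-section; log-amplified flow
  fluorescence vs. log microscopy intensity),
* debris and dead-cell contamination in the flow sample, as separate
  scatter clusters with reduced forward scatter and inflated side
  scatter (separable by linear cuts),
* a dim subpopulation below the microscopy detection limit, present only
  in the flow sample: a distinct low-expression component (the
  non-induced fraction of a Tet-inducible system) whose log
  concentration is truncated just below the detection limit, plus any
  main-population cells that happen to fall below the limit.

It deliberately omits optics (point-spread functions, diffraction) and
any pixel-level image formation.  All draws are governed by explicit
seeds; there is no global RNG state.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import scipy.stats as st

from . import frap, transport
from .calibration import sphere_cross_section

__all__ = [
    "Lognormal",
    "ScaleLink",
    "PopulationTruth",
    "FrapTruth",
    "generate_paired_population",
    "simulate_frap_trace",
    "simulate_current_observations",
]


@dataclasses.dataclass(frozen=True)
class Lognormal:
    """Lognormal parameters on the log scale (mean mu, sd sigma)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("lognormal sigma must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.mu, self.sigma, n)


@dataclasses.dataclass(frozen=True)
class ScaleLink:
    """Identifiable affine link between comparable measurement scales.

    The underlying technique scales are Y = m X_C + d and Y = m' X_T + d'
    (m, m' non-zero for strictly monotonic techniques); only slope = m/m'
    and intercept = (d - d')/m' enter the observable relationship
    X_T = slope * X_C + intercept, so those are what is parameterized.
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("link slope must be non-zero (monotonic technique)")

    def forward(self, x_c) -> np.ndarray:
        return self.slope * np.asarray(x_c, dtype=float) + self.intercept


@dataclasses.dataclass(frozen=True)
class PopulationTruth:
    """Ground truth for one paired microscopy/flow cell population.

    Volumes are um^3 and concentrations uM (fibroblast-like defaults:
    median volume ~1.5 pl, GFP-fusion expression around the uM scale).
    ``dim_threshold`` is a detection limit on the microscopy log-intensity
    scale: dimmer cells are missing from the microscopy sample but remain
    in the flow sample.  ``dim_fraction`` adds a distinct non-expressing
    component (relative to the vital cells) whose log concentration is a
    truncated normal ending at the detection limit — normal-sized cells
    that the scatter gate keeps but microscopy never sees.  Contamination
    fractions refer to the final flow sample and are kept small enough
    for the fixed-quantile scatter gate to isolate (they exist to
    exercise the gate, not to model a specific instrument).
    """

    n_cells: int = 20000
    n_micro: int | None = 200
    volume_dist: Lognormal = Lognormal(mu=math.log(1500.0), sigma=0.25)
    conc_dist: Lognormal = Lognormal(mu=math.log(1.5), sigma=0.6)
    volume_link: ScaleLink = ScaleLink(slope=0.6, intercept=120.0)
    intensity_link: ScaleLink = ScaleLink(slope=0.5, intercept=-1.2)
    dim_threshold: float = -math.inf
    dim_fraction: float = 0.0
    dim_offset: float = 0.5
    dim_sigma: float = 0.45
    debris_fraction: float = 0.01
    dead_fraction: float = 0.005
    scatter_slope: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("debris_fraction", "dead_fraction", "dim_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.debris_fraction + self.dead_fraction >= 1:
            raise ValueError("contamination fractions must sum below 1")
        if self.dim_fraction > 0 and not math.isfinite(self.dim_threshold):
            raise ValueError("dim_fraction > 0 requires a finite dim_threshold")


@dataclasses.dataclass(frozen=True)
class FrapTruth:
    """Ground truth for one simulated FRAP experiment.

    Rates are normalized by the chosen K (units 1/(s * K-unit)); with
    ``K_mode='none'`` the alphas carry um^3/s.  ``c_nuc=None`` derives the
    nuclear concentration from the steady-state equal-currents condition
    alpha_imp c_cyt = alpha_exp c_nuc, the regime the extraction formulas
    assume.  ``epsilon`` is the continuous acquisition-bleaching rate and
    ``drift`` the coefficient of the linear signal scaling f(t) = 1 +
    drift * t; both cancel in the compositional transform and exist to
    falsify implementations that do not cancel them.
    """

    V_cyt: float = 1150.0
    V_nuc: float = 270.0
    c_cyt: float = 1.0
    c_nuc: float | None = None
    alpha_imp: float = 0.45
    alpha_exp: float = 0.29
    K_mode: str = "none"
    epsilon: float = 2e-4
    bleach_depth: float = 0.9
    drift: float = 5e-5
    n_pre: int = 10
    n_post: int = 240
    dt: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("V_cyt", "V_nuc", "c_cyt", "alpha_imp", "alpha_exp", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must lie in (0, 1]")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.c_nuc is None:
            object.__setattr__(
                self, "c_nuc", self.alpha_imp * self.c_cyt / self.alpha_exp
            )
        if not self.c_nuc > 0:
            raise ValueError("c_nuc must be positive")


def _vital_flow_channels(
    rng: np.random.Generator, truth: PopulationTruth, volume, conc
):
    x_vol = sphere_cross_section(volume)
    f0 = truth.volume_link.forward(x_vol)
    f1 = truth.scatter_slope * f0 * rng.lognormal(0.0, 0.15, f0.size)
    f2 = truth.intensity_link.forward(np.log(conc))
    return f0, f1, f2


def generate_paired_population(
    truth: PopulationTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a microscopy sample and a flow sample from the same population.

    Returns ``(micro, flow)``.  ``micro`` has columns ``volume`` (um^3)
    and ``intensity`` (linear fluorescence, concentration scale); cells
    below the detection limit are absent.  ``flow`` has the instrument
    channels ``F0`` (forward scatter, linear), ``F1`` (side scatter,
    linear), ``F2`` (log-amplified fluorescence) plus ground-truth
    columns ``label`` ('vital'/'dim'/'debris'/'dead') and, for intact cells,
    ``true_volume``/``true_conc`` (NaN otherwise).  Both samples are
    independent draws from the same volume and concentration
    distributions; identical seeds reproduce identical tables.
    """
    n = truth.n_cells
    if n < 10:
        raise ValueError("n_cells < 10: quantile estimation is meaningless")
    n_micro = truth.n_micro if truth.n_micro is not None else n
    if n_micro < 10:
        raise ValueError("n_micro < 10: quantile estimation is meaningless")
    rng = np.random.default_rng(truth.seed)

    # microscopy sample: direct volume/intensity records, dim cells lost
    v_m = truth.volume_dist.sample(rng, n_micro)
    c_m = truth.conc_dist.sample(rng, n_micro)
    detected = np.log(c_m) > truth.dim_threshold
    micro = pd.DataFrame({"volume": v_m[detected], "intensity": c_m[detected]})

    # flow sample: vital cells (all of them, including dim) ...
    v_f = truth.volume_dist.sample(rng, n)
    c_f = truth.conc_dist.sample(rng, n)
    f0, f1, f2 = _vital_flow_channels(rng, truth, v_f, c_f)
    parts = [
        pd.DataFrame(
            {
                "F0": f0,
                "F1": f1,
                "F2": f2,
                "label": "vital",
                "true_volume": v_f,
                "true_conc": c_f,
            }
        )
    ]

    # ... plus the non-expressing dim component, undetectable by microscopy
    if truth.dim_fraction > 0:
        n_dim = round(n * truth.dim_fraction / (1.0 - truth.dim_fraction))
        v_dim = truth.volume_dist.sample(rng, n_dim)
        hi = truth.dim_threshold
        logc_dim = st.truncnorm.rvs(
            -np.inf,
            truth.dim_offset / truth.dim_sigma,
            loc=hi - truth.dim_offset,
            scale=truth.dim_sigma,
            size=n_dim,
            random_state=rng,
        )
        c_dim = np.exp(logc_dim)
        f0_m, f1_m, f2_m = _vital_flow_channels(rng, truth, v_dim, c_dim)
        parts.append(
            pd.DataFrame(
                {
                    "F0": f0_m,
                    "F1": f1_m,
                    "F2": f2_m,
                    "label": "dim",
                    "true_volume": v_dim,
                    "true_conc": c_dim,
                }
            )
        )

    # ... plus debris / dead-cell contamination as separate clusters
    clean = 1.0 - truth.debris_fraction - truth.dead_fraction
    n_debris = round(n * truth.debris_fraction / clean)
    n_dead = round(n * truth.dead_fraction / clean)
    f0_med = float(np.median(f0))
    if n_debris:
        f0_d = f0_med * rng.uniform(0.02, 0.12, n_debris)
        f1_d = truth.scatter_slope * f0_d * rng.lognormal(np.log(2.5), 0.4, n_debris)
        f2_d = truth.intensity_link.forward(
            np.log(truth.conc_dist.sample(rng, n_debris) * 0.05)
        )
        parts.append(
            pd.DataFrame(
                {"F0": f0_d, "F1": f1_d, "F2": f2_d, "label": "debris",
                 "true_volume": np.nan, "true_conc": np.nan}
            )
        )
    if n_dead:
        v_dead = truth.volume_dist.sample(rng, n_dead)
        x_dead = sphere_cross_section(v_dead)
        f0_x = 0.35 * truth.volume_link.forward(x_dead)
        f1_x = truth.scatter_slope * f0_x * rng.lognormal(np.log(2.0), 0.3, n_dead)
        f2_x = truth.intensity_link.forward(
            np.log(truth.conc_dist.sample(rng, n_dead) * 0.3)
        )
        parts.append(
            pd.DataFrame(
                {"F0": f0_x, "F1": f1_x, "F2": f2_x, "label": "dead",
                 "true_volume": np.nan, "true_conc": np.nan}
            )
        )
    flow = pd.concat(parts, ignore_index=True)
    # fixed permutation so contamination is interleaved, not appended
    flow = flow.iloc[rng.permutation(len(flow))].reset_index(drop=True)
    return micro, flow


def simulate_frap_trace(truth: FrapTruth) -> frap.FrapTrace:
    """Simulate one FRAP trace from the closed-form ODE solution.

    The labeled-pool relaxation is evaluated exactly via the
    eigen-decomposition of the 2x2 transport generator (no numerical
    integration), the bleach removes ``bleach_depth`` of the nuclear
    labeled pool at t=0, and the emitted signals are
    S = f(t) exp(-eps t) c_L(t) plus additive Gaussian noise.
    """
    rng = np.random.default_rng(truth.seed)
    K = frap.resolve_k(truth.K_mode, truth.V_cyt, truth.V_nuc)
    M = frap.transport_matrix(
        truth.alpha_imp, truth.alpha_exp, truth.V_cyt, truth.V_nuc, K
    )
    n_frames = truth.n_pre + truth.n_post
    t = np.arange(n_frames) * truth.dt
    bleach_index = truth.n_pre
    tau = t[bleach_index:] - t[bleach_index]

    c0 = np.array([truth.c_cyt, (1.0 - truth.bleach_depth) * truth.c_nuc])
    evals, evecs = np.linalg.eig(M)
    coef = np.linalg.solve(evecs, c0)
    # c(tau) = sum_k coef_k e^{lambda_k tau} v_k, exact for the linear ODE
    modes = coef[None, :] * np.exp(np.outer(tau, evals))
    c_post = modes @ evecs.T  # (n_post, 2)

    c_l = np.empty((n_frames, 2))
    c_l[:bleach_index] = (truth.c_cyt, truth.c_nuc)
    c_l[bleach_index:] = np.real(c_post)

    scaling = (1.0 + truth.drift * t) * np.exp(-truth.epsilon * t)
    s = scaling[:, None] * c_l
    if truth.noise_sd > 0:
        s = s + rng.normal(0.0, truth.noise_sd, s.shape)
    s = np.clip(s, 0.0, None)
    return frap.FrapTrace(
        t=t,
        S_cyt=s[:, 0],
        S_nuc=s[:, 1],
        V_cyt=truth.V_cyt,
        V_nuc=truth.V_nuc,
        c_cyt=truth.c_cyt,
        c_nuc=truth.c_nuc,
        bleach_index=bleach_index,
    )


def simulate_current_observations(
    beta: float,
    gamma: float,
    mode: str = "v_nuc",
    n: int = 39,
    noise_cv: float = 0.1,
    seed: int = 0,
    direction: str = "imp",
    conc_span: tuple[float, float] = (0.1, 10.0),
) -> pd.DataFrame:
    """Per-cell transport-current observations under a saturable pump.

    Concentrations are drawn log-uniformly over ``conc_span`` times the
    half-saturation gamma so the fit sees both the linear and the
    saturated regime.  The raw current is I = K * beta c/(gamma + c) with
    K the cell's normalization quantity for ``mode`` (so the currents are
    exactly Michaelis-Menten after dividing by K), times multiplicative
    Gaussian noise of relative size ``noise_cv``.  Heterogeneous per-cell
    A_nuc, V_nuc, V_cyt are attached so all four normalizations can be
    formed downstream.

    Returns a table with columns c, I, sigma_I, A_nuc, V_nuc, V_cyt,
    direction.
    """
    if not (beta > 0 and gamma > 0):
        raise ValueError("beta and gamma must be positive")
    if mode not in frap.K_MODES:
        raise ValueError(f"mode must be one of {frap.K_MODES}")
    rng = np.random.default_rng(seed)
    c = gamma * np.exp(
        rng.uniform(np.log(conc_span[0]), np.log(conc_span[1]), n)
    )
    v_nuc = rng.lognormal(np.log(270.0), 0.3, n)
    v_cyt = 4.27 * v_nuc * rng.lognormal(0.0, 0.2, n)
    a_nuc = (36.0 * np.pi) ** (1.0 / 3.0) * v_nuc ** (2.0 / 3.0)
    k = {"none": np.ones(n), "area": a_nuc, "v_nuc": v_nuc, "v_cyt": v_cyt}[mode]
    ideal = k * transport.michaelis_menten_current(c, beta, gamma)
    noise = 1.0 + noise_cv * rng.standard_normal(n) if noise_cv > 0 else 1.0
    current = ideal * noise
    return pd.DataFrame(
        {
            "c": c,
            "I": current,
            "sigma_I": noise_cv * np.abs(ideal),
            "A_nuc": a_nuc,
            "V_nuc": v_nuc,
            "V_cyt": v_cyt,
            "direction": direction,
        }
    )
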