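"""Michaelis-Menten transport-current fitting and normalization ranking.

Nuclear import/export of a shuttling protein through a finite set of
pores with limited transport cofactors saturates with cargo
concentration; the population-level current follows a Michaelis-Menten
curve I(c) = beta c / (gamma + c).  Since the pump capacity may scale
with a per-cell quantity K — nuclear surface area (pore count),
cytoplasmic or nuclear volume (cofactor abundance) — currents are
compared after normalizing by K under four hypotheses: none, A_nuc,
V_nuc, V_cyt.  Each hypothesis is fitted by weighted nonlinear least
squares and the hypotheses are ranked by a cell-resampling bootstrap of
the pairwise chi-square differences.

Observation tables use columns ``c`` (originating-compartment
concentration, uM), ``I`` (raw current), optional ``sigma_I``
(propagated error of I), ``A_nuc``/``V_nuc``/``V_cyt`` (normalization
quantities) and ``direction`` ('imp' or 'exp').
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MODES",
    "MMFit",
    "ModelComparison",
    "michaelis_menten_current",
    "normalize_current",
    "fit_mm",
    "compare_models",
    "superiority",
]

MODES = ("none", "area", "v_nuc", "v_cyt")

_K_COLUMN = {"area": "A_nuc", "v_nuc": "V_nuc", "v_cyt": "V_cyt"}


@dataclasses.dataclass
class MMFit:
    """Fitted Michaelis-Menten parameters for one direction x normalization."""

    beta: float
    gamma: float
    se_beta: float
    se_gamma: float
    chi2: float
    mode: str = "none"
    direction: str = ""
    flags: tuple[str, ...] = ()


@dataclasses.dataclass
class ModelComparison:
    """Bootstrap ranking of the four normalization hypotheses.

    ``q[direction]`` is a 4x4 DataFrame (rows i, columns j) of
    q_ij = P(chi2_i - chi2_j < 0) + P(tie)/2 over bootstrap resamples of
    the cells; small q_ij means model j fits better than model i.  Exact
    ties count half toward each side, so q_ij + q_ji = 1 and two models
    fitted to identical data come out at exactly 0.5 (no false
    discrimination); the uninformative diagonal is set to 0.
    """

    q: dict[str, pd.DataFrame]
    B: int
    seed: int
    n_failed: dict[str, int]


def michaelis_menten_current(c, beta: float, gamma: float) -> np.ndarray:
    """I(c) = beta c / (gamma + c); saturates at beta, half-saturates at gamma."""
    if not (beta > 0 and gamma > 0):
        raise ValueError("beta and gamma must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return beta * c / (gamma + c)


def normalize_current(I, K) -> np.ndarray:
    """j = I / K; K is the per-cell pump-capacity quantity (K=1 for 'none')."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("normalization quantity K must be positive")
    return np.asarray(I, dtype=float) / K


def _fit_core(c: np.ndarray, j: np.ndarray, w: np.ndarray):
    """Weighted MM fit in log-parameters; returns (logb, logg, resid, jac)."""
    u0 = np.array([np.log(max(j.max(), 1e-300)), np.log(np.median(c))])

    def resid(u):
        b, g = np.exp(u)
        return (j - b * c / (g + c)) * w

    def jac(u):
        b, g = np.exp(u)
        m = b * c / (g + c)
        return np.column_stack((-m * w, (m * g / (g + c)) * w))

    res = least_squares(resid, u0, jac=jac, method="lm", xtol=1e-13, ftol=1e-13)
    if not res.success:
        raise RuntimeError(f"Michaelis-Menten fit failed: {res.message}")
    return res


def fit_mm(
    observations: pd.DataFrame,
    floor_fraction: float = 0.05,
    mode: str = "none",
    direction: str = "",
) -> MMFit:
    """Weighted least-squares Michaelis-Menten fit of normalized currents.

    ``observations`` needs columns ``c`` and ``j`` (already normalized)
    and optionally ``sigma`` (propagated per-point error).  Total weights
    use sigma_i^2 + sigma_0^2 with the constant floor sigma_0 =
    floor_fraction * max(j), which prevents near-zero currents from
    dominating the fit.  Positivity of (beta, gamma) is enforced by
    fitting log-parameters with a damped (Levenberg-Marquardt) solver;
    standard errors come from the curvature at the optimum.  A gamma
    estimate far outside the observed concentration range is flagged as
    unidentifiable.
    """
    c = np.asarray(observations["c"], dtype=float)
    j = np.asarray(observations["j"], dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(c) <= 0:
        raise ValueError("degenerate concentration range")
    sigma = (
        np.asarray(observations["sigma"], dtype=float)
        if "sigma" in observations
        else np.zeros_like(j)
    )
    floor = floor_fraction * np.max(np.abs(j))
    tot = np.sqrt(sigma**2 + floor**2)
    if np.any(tot <= 0):
        tot = np.ones_like(j)  # unweighted fallback
    w = 1.0 / tot

    res = _fit_core(c, j, w)
    beta, gamma = np.exp(res.x)
    chi2 = float(res.fun @ res.fun)
    try:
        cov_u = np.linalg.inv(res.jac.T @ res.jac)
        se_beta = beta * np.sqrt(max(cov_u[0, 0], 0.0))
        se_gamma = gamma * np.sqrt(max(cov_u[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_beta = se_gamma = np.nan
    flags = []
    if gamma < 1e-2 * c.min() or gamma > 1e2 * c.max():
        flags.append("gamma_unidentifiable")
    return MMFit(
        beta=float(beta),
        gamma=float(gamma),
        se_beta=float(se_beta),
        se_gamma=float(se_gamma),
        chi2=chi2,
        mode=mode,
        direction=direction,
        flags=tuple(flags),
    )


def _k_values(obs: pd.DataFrame, mode: str) -> np.ndarray:
    if mode == "none":
        return np.ones(len(obs))
    return np.asarray(obs[_K_COLUMN[mode]], dtype=float)


def fit_mode(
    obs: pd.DataFrame,
    mode: str,
    floor_fraction: float = 0.05,
    direction: str = "",
) -> MMFit:
    """Normalize raw currents by the mode's K and fit the MM curve."""
    k = _k_values(obs, mode)
    tab = pd.DataFrame(
        {"c": np.asarray(obs["c"], dtype=float), "j": normalize_current(obs["I"], k)}
    )
    if "sigma_I" in obs:
        tab["sigma"] = np.asarray(obs["sigma_I"], dtype=float) / k
    return fit_mm(tab, floor_fraction=floor_fraction, mode=mode, direction=direction)


def _chi2_all_modes(obs: pd.DataFrame, floor_fraction: float) -> np.ndarray:
    c = np.asarray(obs["c"], dtype=float)
    i_raw = np.asarray(obs["I"], dtype=float)
    s_raw = (
        np.asarray(obs["sigma_I"], dtype=float)
        if "sigma_I" in obs
        else np.zeros_like(i_raw)
    )
    out = np.empty(len(MODES))
    for m, mode in enumerate(MODES):
        k = _k_values(obs, mode)
        j = i_raw / k
        sigma = s_raw / k
        floor = floor_fraction * np.max(np.abs(j))
        tot = np.sqrt(sigma**2 + floor**2)
        if np.any(tot <= 0):
            tot = np.ones_like(j)
        res = _fit_core(c, j, 1.0 / tot)
        out[m] = float(res.fun @ res.fun)
    return out


def compare_models(
    observations: pd.DataFrame,
    B: int = 10000,
    seed: int = 0,
    floor_fraction: float = 0.05,
    max_failure_fraction: float = 0.05,
) -> ModelComparison:
    """Bootstrap chi-square ranking of the four normalization hypotheses.

    Per replicate, the cells of each direction are resampled with
    replacement, all four models refitted, and the pairwise differences
    delta_ij = chi2_i - chi2_j recorded; q_ij is the fraction of
    replicates with delta_ij < 0, plus half the fraction of exact ties.
    Replicates whose fits fail are excluded and counted; more than
    ``max_failure_fraction`` of failures aborts.
    """
    rng = np.random.default_rng(seed)
    q = {}
    n_failed = {}
    for direction, obs in observations.groupby("direction"):
        obs = obs.reset_index(drop=True)
        n = len(obs)
        less = np.zeros((len(MODES), len(MODES)))
        used = 0
        failed = 0
        for _ in range(B):
            idx = rng.integers(0, n, n)
            try:
                chi2 = _chi2_all_modes(obs.iloc[idx], floor_fraction)
            except (RuntimeError, np.linalg.LinAlgError):
                failed += 1
                if failed > max_failure_fraction * B:
                    raise RuntimeError(
                        f"more than {max_failure_fraction:.0%} of bootstrap "
                        f"fits failed for direction {direction!r}"
                    )
                continue
            delta = chi2[:, None] - chi2[None, :]
            less += (delta < 0) + 0.5 * (delta == 0)
            used += 1
        qmat = less / max(used, 1)
        np.fill_diagonal(qmat, 0.0)
        q[direction] = pd.DataFrame(qmat, index=list(MODES), columns=list(MODES))
        n_failed[direction] = failed
    return ModelComparison(q=q, B=B, seed=seed, n_failed=n_failed)


def superiority(q: pd.DataFrame, p: float) -> pd.DataFrame:
    """Pairwise verdicts at confidence 1 - p from a bootstrap q matrix.

    q_ij < p: column model j is superior to row model i; q_ij > 1 - p:
    row model i is superior; otherwise the pair is indistinguishable.
    """
    if not 0 < p < 0.5:
        raise ValueError("p must lie in (0, 0.5)")
    vals = q.to_numpy()
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("q values must lie in [0, 1]")
    verdict = np.full(vals.shape, "indistinguishable", dtype=object)
    verdict[vals < p] = "column"
    verdict[vals > 1 - p] = "row"
    np.fill_diagonal(verdict, "-")
    return pd.DataFrame(verdict, index=q.index, columns=q.columns)
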