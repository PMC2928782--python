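"""Population-level prediction of transport-current distributions.

Once the flow cytometer is calibrated against microscopy, every gated
flow event yields an absolute cell volume and whole-cell concentration.
Flow cytometry cannot resolve compartments, so the population-mean
ratios f_V = V_cyt/V_nuc and f_c = c_cyt/c_nuc (determined from the
microscopy/FRAP cells) split each cell into nucleus and cytoplasm:

    V_nuc = V_cell / (1 + f_V)          V_cyt = V_cell f_V / (1 + f_V)
    c_nuc = c_cell (1 + f_V) / (1 + f_c f_V)    c_cyt = f_c c_nuc,

which conserve volume and mass exactly.  Scalar means are used because
the measured correlations of f_V with cell volume and f_c with total
concentration are negligible; a per-cell regression would not improve
the estimate.  Applying the fitted saturable-pump curves to the
compartment concentrations then predicts the per-cell import and export
currents, normalized to the originating compartment (cytoplasm for
import, nucleus for export), for the whole population.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .calibration import CalibrationMap, sphere_volume, translate
from .transport import MMFit, michaelis_menten_current

__all__ = [
    "PopulationPrediction",
    "absolute_from_flow",
    "split_compartments",
    "predict_currents",
    "summarize",
]


@dataclasses.dataclass
class PopulationPrediction:
    """Per-cell absolute quantities and predicted currents for a population.

    ``per_cell`` holds V_cell, c_cell, V_nuc, V_cyt, c_nuc, c_cyt, j_imp,
    j_exp (currents per unit originating-compartment volume); ``summary``
    maps direction -> summary statistics, ``density`` direction -> KDE
    table.
    """

    per_cell: pd.DataFrame
    summary: dict
    density: dict


def absolute_from_flow(
    events: pd.DataFrame,
    vol_map: CalibrationMap,
    int_map: CalibrationMap,
    z_star: float | None = None,
    f0: str = "F0",
    f2: str = "F2",
) -> tuple[pd.DataFrame, int]:
    """Translate gated flow events to absolute volumes and concentrations.

    Forward scatter is mapped back to the microscopy cross-section scale
    and inverted to a volume, V = (X^3/(36 pi))^(1/2); the log-amplified
    fluorescence channel is mapped back to the microscopy log-intensity
    scale and exponentiated.  Events at or below the dim-cell cut-off
    ``z_star`` (on the flow fluorescence scale) are excluded, as are
    events whose back-translated cross-section is non-positive; the
    second return value counts all exclusions.
    """
    f0_vals = np.asarray(events[f0], dtype=float)
    f2_vals = np.asarray(events[f2], dtype=float)
    keep = np.ones(f0_vals.size, dtype=bool)
    if z_star is not None:
        keep &= f2_vals > z_star
    x_vol = translate(f0_vals, vol_map, "t_to_c")
    keep &= x_vol > 0
    n_excluded = int(np.count_nonzero(~keep))
    v_cell = sphere_volume(x_vol[keep])
    c_cell = np.exp(translate(f2_vals[keep], int_map, "t_to_c"))
    return pd.DataFrame({"V_cell": v_cell, "c_cell": c_cell}), n_excluded


def split_compartments(V_cell, c_cell, f_V: float, f_c: float) -> pd.DataFrame:
    """Split whole-cell quantities into compartments via the mean ratios.

    Returns a table with V_nuc, V_cyt, c_nuc, c_cyt satisfying
    V_nuc + V_cyt = V_cell and c_cyt V_cyt + c_nuc V_nuc = c_cell V_cell
    exactly.
    """
    if not (f_V > 0 and f_c > 0):
        raise ValueError("f_V and f_c must be positive")
    V_cell = np.asarray(V_cell, dtype=float)
    c_cell = np.asarray(c_cell, dtype=float)
    if np.any(V_cell <= 0) or np.any(c_cell <= 0):
        raise ValueError("volumes and concentrations must be positive")
    v_nuc = V_cell / (1.0 + f_V)
    v_cyt = V_cell * f_V / (1.0 + f_V)
    c_nuc = c_cell * (1.0 + f_V) / (1.0 + f_c * f_V)
    c_cyt = f_c * c_nuc
    return pd.DataFrame(
        {"V_nuc": v_nuc, "V_cyt": v_cyt, "c_nuc": c_nuc, "c_cyt": c_cyt}
    )


def predict_currents(
    compartments: pd.DataFrame, mm_imp: MMFit, mm_exp: MMFit
) -> PopulationPrediction:
    """Per-cell import/export currents from the fitted saturation curves.

    j_imp = beta_imp c_cyt/(gamma_imp + c_cyt) per unit cytoplasmic
    volume; j_exp analogous with the nuclear concentration and volume.
    The two fits must share the originating-compartment normalization
    convention: import normalized by V_cyt and export by V_nuc (or both
    unnormalized).
    """
    ok = (mm_imp.mode == "v_cyt" and mm_exp.mode == "v_nuc") or (
        mm_imp.mode == mm_exp.mode == "none"
    )
    if not ok:
        raise ValueError(
            "mismatched normalization modes: expected import 'v_cyt' with "
            f"export 'v_nuc' (or both 'none'), got {mm_imp.mode!r}/{mm_exp.mode!r}"
        )
    per_cell = compartments.copy()
    per_cell["j_imp"] = michaelis_menten_current(
        per_cell["c_cyt"], mm_imp.beta, mm_imp.gamma
    )
    per_cell["j_exp"] = michaelis_menten_current(
        per_cell["c_nuc"], mm_exp.beta, mm_exp.gamma
    )
    summary, density = summarize(per_cell)
    return PopulationPrediction(per_cell=per_cell, summary=summary, density=density)


def summarize(
    per_cell: pd.DataFrame,
    directions: tuple[str, ...] = ("j_imp", "j_exp"),
    n_grid: int = 512,
) -> tuple[dict, dict]:
    """Summary statistics and kernel density estimates of the currents.

    The KDE uses Silverman's bandwidth and a grid extending eight
    bandwidths past the data range, so the density integrates to one to
    high accuracy.  Degenerate (zero-variance) inputs get a point-mass
    summary and no density table.
    """
    if len(per_cell) == 0:
        raise ValueError("empty prediction")
    summary: dict = {}
    density: dict = {}
    for col in directions:
        x = np.asarray(per_cell[col], dtype=float)
        qs = np.quantile(x, [0.05, 0.25, 0.5, 0.75, 0.95])
        summary[col] = {
            "mean": float(x.mean()),
            "var": float(x.var(ddof=1)) if x.size > 1 else 0.0,
            "n": int(x.size),
            "quantiles": dict(zip(("q05", "q25", "q50", "q75", "q95"), map(float, qs))),
        }
        if np.ptp(x) > 0 and x.size > 1:
            kde = gaussian_kde(x, bw_method="silverman")
            bw = kde.factor * x.std(ddof=1)
            grid = np.linspace(x.min() - 8 * bw, x.max() + 8 * bw, n_grid)
            density[col] = pd.DataFrame({"x": grid, "density": kde(grid)})
    return summary, density
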