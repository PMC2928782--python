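# cytolink

Link high-content single-cell microscopy with high-throughput flow
cytometry, and predict nucleocytoplasmic transport-current distributions
for whole cell populations.

## The problem

Some single-cell quantities can only be measured slowly and on few cells
(confocal microscopy, FRAP), while flow cytometry measures thousands of
cells per run but only coarse whole-cell observables on arbitrary
instrument scales.  `cytolink` implements a model-based workflow that
combines the two, using the nucleocytoplasmic cycling of a GFP-tagged
transcription factor (STAT5B-GFP in fibroblasts) as the motivating
system:

1. **Gating** (`cytolink.gating`).  Flow samples contain debris and dead
   cells.  A line is fitted through the forward/side-scatter cloud by
   no-intercept regression (slope `s = ΣF0F1/ΣF0²`) and two cuts
   perpendicular to it retain the vital-cell band.

2. **QQ calibration** (`cytolink.calibration`).  If both techniques
   observe the same quantity *Y* on affine scales, `Y = m X_C + d` and
   `Y = m' X_T + d'`, the two observables' distributions belong to one
   location-scale family and the quantile-quantile plot of `X_T` against
   `X_C` is a straight line with slope `m/m'` and intercept `(d−d')/m'`.
   Comparable scales first: microscopy intensities are logarithmized
   (the flow fluorescence channel is log-amplified), and microscopy
   volumes become cross-sections `X = (36π)^{1/3} V^{2/3}` (forward
   scatter ∝ cross-section of the roughly spherical detached cell).
   Cells below the microscopy detection limit are removed from the flow
   sample by a cut-off *Z* minimizing the penalized residual
   `X² = ½χ² + ½χ²(n+1)pⁿ` (p = dropped fraction, n = 2); the final
   regression uses the inner 66% of quantile points.

3. **FRAP kinetics** (`cytolink.frap`).  After bleaching the nuclear
   pool, labeled concentrations relax by the linear two-compartment
   system with generator `M = K [[-α_imp/V_cyt, α_exp/V_cyt],
   [α_imp/V_nuc, -α_exp/V_nuc]]`; one eigenvalue is 0 (conservation),
   the other `λ₂ = K(α_imp/V_cyt + α_exp/V_nuc)`.  The compositional
   signals `cyt = V_cyt S_cyt/(V_cyt S_cyt + V_nuc S_nuc)`, `nuc = 1 −
   cyt` cancel acquisition bleaching and any time-dependent signal
   scaling; the contrast `cyt·V_nuc/V_cyt − nuc·V_cyt/V_nuc` is fitted
   to `a₀e^{−a₁t} + a₂`, and `a₁ = λ₂` yields the import/export rates
   with Gaussian error propagation (≈10% relative errors on volumes and
   concentrations dominate).

4. **Saturable pump** (`cytolink.transport`).  Transport currents follow
   Michaelis-Menten kinetics `I(c) = βc/(γ+c)`.  Because pump capacity
   may scale with nuclear surface area, nuclear volume or cytoplasmic
   volume, currents are fitted under all four normalization hypotheses
   and ranked by a cell-resampling bootstrap of pairwise χ² differences
   (`q_ij = P(χ²_i − χ²_j < 0)`; `q_ij < p` ⇒ model *j* superior at
   confidence 1−p).

5. **Population prediction** (`cytolink.population`).  Calibrated flow
   events become absolute per-cell volumes and concentrations, split
   into compartments by the population-mean ratios `f_V = V_cyt/V_nuc`
   and `f_c = c_cyt/c_nuc`, and the fitted pump curves predict each
   cell's import and export currents.

A first-class synthetic-data generator (`cytolink.synth`) emulates all
three input kinds — paired microscopy/flow populations with a known
affine link, debris/dead contamination and a dim subpopulation; FRAP
traces from the closed-form ODE solution with continuous bleaching and
signal drift; saturable-pump current observations — so the entire
pipeline is testable against known ground truth.

## Worked example

```python
import numpy as np
from cytolink import synth, gating, calibration as cal, population, transport

truth = synth.PopulationTruth(n_cells=20000, n_micro=1000, seed=7)
micro, flow = synth.generate_paired_population(truth)

# gate out debris/dead events
g = gating.gate_events(flow, gating.choose_cuts(flow, gating.fit_scatter_axis(flow)))

# calibrate the volume channel: cross-section scale vs forward scatter
nq = len(micro)
vol_map = cal.fit_qq(
    cal.sample_quantiles(cal.sphere_cross_section(micro["volume"]), nq),
    cal.sample_quantiles(np.asarray(g["F0"], float), nq))

# calibrate the fluorescence channel with the dim-cell cut-off scan
xm = cal.log_intensity(micro["intensity"]); xf = np.asarray(g["F2"], float)
scan = cal.scan_cutoff(xf, xm)
int_map = cal.fit_qq(cal.sample_quantiles(xm, nq),
                     cal.sample_quantiles(xf[xf > scan.z_star], nq))

# absolute quantities, compartment split, predicted currents
mm_imp = transport.MMFit(22.14, 3.43, 0, 0, 0, mode="v_cyt", direction="imp")
mm_exp = transport.MMFit(40.13, 6.81, 0, 0, 0, mode="v_nuc", direction="exp")
absolute, _ = population.absolute_from_flow(g, vol_map, int_map, z_star=scan.z_star)
comp = population.split_compartments(absolute["V_cell"], absolute["c_cell"],
                                     f_V=4.27, f_c=0.645)
pred = population.predict_currents(comp, mm_imp, mm_exp)
```

This run gates 19491 of 20305 events, recovers the volume-channel link
as slope 0.628 ± 0.031, intercept 106 ± 19 (simulated truth 0.6, 120)
and the fluorescence link as slope 0.473 ± 0.023, intercept −1.179 ±
0.015 (truth 0.5, −1.2) with cut-off `z* = −1.75`, and yields 19356
cells with mean volume 1504 µm³ and mean concentration 1.80 µM.  The
predicted currents, normalized to the originating compartment, have mean
(variance) 6.55 (7.3) for import and 10.04 (20.0) for export — the
per-cell distribution that a whole-cell measurement alone could not
provide.

A FRAP trace fitted with `frap.fit_trace` on 2%-noise synthetic data
gives `a₁ = 1.52e-3 /s` against a ground-truth relaxation rate of
`1.47e-3 /s`, and `frap.extract_rates` plus `propagate_errors` turn it
into `α_imp = 4.07e-4 ± 0.6e-4`, `α_exp = 2.62e-4 ± 0.29e-4` per unit of
the chosen capacity normalization.

The same pipeline is scriptable from the shell (`cytolink simulate`,
`gate`, `calibrate`, `frap-fit`, `mm-fit`, `predict --config ...`); see
`cytolink --help`.

## Limitations

See `docs/methods.md` for the model assumptions, parameter defaults,
what the synthetic data does and does not emulate, and numerical
choices.
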