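# Methods

## Scope and model

`cytolink` treats a measurement technique as a strictly monotonic map
between a quantity of interest and an instrument observable, linear on a
suitably chosen scale.  Two techniques observing the same per-cell
quantity then produce samples in a common location-scale family, and the
affine link between their scales is identifiable from the
quantile-quantile (QQ) plot alone — no cell-by-cell pairing is needed,
only that both samples come from the same population.  This is the
central assumption: the *identical* cell population must be measured by
both techniques, and any preprocessing (gating, detection-limit cut)
must leave the two retained subpopulations distributionally matched.

The biological model is steady-state nucleocytoplasmic cycling of a
GFP-tagged shuttling protein.  At equilibrium the import and export
currents are equal (`j_imp = j_exp = j`), and only the *labeled* pools
are perturbed by photobleaching, so the relaxation is linear even though
the underlying pump saturates.  The pump model is Michaelis-Menten,
`I(c) = βc/(γ+c)`, with the capacity (β and the initial slope β/γ)
proportional to a per-cell quantity K — nuclear surface area (pore
count) or a compartment volume (transport-cofactor abundance) — while γ
is a cell-independent constant.  These proportionalities are what make a
population-level current formula possible at all.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `trim` (final QQ fit) | 0.66 | – | border quantiles are systematically off when the two instruments see slightly different subpopulations; inner-66% by symmetric rank |
| `n_penalty` | 2 | – | quadratic penalty; prefactor n+1 makes E[(n+1)pⁿ] = 1 over p~U(0,1), so penalty and residual have equal magnitude |
| Z grid | 101 points, 0–60th percentile of X_F | flow scale | dim cells live in the lower tail; scanning past the 60th percentile would discard the bulk |
| gate band | (0.02, 0.98) | projection quantiles | reproducible surrogate for cuts placed by eye |
| `rel_err_conc`, `rel_err_vol` | 0.10 | – | typical relative accuracy of confocal volume/concentration estimates |
| `floor_fraction` | 0.05 | of max current | constant error floor keeps near-zero currents from dominating the weighted fit |
| bootstrap B | 10000 (ranking), 200 (QQ SEs) | – | ranking needs tail probabilities; SEs only need ~5% precision |
| `f_V`, `f_c` | 4.27, 0.645 | – | population-mean compartment ratios of the motivating system |
| MM defaults in examples | β 22.14/40.13, γ 3.43/6.81 | per unit K; µM | magnitudes of originating-compartment-normalized fits in the motivating system |

Internal units are µm³ (volumes), µm² (areas), µM (concentrations),
seconds (time); currents are per unit of the chosen normalization K.

## Numerical choices

* **Quantiles.**  Plotting positions `(i−0.5)/N` with the inverted-CDF
  convention, so N quantiles of an N-sample are exactly the sorted
  sample.  Implemented by direct order-statistic indexing (the generic
  quantile routine is orders of magnitude slower for thousands of
  probability points).
* **QQ standard errors.**  Neighbouring order statistics are strongly
  positively correlated; ordinary least-squares standard errors on a QQ
  plot undercover badly (≈19% coverage at nominal 3σ in our
  simulations).  `fit_qq` therefore bootstraps each quantile vector as
  an N-sample (B=200 by default).  On the larger sample's side this
  overstates the noise, making the errors mildly conservative.
* **Cut-off scan.**  The scan minimizes `X² = ½χ²(1 + (n+1)pⁿ)` over the
  grid, taking the global minimum and the smallest Z on ties.  The
  scan's χ² sums *all* squared QQ residuals (`trim=1.0`): the border
  quantiles carry the detection-limit signal, and trimming them flattens
  the minimum beyond recovery.  The inner-66% restriction applies to the
  final calibration fit only.  Grid points leaving fewer than 10 values
  are excluded with a warning.
* **Relaxation fit.**  Three free parameters (a₀, a₁, a₂), unweighted
  least squares, time re-zeroed at the first post-bleach frame.
  Initialization: a₂ from the last 10% of points, a₀ from the initial
  offset, a₁ from the time to half recovery.  The contrast prefactors
  V_nuc/V_cyt and −V_cyt/V_nuc are a convention; any fixed linear
  combination of `cyt` and `nuc` decays with the same a₁, so only a₀
  and a₂ depend on this choice.  Flat traces are flagged
  (`no_recovery`) rather than fitted.
* **Michaelis-Menten fit.**  Log-parameterization of (β, γ) enforces
  positivity inside a damped (Levenberg-Marquardt) least-squares solver
  with analytic Jacobian; starts β₀ = max j, γ₀ = median c.  Standard
  errors from the curvature at the optimum.  γ estimates outside
  [min c/100, 100 max c] are flagged unidentifiable.
* **Bootstrap ranking.**  Cells (not residuals) are resampled with
  replacement, per direction.  q_ij = P(δ_ij < 0) + P(δ_ij = 0)/2: exact
  ties split evenly, so q_ij + q_ji = 1 and two models fitted to
  identical data are exactly indistinguishable (q = ½); the
  uninformative diagonal is reported as 0.  Replicates with failed fits
  are excluded and counted; >5% failures abort.
* **Error propagation.**  First-order Gaussian propagation with analytic
  gradients of the rate formulas, treating c_cyt, c_nuc, V_cyt, V_nuc
  (and A_nuc under the area normalization) as independent.  When K is
  itself one of the volumes, its contribution enters through that
  volume's derivative, not twice.
* **Density estimates.**  Gaussian KDE with Silverman bandwidth on a
  grid extending eight bandwidths past the data range (integral accurate
  to ~1e-15); zero-variance inputs get a point-mass summary, no KDE.

## The synthetic-data generator

`synth` emulates exactly the features the pipeline must cope with:
lognormal volume (median 1500 µm³, σ_log 0.25) and expression (median
1.5 µM, σ_log 0.6) distributions; a known affine link per channel;
side scatter proportional to forward scatter with lognormal granularity
noise; debris (very low F0, inflated F1/F0) and dead-cell (shrunken F0,
inflated F1/F0) clusters; a non-expressing dim component truncated just
below the microscopy detection limit (the non-induced fraction of a
Tet-inducible expression system); FRAP traces computed from the exact
eigen-decomposition of the 2×2 transport generator, with continuous
bleaching `e^{−εt}` and a linear signal drift `f(t) = 1 + δt` (defaults
ε = 2e-4/s, δ = 5e-5/s, |δ|·T ≈ 0.12) deliberately large enough to
falsify implementations that do not cancel them.

Default contamination (1% debris, 0.5% dead) is intentionally small:
the fixed-quantile gate band (0.02, 0.98) can remove at most ~4% of
events, so these defaults are chosen for separability by the default
gate rather than to model a particular instrument; the cells' noise
magnitudes likewise are chosen for test power, not measured realism.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: optics (PSF, diffraction, z-stack
segmentation error), intra-compartment diffusion during FRAP (the
two-compartment model assumes well-mixed pools), bleach-spot geometry,
instrument saturation and spectral spillover in the cytometer, and any
deviation of detached cells from sphericity.  Real calibrations must
also contend with the two techniques genuinely seeing different
subpopulations, which here exists only in the controlled forms above.

## Measurement-design notes

* The one-grid-step localization of the detection-limit cut-off is a
  large-sample property: with a 200-cell microscopy sample the scan
  minimum has a sampling scatter of many grid steps, because the χ²
  signal of a one-step mis-cut is far below the quantile noise floor.
  The recovery checks therefore use 5×10⁴–10⁵ cells per sample and
  report the median offset over three replicate simulations.
* Likewise, the end-to-end population recovery (KS < 0.05, mean current
  within 2%) uses a 5000-cell microscopy calibration; with 200 cells the
  calibration slope noise alone produces mean-current errors of up to
  ~5%.
* The bootstrap ranking at B = 1000 resolves tail probabilities to
  ~0.01; the production default B = 10⁴ sharpens the 99%-confidence
  verdicts.

## Known limitations

The affine-link assumption fails for saturating detectors or nonlinear
amplification not removable by a log transform; no nonlinear
calibration is attempted.  The compartment split uses scalar population
means f_V and f_c — justified when their correlations with cell size
and expression are negligible, as observed in the motivating system —
so per-cell compartment variability is not propagated into the
predicted current distributions.  Stimulated (non-steady-state) cells
violate the equal-currents assumption and are out of scope, as is
estimating ε or f(t) themselves (they cancel, by construction).
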