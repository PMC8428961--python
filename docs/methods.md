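# Methods

This note documents the models and numerical choices behind `eelvkit`: a
toolkit for estimating end-expiratory lung volume (EELV) from a
multiple-breaths nitrogen washin–washout (MBNW) maneuver, quantifying lung
aeration on CT, estimating PEEP-induced alveolar recruitment, and running
the method-comparison statistics used to validate such monitors.

## The MBNW estimator

During mechanical ventilation, stepping the inspired oxygen fraction
(FiO₂) by ~10% and holding it until a new steady state changes the
alveolar nitrogen fraction by ΔFN₂. Nitrogen is neither produced nor
consumed, so the net N₂ volume crossing the airway opening between the two
steady states equals the change in the lung's N₂ store:

    EELV_MBNW = cumulative ΔN₂ volume / ΔFN₂

The pipeline is:

1. **Breath segmentation** (`breaths.segment_breaths`): flow zero-crossings
   with a hysteresis of 2% of the 95th-percentile flow magnitude; candidate
   breaths under `min_vt_ml` (default 10 mL) are discarded.
2. **Volumetric gas exchange** (`breaths.breath_gas_volumes`): trapezoidal
   integration of flow × fraction per species over each breath, with
   FN₂ = 1 − FO₂ − FCO₂ sample by sample; by construction the three
   species volumes sum exactly to the tidal volume.
3. **Phase detection** (`mbnw.detect_phases`): FiO₂ steps are read from
   jumps (> 0.02) in the per-breath mean inspired O₂ fraction. A plateau
   is steady when the rolling mean of end-tidal FN₂ over `k_ss = 5`
   breaths changes by < `ε_ss = 0.001` per breath; the steady-state window
   is the last 5 breaths of the plateau. End-tidal FN₂ is averaged over
   the final quarter of each expiration (the alveolar plateau) rather than
   taken from a single 100 Hz sample — single-sample estimates made the
   steady-state criterion noise-fragile without changing the noise-free
   result.
4. **Estimation** (`mbnw.estimate_eelv`): the baseline net N₂ flux (mean
   over the preceding steady window, ≈ 0 at a true steady state) is
   subtracted breath by breath, and the corrected flux is summed from the
   step change to the end of the following plateau. Summing only to the
   detected steady-state onset would truncate the slow exponential tail —
   up to ~0.4% of ΔFN₂ per the ε_ss criterion — so the sum runs through
   the plateau, where post-onset breaths contribute ≈ 0. ΔFN₂ is the
   difference of the steady-window end-tidal means; ΔFN₂ ≤ `ε_fn2 = 0.02`
   is rejected as degenerate (a 10% FiO₂ step yields ≈ 0.10). Washout
   (FiO₂ up) and washin (back down) are estimated symmetrically and
   averaged; the instrumental dead space — apparatus gas between the
   sensor and the tube tip, which washes in and out along with the lung —
   is subtracted at the end, so the subtraction is exactly linear in the
   configured volume.
5. **Stability**: VO₂ and VCO₂ means are compared between the baseline
   and final steady windows; a relative change above `τ_stab = 10%`
   (configurable; no standard threshold exists) clears the `stable` flag.

The estimate measures the lung volume participating in gas mixing.
Unventilated gas — e.g. overinflated regions at high PEEP — is invisible
to the washout and biases the estimate low by its volume relative to an
anatomical (CT) reference; the simulator reproduces this mechanism
exactly.

## The lung-gas simulator

`simkit.simulate_maneuver` integrates a single perfectly mixed alveolar
compartment breath by breath, with: a plug-flow series dead space
(anatomical + instrumental) that is rebreathed at the start of each
inspiration and expired first at the start of each expiration; per-breath
O₂ removal and CO₂ addition (so the expired tidal volume differs from the
inspired by VCO₂ − VO₂); and an optional unventilated pocket whose gas
never exchanges. Nitrogen conservation holds exactly in the discrete
recursion, which is what makes the simulator an oracle: the net N₂ export
between steady states equals (mixing volume + dead space) × ΔFN₂.

Within a breath only volumetric integrals matter to the estimator, so the
waveform shapes are minimal: constant inspiratory flow for a third of the
cycle, a constant dead-space plug outflow, then an exponentially decaying
alveolar outflow (τ = ⅕ of the phase). Signals are piecewise linear with
zero-flow knots placed exactly on sample points at every phase and
composition boundary, and phase amplitudes are calibrated so trapezoidal
integration of the sampled signal reproduces the model's volumes to
machine precision — otherwise half-sample boundary triangles produce an
FN₂-proportional integration bias that baseline subtraction cannot
remove. Defaults mirror the bench setting the package targets: 100 Hz
sampling, FiO₂ 0.5 → 0.6 → 0.5, VT 180 mL, RR 25/min, airway dead space
30 mL, VO₂ 100 and VCO₂ 85 mL/min. Optional i.i.d. Gaussian noise is
added to flow and gas fractions after synthesis (seeded; fractions are
clipped to the physical simplex).

What the simulator deliberately omits: cardiogenic oscillations, a
sloping alveolar phase III, sensor response times, pressure-dependent
mechanics and multi-compartment ventilation heterogeneity. Passing the
oracle tests therefore demonstrates correctness of the volumetric
accounting, not robustness to every artifact of real signals.

## Quantitative CT

Voxel gas volume follows the linear HU mixture rule (−1000 HU = gas, 0 HU
= water): gas = −HU/1000 × voxel volume on [−1000, 0], zero above 0 HU,
the full voxel below −1000 HU; tissue is the complement. EELV_CT is the
summed voxel gas volume over the lung mask at end-expiration. Aeration
compartments by HU: non-inflated (+100 to −100), poorly inflated (−101 to
−500), normally inflated (−501 to −900), overinflated (−901 to −1000).
HU grids are real-valued, so the integer bin edges are implemented ±0.5
(half-open, upper edge included): every real HU is classified and integer
values land in the printed bins. Masked voxels above +100 HU are counted
as non-inflated tissue rather than dropped, since the mask is taken as
authoritative; reports flag no voxels as unclassified. No segmentation or
inter-scan registration is attempted — HU and mask must share a grid.

CT recruitment between a lower PEEP step *n* and the next:

    Vrec_CT = (Vtis_n − Vtis_n+1) / (1 − Fgas_n) × Fgas_n

with Vtis the non-aerated-compartment tissue volume and Fgas the gas
fraction of the aerated region, both at end-expiration. Positive values
mean recruitment with increasing PEEP.

`simkit.generate_phantom` builds HU grids from homogeneous regions of
configured HU and volume (realized as whole-voxel slabs, so volumes match
up to voxel discretization); its truth report is computed by the same
voxel formulas, making the CT module's oracle exact by construction.

## Recruitment from EELV

    Vrec = ΔEELV − C_stat(lower PEEP) × ΔPEEP,  C_stat = VT / (Pplat − PEEP_tot)

Total PEEP (including intrinsic PEEP) is preferred over set PEEP when
available, and the output records which was used. Because compliance is
anchored at the lower PEEP step, the estimator is not antisymmetric under
step reversal; this is a property of the method, not a bug. The linearity
of compliance over the PEEP change is an assumption the data cannot
verify.

## Method-comparison statistics

- **Repeatability**: per duplicate pair, CV = (|x₁−x₂|/√2) / mean;
  precision = 2 × CV; least significant change LSC = CV × 1.96 × √2
  (so LSC/precision ≈ 1.386 identically). Medians over pairs are reported
  with BCa bootstrap 95% CIs (10,000 resamples by default, pairs
  resampled, via `scipy.stats.bootstrap`).
- **Agreement**: bias = test − reference is regressed on the reference by
  OLS, giving the conversion equation test = (1 + β) × ref + α. The
  original validation used posterior medians of an MCMC chain for the
  non-constant-bias model; this package uses a frequentist equivalent —
  OLS with a subject-clustered bootstrap for parameter uncertainty — and
  makes no claim of numerical equality with the MCMC, validating instead
  by parameter recovery on synthetic data. The 95% prediction interval of
  the bias is the 2.5–97.5 percentile half-width of bootstrap draws
  α* + β*·ref̄ + ε*, ε* ~ N(0, σ*) with σ* the resample's residual SD,
  reported at the mean reference (a ref-dependent band is also emitted).
  With a single subject the bootstrap falls back to i.i.d. rows with a
  warning. Percentage error = 2 × SD(bias) / mean(reference).
- **Trending**: within-subject deltas between consecutive conditions.
  Four-quadrant concordance is the percentage of delta pairs with equal
  signs (no exclusion zone by default; an optional one drops pairs whose
  changes are both inside it), with a Wilson score 95% CI
  (`statsmodels`). Polar statistics: each pair maps to
  θ = atan2(Δtest, Δref) − 45°, wrapped to (−180°, 180°], after
  reflecting joint-decrease pairs through the origin so a concordant
  decrease also scores 0°; angular bias is the mean θ and the radial
  limits of agreement are 1.96 × SD(θ) (a percentile variant is
  available). Angles are in degrees, counterclockwise positive, identity
  axis at 0°.

## Synthetic paired series

`simkit.generate_paired_series` emulates the validation tables: reference
values uniform over a configured span, test = slope × ref + intercept +
Gaussian noise, dealt round-robin to subjects with a per-subject condition
order. Defaults match the validation scale this package targets: 7
subjects, 32 observations, references 254–1200 mL, slope 0.92, intercept
36 mL, residual SD 40 mL (≈ a ±86 mL 95% prediction interval / 1.96).
The recruited-volume comparison uses 20 observations over −100 to 300 mL
with slope 1.43 and residual SD 75 mL (≈ ±147 mL / 1.96). These series
have i.i.d. noise and no true between-subject random effects; recovery
tests therefore validate the fitting machinery, not robustness to real
clustered heteroscedastic data. At this scale the sampling SE of the
recovered intercept (~20 mL) and of the recruitment slope (~0.15) is of
the same order as the recovery tolerances, so single-seed recoveries
scatter accordingly; the 50-seed mean-slope check verifies unbiasedness.

## Numerical conventions and degenerate inputs

- Gas composition is handled as dry fractions; partial-pressure inputs are
  converted as F = P/Pb (default 760 mmHg), without water-vapor or
  BTPS/STPD correction — the simplest self-consistent convention, applied
  uniformly to simulation and estimation.
- Flow is positive during inspiration; CSV readers never flip signs.
- All stochastic routines take explicit seeds; identical seeds give
  bit-identical outputs.
- Degenerate inputs raise typed errors rather than returning NaN: constant
  FiO₂ or short/unsteady plateaus (maneuver-incomplete), ΔFN₂ below ε_fn2
  (degenerate maneuver), non-positive EELV after dead-space subtraction
  (estimation-failed, with diagnostics), empty CT masks, Pplat ≤ PEEP,
  constant-reference agreement fits, zero-length trend deltas.

## Problem sizes

Test and validation runs use maneuvers of 60 s baseline plus two holds of
120 s–or–12 washout time constants (whichever is longer) at 100 Hz, EELVs
of 250–1200 mL, phantoms of ≤ 72,000 voxels, and bootstrap sizes of
2,000–10,000; these sizes keep the full suite fast while leaving the
slowest oracle cases (EELV 1200 mL) within their tolerances.

## Known limitations

- Single-compartment ventilation: no distribution of time constants, so
  the simulator cannot probe slow-compartment underestimation seen in
  heterogeneous disease.
- The Bland–Altman prediction interval is a bootstrap approximation, not
  the MethComp MCMC posterior; equality with published interval widths is
  not claimed.
- The CT module trusts the provided mask; pleural effusion or hilar
  structures inside the mask are counted as non-inflated tissue.
- Recruitment estimates inherit compliance-linearity and multi-device
  error assumptions discussed above.
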