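# Methods

## Conventions

All concentrations are µM; totals for a self-associating species are
**monomer equivalents**, `T = [M] + 2[D]`. The homodimer dissociation
constant is `K_D = [M]²/[D]` (units of concentration). This is the only
convention under which the closed forms below hold as written; unit
conversion belongs at the I/O boundary, not inside the API.

## Monomer–dimer mass action

Free monomer at total `T` solves `m + 2m²/K_D = T`, giving

    m = (−K_D + √(K_D² + 8·K_D·T)) / 4 .

The package evaluates the algebraically identical, cancellation-free form
`m = 2T / (1 + √(1 + 8T/K_D))`, which keeps full precision when
`K_D ≫ T` and makes the landmark identities exact in floating point:
`f_dimer(T=K_D) = 1/2` and `f_bound(T=K_D) = 1/3`. An independent
bisection on the mass balance (`oracle_mass_balance`) is kept in the public
API as a cross-check; the two agree to better than 1e-8 relative over
`T ∈ [1e−3, 1e4] × K_D ∈ [1e−2, 1e3]` µM, and all returned states satisfy
conservation and the mass-action law to 1e-9 relative.

## SEC of a fast-exchange homodimer

Assumptions: monomer↔dimer exchange is much faster than the run, so a
single population-averaged peak is observed; elution *velocity* at constant
flow rate is proportional to 1/V; diffusion, dispersion and on-column
dilution are ignored, so the loaded concentration stands in for the
equilibrium total. The last simplification biases the estimate (the plug
dilutes as it migrates), which is one reason a SEC-derived K_D should be
read as a range; the estimator exposes this through the calibration
sensitivity (shifting `v_dimer`/`v_monomer` moves `kd_hat` monotonically).

Pipeline: peak volume = global maximum of the (optionally smoothed) trace;
smoothing is a centred moving average, default window 5 points — enough to
de-noise without moving a unimodal maximum; ties break to the smallest
volume, and a maximum on a trace boundary raises a truncated-peak warning.
Observed volumes invert through the linear velocity-mixing rule to dimer
fractions; volumes outside `[v_dimer, v_monomer]` by up to 2% of the
interval width are clamped (measurement noise), further out is treated as
mis-calibration and rejected. The K_D is then fit by 1-D least squares **on
the fraction scale** (the observable the mixing rule actually delivers),
over `log10 K_D ∈ [−4, 5]`, initialised at the load whose observed
fraction is nearest 1/2. Designs with fewer than 3 runs, under 4-fold
concentration span, or with all fractions below 0.05 / above 0.95 (no
transition sampled) are rejected as unidentifiable.

## Steady-state SPR

Two isotherms, both fit by nonlinear least squares on the response scale
(unweighted absolute RU, matching common instrument-software practice):

* `langmuir_1to1`: `R = Rmax·C/(K_D + C)`;
* `selfdimer_corrected`: `R = Rmax·m/(K_D + m)` with `m = free monomer` —
  analyte sequestered in solution homodimers does not bind the surface.
  This assumes a single K_D governs both the solution homodimer and the
  surface interaction (the surface ligand is the same monomer, sparsely
  immobilised); a two-constant variant would be a straightforward
  extension but is not built.

Optimisation is over `(log10 K_D, Rmax)` with bounds
`K_D ∈ [1e−4, 1e5] µM`, `Rmax ∈ (0, 10 × max response]`; initial guesses
are the concentration nearest half-maximal response and 1.1 × max
response. Weak binders whose unconstrained K_D estimate exceeds three
times the top analyte concentration are rejected with advice to constrain
Rmax; the constrained path fixes Rmax to an independently determined value
(e.g. the wild-type fit on the same channel) and optimises K_D alone.

Fitting the plain Langmuir model to data from a self-dimerizing analyte
(`apparent_kd_naive`) always inflates the apparent K_D, because the
corrected occupancy is pointwise below the Langmuir curve at equal K_D —
the quantitative analogue of the discrepancy between high-density surfaces
of a dimerizing ligand and surfaces of a non-dimerizing partner.

## Confidence intervals

Both estimators report a **seeded residual bootstrap** interval,
studentized on the log10 K_D scale: fitted residuals are inflated by
√(n/(n−p)) to undo the shrinkage from estimating p parameters, each
replicate is refit and reduced to the pivot
`|log10 kd* − log10 kd| / se*` (linearized standard error from the
replicate's own Jacobian), and the interval is the point fit's standard
error scaled by the `ci_level` quantile of the pivots. At the 6–8 points a
titration or dilution series affords, plain percentile intervals are
noticeably anticonservative (~82% observed coverage at nominal 95% in our
calibration runs); the symmetric studentized interval restores ≥90%
observed coverage under the generators' default noise. Default 1000
replicates; `n_boot=0` disables the interval.

## Homo/hetero competition

For totals `R_tot` (monomer equivalents) and `P_tot` with constants
`K_homo`, `K_het`, the free-partner variable is eliminated analytically and
the receptor conservation residual

    g(r) = r + 2r²/K_homo + r·P_tot/(K_het + r) − R_tot

is strictly increasing in the free receptor `r` with `g(0) < 0 ≤ g(R_tot)`,
so bisection on `[0, R_tot]` is globally convergent; it runs to a residual
tolerance of 1e−12 × max(1, R_tot, P_tot) (bounded at 200 iterations,
raising a numerical error carrying the residual if exceeded). Limits:
`P_tot = 0` reduces exactly to plain self-association; `K_het → 0` with
excess partner drives all receptor into heterocomplex.

## Mutational energetics

`fold = K_D,mut/K_D,wt`; `ΔΔG = R·T·ln(fold)` with
`R = 1.9872e−3 kcal·mol⁻¹·K⁻¹` and `T = 298.15 K` by default — the
measurement temperature is configurable, and only ΔΔG (not the fold or the
K_D fits) depends on it. Positive ΔΔG = destabilizing; the transform is
antisymmetric and additive along mutation paths, so fold and ΔΔG rank a
panel identically. Censored affinities (no saturation at the top
concentration) propagate as flagged lower bounds, never point estimates.

## Synthetic data

The generators emulate the study designs, not any measured run:

* SEC: six two-fold dilutions, 3.125–100 µM, on a calibration of
  `v_dimer = 11.0`, `v_monomer = 13.2` mL (24 mL column) — chosen so
  `f = 0.5` maps to exactly 12.0 mL. Each run is a Gaussian absorbance
  peak (σ = 0.25 mL, height ∝ load, 0.01 mL grid) centred at the
  model-predicted volume plus additive baseline noise (default 1% of peak
  height). Peak-position jitter therefore arises through the trace and its
  detection, never by perturbing volumes directly.
* SPR: eight three-fold dilutions geometrically centred on the true K_D
  (≈3.3 decades), Rmax = 100 RU (low-density surfaces), multiplicative
  Gaussian noise at 2% CV plus a 0.5 RU additive floor. Mutant panels share
  Rmax across constructs and cap the top concentration at 100 µM, which
  leaves a 700-fold-weakened mutant far from saturation — the regime where
  the Rmax-constrained protocol is required.

All draws come from `numpy.random.default_rng(seed)`; a fixed
`ScenarioSpec` reproduces its dataset byte-for-byte. What passing tests
show: the estimators recover their generating parameters under the assumed
noise (Gaussian, independent, correctly specified mean model) at these
designs. What they do not show: robustness to drifting baselines,
mass-transport limitation, non-specific binding, column dispersion or
concentration errors — none of which the generators emulate.

## Problem sizes

The test suite and the acceptance script run single titrations (8 points),
single SEC series (6 runs), 100–200-replicate Monte Carlo loops for
variance and coverage properties, and 199–1000 bootstrap replicates per
interval; these sizes make every property check reproducible in a couple of
minutes on one core while leaving the Monte Carlo error on coverage
estimates (~±2%) well inside the asserted margins.

## Known limitations

* No kinetics: only equilibrium/steady-state quantities are modelled.
* No oligomers beyond the dimer, and no avidity of dimeric analytes
  binding two surface sites.
* The SEC model's no-dilution assumption biases K_D; the package reports
  the sensitivity direction but does not correct it.
* The self-dimer-corrected SPR isotherm uses one K_D for solution and
  surface binding (see above).
* Chip-surface *cis* dimer occupancy of the immobilised ligand is not
  modelled; the naive-fit inflation quantifies its direction only.
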