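# Methods

This note records the scientific and numerical choices behind `dpkit`:
what each stage computes, the assumptions it makes, and what the tests
do and do not demonstrate.

## Materials and effective atomic number

Two material sets are embedded (`src/dpkit/data/materials.csv`): 23
training materials from a Schneider-style stoichiometric CT calibration
(labelled by Hounsfield-unit bin, densities 0.028–1.934 g/cm³) and 4
ICRP reference tissues for testing (air, lung, soft tissue, cortical
bone).  Compositions are weight fractions over a fixed 12-element set
{H, C, N, O, Na, Mg, P, S, Cl, Ar, K, Ca}; blank table cells are zero,
and rounded rows are accepted when fractions sum to within [0.98, 1.02].
Materials containing other elements are rejected — the chain's feature
vector has one slot per supported element, so this is a hard interface
limit, not merely a data gap.

Effective atomic number and weight use electron-fraction weighting
(Tabata's compound rule):

    Z_eff = Σ w_i (Z_i/A_i) Z_i / Σ w_i (Z_i/A_i),
    A_eff = Z_eff / Σ w_i (Z_i/A_i).

Other compound rules exist (photon-interaction-weighted Z_eff powers,
for instance); the electron-fraction rule is the natural one for
charged-particle ranges and is the documented assumption here.

## CSDA ranges

Ranges are evaluated with the Tabata–Ito–Okabe analytic functional form

    r0(τ) = a1 [ ln(1 + a2 τ)/a2 − a3 τ/(1 + a4 τ^a5) ],  τ = T/m_e c²,

with a1..a5 simple functions of (Z_eff, A_eff).  The original
coefficients target the *extrapolated* range; the set shipped here was
refit on the CSDA scale: reference ranges were computed offline by
integrating the Berger–Seltzer collision stopping power (Bragg-rule
mean excitation energies, generic Sternheimer density-effect
parameterization, rule-of-thumb radiative term S_rad ≈ S_col·T·Z/800)
for the 27 embedded materials plus water over 10–3000 keV, and the ten
b-coefficients were least-squares fitted in log space (median residual
0.3 %, maximum 2.7 %).  For liquid water the fitted formula agrees with
the NIST ESTAR CSDA tabulation within 1.8 % over 10 keV–3 MeV, which
the test suite checks at the 2 % level.  Users who need a specific
published tabulation can pass a two-column `(energy_keV, range_g_cm2)`
CSV as an override; it is interpolated log-log and used everywhere the
analytic fit would be.

## The shell-scoring emulator

Training kernels come from a *parametric emulator* of a shell-scoring
transport run: a monoenergetic point source at the centre of a
homogeneous sphere, energy deposition scored on 60 shells of thickness
R_CSDA/40 out to 1.5·R_CSDA (beyond which real shell tallies become
statistically unusable, so the scoring stops there).  The noiseless
family is

    g(x) = x^a exp(−b x^c), c = 2.2,
    a = clip(0.6 + 0.25 ln(E/100 keV), 0.2, 1.8),
    m = clip(0.35 + 0.05 ln(E/100 keV) + 0.01 (Z_eff − 7), 0.2, 0.7),
    b = a/(c m^c)   (mode of g at x = m),

normalized so the 60-shell deposited-fraction sum equals the absorbed
fraction η = 1 − Y with the radiative-loss proxy
Y = 6·10⁻⁴ Z_eff T_MeV / (1 + 6·10⁻⁴ Z_eff T_MeV).  Per-shell
multiplicative Gaussian noise has relative sigma
0.01·√(f_peak/max(f_i, 10⁻⁴))·√(10⁷/n_primaries) — about 1 % at the
peak shell for 10⁷ primaries, growing toward the tail, which is the
error structure shell tallies actually exhibit.  Draws are clipped at
zero and (in the rare event the noisy sum exceeds unity) renormalized
just below 1 so energy conservation is strict.

What the emulator does and does not emulate: it reproduces the
*qualitative* structure the regression problem needs — a single
interior peak moving outward with energy, smooth dependence on energy
and effective Z, an energy-balance deficit from radiative losses, and
calibrated counting noise.  It does not contain transport physics: no
δ-ray escape, no backscatter structure, no material shell effects.
Passing tests therefore demonstrate that the *pipeline* (features →
chain → beta synthesis → VDK → dose) is correct and self-consistent,
not that its absolute kernels match nature; for that, real Monte Carlo
kernels are imported through the interchange CSV
(`material_label,energy_keV,shell_index,x_mid,F`) and flow through the
identical code path.

## Regressor chains

The 13 features are, in fixed order: E₀ [keV], R_CSDA [g/cm²],
ρ [g/cm³], and the weight fractions of H, C, Na, Mg, P, S, Cl, Ar, K,
Ca.  Nitrogen and oxygen are deliberately absent from the feature list
(their fractions are nearly determined by the remaining ones through
the unit-sum constraint); an issue worth knowing about when adding
materials.  The 60 targets are the shell values F₁..F₆₀.

Link *i* of the chain is a linear model on the features plus targets
1..i−1.  Training uses *observed* previous targets; prediction cascades
each link's output into the next — the canonical chaining algorithm.
Feeding predictions during training instead would compound early-link
errors into every later fit.  Negative cascade outputs are clipped to
zero only when kernels are constructed, not inside the cascade, so the
linear algebra stays exact.

Base objectives (intercept never penalized):

* ridge: ‖Xw − y‖² + α‖w‖², solved in closed form (normal equations;
  minimum-norm least squares when α = 0, which tolerates the exactly
  collinear designs chained targets can create);
* lasso / elastic net: (1/2n)‖Xw − y‖² + γα‖w‖₁ + α(1−γ)/2·‖w‖₂²
  (γ = 1 for lasso), solved by cyclic coordinate descent on the
  covariance form with zero start, fixed cyclic order, active-set
  sweeps between full sweeps, and convergence when the largest
  coefficient update falls below 10⁻⁶ (cap 10⁴ sweeps).  The quadratic
  term's 1/(2n) normalization is used for both so that elastic net with
  γ = 1 *is* the lasso; ridge keeps the unnormalized form, and the
  mapping between conventions is exercised against scikit-learn in the
  tests.  The inner loop is JIT-compiled with numba when available.

Standardization: the chain z-scores its full augmented design (features
and targets-used-as-features) with training-set statistics; targets are
left unscaled.  Penalized objectives are scale-sensitive, and the
augmented columns span two orders of magnitude.

Hyperparameters: no principled values exist a priori, so they are
grid-searched — α ∈ {10⁻⁴…10¹} (6-point log grid), γ ∈ {0.25, 0.5,
0.75} for elastic net — by pooled RMSE of cascaded predictions on a
seeded 20 % validation split, then refit on the full training table.

Metrics: pooled R² (1 − SS_res/SS_tot over all rows and targets against
the pooled mean), pooled RMSE, and MAPE in percent over nonzero truths;
per-target breakdowns accompany every report because pooled numbers
hide tail-shell behaviour.

## Beta-emitter kernels

Spectra are resampled with an interpolating cubic spline to 1000
equally spaced energies from 10 keV to E_max, negative spline values
clipped, intensities renormalized to unit sum (so E_eff = Σ I_j E_j is
independent of the raw tabulation units).  The radionuclide kernel on
120 shells of r_N/100 is

    F_β(x) = r_N Σ_j I_j E_j F_j(x·r_N/r_0j) / r_0j / E_eff,

with each monoenergetic kernel evaluated by linear interpolation on its
own 60-point grid and zero beyond 1.5 (linear interpolation cannot
overshoot a non-negative kernel; higher-order schemes can).  For a
single line this degenerates to the monoenergetic kernel re-gridded;
for any spectrum the kernel integral equals Σ I_j E_j η_j / E_eff,
which the tests verify against direct summation.

Three fictitious test nuclides ship with allowed-shape spectra
N(E) ∝ √(E² + 2E·m_e c²)(Q − E)² at Q = 500/800/2280 keV — synthetic
stand-ins so the package is testable without licensed decay-data files;
real ICRP-107-style data enters as `energy_keV,intensity` CSV.

X90 rescaling (for cross-study comparison) finds the radius containing
90 % of the kernel's own absorbed energy by linear interpolation of the
cumulative curve, divides abscissae by it and multiplies F by it, so
the integral is preserved exactly and the operation is idempotent.

## Voxel dose kernel and dose maps

The VDK is built by Monte Carlo volume integration: for each of the
23³ voxels (1 mm³ default), source points uniform in the central voxel
and target points uniform in the target voxel are paired,
Φ_β(r) = F_β(r/r_N)/(4πρr²r_N) averaged over pairs, and dose per decay
taken as E_eff·Φ̄ (1 keV = 1.602176634·10⁻¹⁶ J).  Pairs closer than
0.1 µm are redrawn (bounded retries, then clamped) because the 1/r²
point kernel is integrable but individual samples are not bounded; for
the same reason voxels adjacent to the source voxel have heavy-tailed
estimators, and the √n error-scaling test pools only non-adjacent
voxels.  All sampling is deterministic given the seed.

Activity maps follow the count-proportional rescaling
A_voxel = A_liver·C_voxel/C_liver (counts outside the normalization
mask are zeroed by default — the administered activity is assumed to
stay in the organ — with a flag to keep them), cumulated activity is
Ã = 1.443·T½·A (permanent trapping, no biological clearance), and dose
is the FFT linear convolution of Ã with the VDK, cropped to the input
grid, tiny negative FFT round-off clipped to zero.  Spacing mismatches
between map and kernel are an error, never silently resampled.  The
convolution assumes one spatially invariant kernel (a single reference
material); per-voxel-material kernels would not be a convolution, and
an activity-partitioning multi-material mode is deliberately left out
of scope.

## Gamma index

γ(r_R) is the minimum over evaluated voxels within a search sphere of
3·δr of √(Δr²/δr² + ΔD²/δD²), with δr = 3 mm, δD = 3 % of the
*reference maximum* by default (global normalization — the common
clinical convention for 3 %/3 mm reporting; a local mode is available
and is strictly harder to pass).  The search is over discrete voxel
centres, sorted by distance with early termination; no sub-voxel
interpolation, which makes the result slightly conservative.  Pass rate
counts reference voxels above a configurable dose threshold (default:
all voxels with dose > 0), with γ = 1 counting as a pass.  γ is
asymmetric in (reference, evaluated) by construction; both directions
are computable and no symmetry is asserted.

## Reproducibility

Every stochastic stage takes an explicit seed; dataset rows, study
replicates and CLI stages derive substreams from one master seed via
`numpy.random.SeedSequence` spawning in documented order, so a master
seed reproduces every artifact bit-identically.  CLI runs write a JSON
manifest of command, parameters and seed.

## Problem sizes

The generalization study (also run by `scripts/acceptance.py`) uses the
study conditions throughout: 23 training materials × 30 log-spaced
energies (690 rows), 10⁷ emulated primaries per kernel, the full tuning
grid, 4 testing materials at the same energies, five replicates.  Test
fixtures elsewhere use a 12-energy grid and 10³–10⁴ VDK pair samples,
sizes at which every asserted tolerance has comfortable statistical
margin.

## Known limitations

* Emulator kernels are synthetic (above); published-kernel MAPE
  benchmarks are only meaningful with imported MC kernels and digitized
  reference data, both user-supplied.
* The range fit was calibrated for Z_eff ≈ 6.4–13.7 (tissue-like
  media); metals and implants are outside both the fit and the fixed
  element set.
* Auger/conversion electrons and photons are not modelled, so
  short-range dose near the source is underestimated for nuclides with
  significant discrete-electron emission.
* The gamma search radius (3·δr) bounds γ from above for badly
  disagreeing voxels; pass rates are unaffected.
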