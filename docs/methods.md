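# Methods

## Exchange model

An N-state network (N ≤ 4 here: F, I1, I2, U) is specified by ordered
state labels, strictly positive equilibrium populations summing to 1,
and a set of exchanging pairs each carrying the total exchange rate
k_ex,JK = k_JK + k_KJ.  Microscopic rates are always derived from the
populations via detailed balance, k_JK = k_ex·p_K/(p_J + p_K); they are
never independent fit parameters.  This guarantees that the first-order
rate matrix K (convention dp/dt = K·p, off-diagonal K[i,j] = k_{j→i},
columns summing to zero) has the population vector as its stationary
state, and that thermodynamic cycles such as F–I1–I2 are automatically
consistent (the product of microscopic rates around the cycle is
direction-independent).  Temperatures are stored in Kelvin; Celsius
inputs are converted by adding 273.15.

The four-state topology is fixed a priori: F exchanges with I1 and I2,
I1 with I2, and only I1 with U.  No direct F–U or I2–U exchange exists,
so the rate matrix has exactly eight nonzero off-diagonal entries.
Model selection beyond comparing fitted two-/three-/four-state levels by
reduced chi-square and AIC is out of scope.

## Bloch–McConnell propagation

For one spin and one RF offset the magnetization of all N states evolves
under the augmented (3N+1)-dimensional matrix: per state a Bloch block
with transverse relaxation −R2, longitudinal relaxation −R1, RF nutation
coupling z↔y at ±2π·B1 (RF phase fixed along x; any fixed phase gives
the same M_z), and x–y precession at the state's rotating-frame offset
2π(ϖ_i,Hz − offset); exchange couples like components of different
states with the microscopic rate matrix; the final unit-augmentation
column carries R1_i·p_i·m_eq return-to-equilibrium terms and the
augmented row is zero.

The scale m_eq is the thermal z-magnetization in units of the prepared
initial magnetization.  The bare evolution matrix defaults to m_eq = 1,
under which thermal equilibrium is exactly stationary without RF.
Profile simulation uses m_eq = 0: the saturation period starts from
polarization transferred from ¹H, which dwarfs the ¹⁵N/¹³C thermal
value, so relaxation during T_EX decays toward ≈ 0 — the standard
convention in CEST fitting, and the one that reproduces the
exp(−R1·T_EX) off-resonance baseline of measured profiles.  Because the
m_eq = 0 system is linear and homogeneous, the normalization
I/I0 = M_z,F(T_EX)/p_F is independent of the overall polarization scale.

Profiles are computed for all offsets at once: the stack of evolution
matrices is eigendecomposed in batch and exp(A·T_EX)·v evaluated
through the eigenbasis, falling back to scipy's `expm` for any offset
whose eigenvector matrix is ill-conditioned (condition number > 1e10).
The batched path agrees with `expm` to ~1e-12 and with adaptive ODE
integration to better than 1e-8.

Optional B1 inhomogeneity averages the profile over 11 B1 values
spanning ±2 standard deviations with Gaussian weights; it is off by
default so that fits are strictly reproducible.

Detection convention: the observed intensity is M_z of the major (first)
state only, normalized by its T_EX = 0 value; minor-state peaks are not
observable in the spectra the profiles come from.  Scalar-coupling
multiplet structure, DANTE-type variants and NOE transfer are out of
scope; ¹³C multiplet broadening would enter only as a larger effective
R2.

## Global fitting

Kinetic parameters (k_ex values and minor populations) are global across
all spins and B1 fields of one condition; each spin carries signed shift
differences Δϖ (minor minus major, ppm; default bounds ±15 ppm for
¹⁵N/¹³C and ±3 ppm for ¹H), its major-state shift, and R1/R2.  R1 is
shared across states of a spin and minor-state R2 is tied to R2 of the
major state by default — the common practice when the data do not
constrain per-state relaxation.  Minor populations are bounded in
(0, 0.5), rates in (0, 5·10⁴ s⁻¹).

The optimizer is scipy's bounded trust-region reflective least squares
with function/parameter tolerances of 1e-10 and at most 500 iterations
per start.  A block-sparsity mask (per-spin parameters touch only that
spin's residual block) lets the finite-difference Jacobian be evaluated
in ~11 perturbed calls instead of one per free parameter, which
dominates the runtime for many-spin fits.  Multi-start: by default 5
seeded restarts perturb the starting point by ±20% (log-kept within
bounds) to guard against local minima in four-state fits; restarts stop
early once a fit reaches essentially zero cost (noiseless data).
Identical inputs, seed and options give identical results.

Quality is reported as chi2_red = Σ[(obs − sim)/σ]²/(N_pts − N_free);
profiles without error columns get unit weights.  Model comparison uses
AIC = chi2 + 2·N_free on fits of identical data.  Uncertainties come
either from the chi2_red-scaled inverse of JᵀJ (covariance) or from a
seeded parametric bootstrap (noise redrawn from the per-point errors
around the best-fit simulation, refit, SD over replicates).  On
well-conditioned synthetic data the two agree within a factor of ~2.

Degenerate null case: data without minor-state dips constrain only the
product kex·p (and are equally explained by Δϖ → 0), so a two-state fit
of exchange-free data collapses along one of those directions rather
than uniquely driving p to its floor; the tests assert the collapse of
the exchange effect, not of one specific parameter.

## Shift-perturbation statistics

Per residue, Δϖ_RMS = sqrt((1/N)·Σ_i (Δϖ_i/ϖ_std,i)²) over the nuclei
for which both a fitted Δϖ and a normalizer ϖ_std are available
(N varies by residue); glycine contributes its two ¹Hα values as two
terms.  Residues with Δϖ_RMS above a threshold (default 0.5) are
classified as structurally perturbed in the minor state.  The shipped
ϖ_std defaults are synthetic round-number stand-ins for the spread of
reported protein shifts per nucleus type; they are configuration, and
all quantitative tests pass explicit tables so the defaults never
silently affect a result.  Shift-set agreement is the RMS of pairwise
differences over shared (residue, nucleus) records, optionally filtered
by nucleus and with residues excluded (e.g. positions adjacent to a
mutation).  Minor-state peak lists are reconstructed as
major + Δϖ per nucleus.

## Thermodynamics and m-values

ΔG_FK = −RT·ln(p_K/p_F) (R = 8.314 J mol⁻¹ K⁻¹, reported in kJ/mol);
for the transition state between K and L,
ΔG_F-TSKL = −RT·ln(p_K/p_F) − RT·ln(k_KL/C) with the arbitrary
prefactor C = 10⁷ s⁻¹.  Detailed balance makes the TS free energy
independent of the side it is computed from, and changing C shifts all
TS free energies by one constant, leaving every m-value untouched; both
identities are asserted in the tests.  m_J = −slope of ΔG_FJ versus
[urea], by weighted least squares (weights 1/SE² when per-point SEs are
supplied, otherwise ordinary least squares).  ΔG standard errors, when
wanted, are propagated first-order from parameter SEs with a
finite-difference delta method (`thermo.delta_method_se`); parameter
covariances are neglected.  Mixing temperatures within one m-value fit
is an error; m_F ≡ 0 by construction since F is the reference.

## Synthetic scenarios

The generator's defaults are the study conditions the fits are validated
against:

* **A** — four-state network at 10 °C: kex,FI1 = 784, kex,FI2 = 406,
  kex,I1I2 = 1600, kex,I1U = 11000 s⁻¹; p_I1 = 0.27%, p_I2 = 0.83%,
  p_U = 0.16%; amide ¹⁵N profiles at B1 = 26, 52.1, 104.1, 208.3 Hz,
  T_EX = 0.4 s, 700 MHz.
* **B** — two-state F ⇌ I2 at 20 °C (20% glucose stabilizes F and I2 and
  depletes I1/U): kex,FI2 = 587 s⁻¹, p_I2 = 2.1%; B1 = 26.4, 52.9 Hz.
* **C** — two-state slow exchange for the proline-destabilized mutant in
  30% glucose at 20 °C: kex,FI2 = 41.4 s⁻¹, p_I2 = 27.2%.  The B1
  fields are not recorded for this condition; 12.5 and 25 Hz were chosen
  as appropriate for kex ≈ 40 s⁻¹ and fixed.
* **D** — urea titration at 2.5 °C on the grid 0–1 M in 0.2 M steps.
  Free energies of every state and transition state are constructed to
  be exactly linear in urea with slopes −m: m_U = 6.6, m_I1 = 2.8,
  m_I2 = −0.1, m_TSUI1 = 4.0, m_TSI1F = 2.1, m_TSI2F = 0.3 kJ mol⁻¹ M⁻¹
  (m_TSI1I2 has no reference value; 1.0 is a documented placeholder).
  The 0 M anchor reuses the Scenario A populations and rates at 2.5 °C;
  anchors shift every ΔG series by a constant and cannot affect a slope,
  which the round trip through the thermodynamic layer confirms exactly.

Spin sets are seeded and deterministic.  The first three spins are
hand-placed reporters: two with large (≥ 2 ppm), distinct ¹⁵N shift
differences to I2 and U so all minor dips are identifiable, and one
whose I1 and U differences nearly coincide, emulating the broad merged
dip produced by rapid I1 ⇌ U exchange.  Remaining spins draw Δϖ
uniformly from ±6 ppm (¹⁵N).  Defaults R1 = 2.0 s⁻¹ and R2 = 20 s⁻¹
stand in for unavailable per-residue values and are recorded in the
ground-truth sidecar so recovery tests fix or fit them knowingly.
Offset grids are 61 points over ±14 ppm (¹⁵N; ±12 ppm ¹³C, ±4 ppm ¹H)
— wide enough to cover the largest shift difference in Scenario A.
Gaussian intensity noise of a chosen SD (fraction of I0) is added
independently per point with a seeded generator.

What the generator does not emulate: spectrometer drift and phase
errors, B0 inhomogeneity, scalar-coupling multiplets, cross-relaxation,
baseline distortions, and realistic per-residue relaxation diversity.
Passing recovery tests therefore demonstrate the correctness and
identifiability of the fitting machinery under the model's own
assumptions, not robustness to every artifact of measured spectra.

## Problem sizes and numerical choices

Recovery tests use 10 spins (Scenario A/B/C) at the full offset grids;
the noisy-replicate calibration (20 replicates at 1% noise) runs at 5
spins to keep 20 four-state fits tractable.  At this reduced data size
the weakly populated I1 branch is determined far less precisely than by
a full ~60-residue dataset: the chi-square calibration is unaffected,
but the sampling distribution of kex,FI1 is broad and right-skewed, and
its replicate median can fall outside the uncertainty band a full-size
dataset supports.  The replicate tests report this behavior as measured
rather than hiding it behind a looser band.  Matrix exponentials use the batched eigendecomposition
described above; ties in dip-position checks are resolved to one grid
step.  Two-point m-value series produce exact lines with zero reported
slope SE (the regression is saturated).  Degenerate inputs (empty offset
lists, nonpositive populations or rates, mixed temperatures, unknown
nuclei or states) raise validation errors before any computation.

## Known limitations

Only the fixed F/I1/I2/U topology family is supported (≤ 4 states); no
Eyring/temperature-dependent kinetics; no Bayesian posterior sampling;
no joint fitting across conditions (each temperature or urea point is
fitted independently); no vendor raw-data readers.  The covariance and
bootstrap uncertainties assume a correctly specified noise model, and
the delta-method SE propagation neglects parameter covariances.
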