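# Methods

This note documents the models behind each stage of the pipeline, the
parameters that matter, the numerical choices, and what the synthetic
presets do and do not emulate.

## Units and constants

Energies are kcal/mol, collective-variable (CV) distances are
dimensionless "u", time is ps. kB = 0.0019872 kcal/mol/K; the default
simulation temperature is 300 K (RT = 0.5962 kcal/mol) and H/D-exchange
analyses use 298 K (RT = 0.5922 kcal/mol), a typical exchange condition.
The effective Langevin mass is 1 kcal/mol·ps²/u², which makes velocities
come out in u/ps with no conversion factors. The Eyring prefactor kT/h
uses SI constants (6.25×10¹² s⁻¹ at 300 K); 1 M standard-state volume
V₀ = 1660 Å³.

## Toy landscapes

A `ToyLandscape` is a sum of Gaussian wells/barriers plus an optional
harmonic term, with harmonic confining walls (k = 20 kcal/mol/u²) outside
the stated domain. `make_landscape` calibrates the Gaussian centres and
heights by a Newton solve of the 2n conditions {U(sᵢ) = Fᵢ, U′(sᵢ) = 0}
so every declared minimum/saddle is a true stationary point at the
requested position and free energy (residuals < 10⁻⁷; a solve whose
centres drift more than one width from their features is rejected as
ill-posed — in practice this means the baseline must sit clearly below
the saddles so the barrier Gaussians have gradient authority).

The binding preset places bound poses A (s = 3, F = 0) and B (s = 6,
F = 0.3), the main barrier TS1 at s = 12, the external pose C at s = 15.5
(F = +4.0), a smaller exit saddle TS2 at s = 19 and an unbound plateau at
the baseline free energy for s > 22. The default main barrier is
7 kcal/mol so that brute-force rate oracles finish in minutes; a
`full_scale=True` flag selects the 16.5 kcal/mol barrier with the
plateau 14 kcal/mol above the bound minimum for analytic (not
brute-force) work. Well widths are iteratively rescaled so all minima
share the A-well curvature; with equal curvatures the basin free-energy
differences equal the minimum offsets up to small anharmonic
corrections (the double-well preset's quadrature ΔG is 0.94 for a
nominal 1.0). The optional second axis `q_flip` is a quartic double well
(conformational "in"/"out" states at q = ∓1) with a linear tilt setting
the flip penalty and a bilinear coupling to s; the flip penalty at fixed
s is evaluated by quadrature over each q half-axis.

## Langevin dynamics

BAOAB splitting with friction default 1 ps⁻¹ — stable and
well-characterised for toy potentials, and in the intermediate-friction
regime for the preset wells (ω ≈ 2–4 ps⁻¹). Forces are linearly
interpolated from a dense table (0.002 u spacing; interpolation error far
below thermal noise), which is what lets the numba kernels integrate
~10⁷ steps/s. A timestep is rejected when ω_max·dt > 0.5 (harmonic
stability proxy keeping per-step energy errors ≪ 10⁻³ kT); a trajectory
leaving the tabulated region (domain + wall pad) aborts with a
divergence diagnostic. All kernels seed their generator explicitly, so
identical inputs are bit-reproducible.

## Metadynamics and reconstruction

Well-tempered deposition: hill height w_k = w₀·exp(−V_bias(s_k)/(kB·ΔT))
with ΔT = (γ−1)T; defaults w₀ = 0.1 kcal/mol, σ = 0.3 u, pace = 500
steps, γ = 8, chosen so the desk-scale presets converge in seconds to
minutes of CPU. Multiple walkers share one bias (deposited on a grid
with its analytic gradient) and deposit round-robin each pace cycle. The
free energy is F(s) = −[γ/(γ−1)]·V_bias(s) (factor 1 for standard
metadynamics), min-shifted to 0. Uncertainty is the per-bin standard
deviation over ≥5 profiles reconstructed at evenly spaced deposition
counts in the final window (default last 20%), after subtracting each
snapshot's mean — metadynamics profiles are defined only up to a
constant. Hills are exchanged in the PLUMED text dialect
(`#! FIELDS time s sigma_s height biasf walker`); the reader is strict
about malformed widths/heights. A parallel-tempering swap step applies
Metropolis acceptance min(1, exp[(βᵢ−βⱼ)(Uᵢ−Uⱼ)]) on the biased
potential energies of neighbouring replicas.

## Path collective variables

The standard exponentially weighted sums over N ordered frames with
1-based indexing, so s ∈ [1, N] and a 30-frame default maps the toy
landmarks (main barrier ≈ 12, external pose ≈ 15–16, flip comparison
near 25) directly onto the s scale. Sums use a log-sum-exp shift; a
configuration whose exponents all underflow double precision is rejected
as "off-path" instead of returning NaN. λ defaults to 2.3/⟨d²⟩ over
adjacent frames, which makes neighbouring frames resolvable; frames are
reparametrised to equal chord-length spacing, and adjacent spacing must
stay within a factor 2 of its mean. Two limits worth noting: z is exactly
zero on the path only as λ grows (at finite λ it is the softmin of the
squared frame distances, and the off-path increment z(Δ)−z(0) = Δ² is the
exact invariant), and the two end frames carry a one-sided softmax bias
of ≈ e^(−λ⟨d²⟩) in s that interior frames do not.

## Basin thermodynamics

Basin ΔG by trapezoidal Boltzmann quadrature of e^(−βF) over basin
intervals; watershed boundaries on a 1D profile are the saddle positions
(each bin drains monotonically to its minimum). Minima are detected with
a 0.2 kcal/mol prominence threshold and labelled A, B, C… by increasing
s, saddles TS1, TS2… between adjacent minima — note the labels are
positional, so on the full preset the low intra-basin A–B saddle takes
"TS1". Uncertainty is propagated by 200 seeded Gaussian resamples of the
per-bin profile errors. The standard-state correction is kT·ln(V/V₀).
Populations are reported in two conventions that deliberately disagree: a
point-state Boltzmann weight (ΔΔG = 4 kcal/mol → 0.12%) and a
basin-integrated weight (the broad external basin reaches the ~1% scale);
the module computes both and does not force agreement. Quadrature
accuracy is asserted against 10× refined grids in the tests.

## Kinetics

The reported rate always satisfies k = (kT/h)·κ·e^(−βΔG‡) exactly, with
κ absorbing *all* dynamical corrections: both barrier recrossing and the
ratio of the true 1D attempt frequency to kT/h. Operationally the
interface-shooting estimate is k = k_TST,1D · κ_dyn where

- k_TST,1D = ½⟨|v|⟩·e^(−βF(s‡)) / ∫_bound e^(−βF) ds is the exact
  ballistic flux-over-population rate of the 1D landscape, and
- κ_dyn is the velocity-weighted commitment estimator at the saddle
  interface, κ = Σ(v·1_unbound)/Σ(v·1_{v>0}) over Maxwell–Boltzmann
  shots, which equals 1 in the no-recrossing TST limit.

Five interfaces default to ±1 u around the saddle; the spread of κ across
interfaces provides the reported min–max rate range, and a trajectory
commits when it reaches the declared minimum flanking the saddle on
either side (descending the whole watershed avoids boundary flicker).
The correctness arbiter is a brute-force mean-first-passage oracle:
unbiased runs from the bound minimum absorbed at the first minimum
beyond the barrier (so recrossings settle before a passage counts);
agreement within a factor 2 is required on the 7 kcal/mol preset. The
problem sizes used in the shipped checks — 500 shots per interface and
80–100 first-passage runs at dt = 0.05 ps — were chosen so the oracle's
sampling error (≈12% on the MFPT) stays well inside that factor.

SPR dissociation phases are fit as R(t) = R₀e^(−k_d t) + c by
Levenberg–Marquardt with asymptotic 95% intervals from the Jacobian
covariance; a zero-amplitude or non-decaying signal raises "no
dissociation detected", and fits spanning less than one half-life warn.

## NMR observables

**Model-free.** J(ω) = (2/5)[S²τc/(1+(ωτc)²) + (1−S²)τ′/(1+(ωτ′)²)],
τ′⁻¹ = τc⁻¹ + τe⁻¹, with the standard ¹⁵N dipolar/CSA expressions for
R1, R2 (+Rex) and NOE. Interaction constants are the community defaults
(N–H 1.02 Å, CSA −160 ppm, standard gyromagnetic ratios); tumbling is
isotropic only. The fit is two-stage: τc from the trimmed R2/R1 ratio of
the rigid subset (NOE ≥ 0.65, ratio within 1 SD of the 10%-trimmed
mean), refined by minimising the pooled per-residue misfit over that
subset (bounded scalar search, 10⁻³ ns resolution); then per-residue
selection among (S²), (S², τe), (S², Rex) by the score χ² + 2k with ties
within 2 going to the simpler model. With three observables per residue
the sample is too small for the usual small-sample AIC correction, hence
the plain penalised-χ² score. Synthetic tables carry a 0.1% error floor
even at zero noise so χ² weighting stays on a sensible scale. The R1R2
product flags exchange-broadened residues above the 10%-trimmed mean
plus 1.5 trimmed SD.

**Shifts.** Δδ = √(ΔδH² + (α·ΔδN)²) with α = 0.15 (configurable; a
community default, as is the 0.7 ppm three-level CSI threshold). Signal
classes (appearing/disappearing/unchanged) and the bookkeeping block
(total/visible/assigned counts and percentages) come from the visibility
and assignment flags; invisible residues propagate as absent records
(NaN), never as zeros. A minimal NMR-STAR reader imports deposited
H/N chemical-shift loops for real assignments.

**Order parameters.** Trajectory S² is the plateau (mean over the final
half of the computed lags, which extend to one fifth of the series) of
the P2 autocorrelation of the unit bond vector, evaluated through the
five real second-rank components with FFT correlations. The wobble-in-a-
cone closed form S² = [cosθ(1+cosθ)/2]² is the analytic cross-check; the
cone simulator takes tangent-plane Gaussian steps with rejection at the
cone wall. MD-vs-NMR agreement is summarised as the mean absolute
percentage deviation over shared residues.

**H/D exchange.** Single-exponential least squares per residue;
P = k_intr/k_exch and ΔG_unfold = RT·ln P as an exact identity. Residues
already exchanged out at the first timepoint get a lower bound on
k_exch (flag "exhausted"); curves with no resolvable decay
(k·t_last < 0.05 or decay within 3× the fit RMS) get an upper bound
(flag "no_decay") so P is a lower bound. The sequence-based intrinsic-
rate helper is an explicitly simplified, order-of-magnitude table
(single left/right log-factor per residue type, base-catalysed regime,
Q10 = 3); ground-truth tests always supply explicit k_intr values.

## What the synthetic data does and does not emulate

The generators reproduce the *statistical structure* of a kinase binding
study: ~250 analysable amides with mean S² 0.85 (apo) / 0.87 (bound) and
floppy termini/loops, τc = 18 ns (plausible for a ~32 kDa domain; a
choice, not a measured value), Gaussian noise at typical instrument
precision (2% relaxation, 3% HDX intensity, 1 RU SPR), shift
perturbations confined to a declared pocket with a 268/196/179
total/visible/assigned bookkeeping preset, protection factors spanning
10–10⁶, and dissociation rates drawn from 0.024–0.19 s⁻¹. They do not
emulate spectrometer artefacts (baseline roll, peak overlap, TROSY
details), anisotropic tumbling, EX1 exchange kinetics, mass-transport
effects in SPR, or any atomistic structure — so passing tests
demonstrate that the estimators invert their own forward models at
realistic noise, not that they are robust to every pathology of real
spectra.

## Known limitations

- 1D free-energy profiles only; the flip axis enters through quadrature
  at fixed s, not through 2D minimum-energy-path tracing.
- The interface-shooting κ estimator is validated against the
  brute-force oracle on toy landscapes only; no full RETIS/FFS bookkeeping.
- No reweighting of auxiliary observables from the metadynamics bias.
- Association (on-rate) kinetics, enthalpy/entropy decomposition and
  protonation corrections are out of scope.
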