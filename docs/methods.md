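# Methods

This note documents the model, the numerical choices and the conventions
behind `masjump`, and states what the shipped simulations do and do not
capture.

## Spin dynamics in the composite space

The equation of motion is the stochastic Liouville equation in the composite
space of spin ⊗ conformational site.  Density operators are vectorized in
row-major (C) order, so the commutation superoperator of a Hamiltonian `H`
is `L = H ⊗ 1 − 1 ⊗ Hᵀ` and a unitary sandwich lifts to `U ⊗ conj(U)`.  The
composite ordering is site-major: the state concatenates `vec(ρ_site)` over
sites, making the exchange superoperator literally `K ⊗ 1_{d²}` and the
coherent part block diagonal.  All shipped jump models have equal
populations and symmetric exchange; the `JumpModel` type accepts arbitrary
stationary populations and generators but none of the canned experiments use
them.

Interaction strengths are stored as angular frequencies (rad s⁻¹, ħ = 1);
user-facing values are δ/2π in Hz.  Spin parts are normalized such that a
static crystallite with its unique axis at angle β to the field shows

* dipolar:  `H = δ P₂(cos β) Iz Sz` (heteronuclear secular part),
* CSA:      `H = δ P₂(cos β) Iz`,
* quadrupole (spin 1, first order): `H = ½ δ_Q P₂(cos β) (3Iz² − 2)`,

with δ_IS = −2(μ₀/4π) ħ γ_I γ_S / r³ and δ_Q = 2π C_qcc / (2I(2I−1)).
Physical constants are CODATA 2018.

## Frames, rotations, powder averaging

Spherical components use A₂₀ = √(3/2) δ, A₂±₂ = −δη/2 in the principal-axis
system.  Euler angles are active ZYZ (`R = Rz(α) Ry(β) Rz(γ)`); components
transform as `A'_m = Σ_m' D²[m, m'] A_m'` with
`D²[m, m'] = e^{−i m α} d²[m,m'](β) e^{−i m' γ}`.  Worked example: an axial
tensor rotated by (α, β, 0) acquires `A'_m = e^{−imα} d²[m,0](β) A₂₀`, so a
three-site cone at azimuths 0°, 120°, 240° averages to an axial tensor
scaled by P₂(cos θ) — the fast-exchange limit used throughout.  The reduced
Wigner matrix is cross-checked against sympy's in the test suite.

The frame chain is PAS → jump site → crystallite → rotor, followed by the
time-dependent rotor → lab rotation at θ_rot = θ_m + Δ.  The spatial
coefficient is ω(t) = Σ_m w_m e^{imω_r t} with
w_m = d²[0,−m](θ_rot)·A₂,−m(rotor frame); at the magic angle the m = 0
(static) coefficient vanishes identically.

Powder schemes are ZCW sets built from the Fibonacci recursion: N points
with cos β swept linearly, α stepped by F_{k−2}/N and (for three-angle sets)
γ stepped by F_{k−4}/N — the F_{k−3} increment is avoided because
F_{k−2} + F_{k−3} = F_{k−1} anti-correlates α and γ.  When the requested
count is not a set size, the nearest larger set is used (538 → 610).

## Time propagation

The composite generator is periodic in the rotor period (or two periods for
phase-cycled supercycles).  Each period is split into piecewise-constant
steps with the Hamiltonian sampled at the step midpoint; the step count is
chosen so that max|ω(t)|·dt < 0.1 rad and ν₁·dt < 0.05 cycles.  Midpoint
sampling makes the integral of every rotor harmonic over a full period exact,
so there is no secular phase drift across periods.  Step propagators are
matrix exponentials (scipy's scaling-and-squaring, batched over
crystallites); the period propagator and the cumulative sub-period
propagators at the sampling offsets are cached and reused for all later
periods.  Very fast exchange needs no special casing — the exchange part is
negative semidefinite and the exponential is computed directly.

Echo-type sequences with a single midpoint pulse (REDOR, off-MAS) are
evaluated in linear cost by iterating the state vector for the first half
and a detection covector for the second half.

The ²H FID uses a dedicated fast path: the first-order quadrupolar
Hamiltonian is diagonal in the Zeeman basis for every site, so each
single-quantum coherence evolves in an (n_sites × n_sites) block and the two
coherences are propagated independently.  The second-order quadrupolar
interaction enters as a static secular level correction per crystallite and
site, computed by second-order perturbation theory over the Zeeman ladder
from the rotor-period averages ⟨|A₂±₁(t)|²⟩, ⟨|A₂±₂(t)|²⟩ (the oscillating
cross terms drop).  The correction is validated against exact
diagonalization of the static Hamiltonian and is ∝ δ_Q²/ω₀ (~10–100 Hz level
shifts at 18.7 T); toggling it changes sideband intensities by < 1 % there.

## Sequence details and deliberate choices

* **CP.** Continuous rf on both channels; the default match mirrors the
  printed 20 kHz MAS pair (ν₁S = 3.65·ν_r rounded to whole kHz,
  ν₁I = ν₁S + ν_r); the achieved Hartmann–Hahn offsets are logged in the
  trajectory metadata.  The tilted variant applies the effective field
  ν₁(sin ϑ₁ x̂ + cos ϑ₁ ẑ) with the initial I state along that axis and the
  match kept on the effective-field magnitudes; the simulated effective
  coupling scales as sin ϑ₁ (ϑ₁ measured from +z, 90° = standard CP).
* **REDOR.** Two I-channel π pulses per rotor period centred at ε·τ_r and
  (ε+0.5)·τ_r (classic ε = 0.25, XY-4 phases, finite 100 kHz pulses by
  default with an ideal-pulse switch).  The half after the echo centre is
  the time-mirrored train and the centre carries ideal π pulses on both
  channels.  The central π_I is essential: with a continuous train and a
  lone π_S the echo refocuses the dipolar phase exactly (ΔS ≡ 0).  The
  mirrored geometry reproduces both the classic universal curve and the
  sin(2πε) effective scaling of the shifted variant (ε = 0.45 at 5 kHz is
  numerically indistinguishable from classic REDOR at 1545 Hz).
* **wPARS (R10₁³).**  RN₀ and RN_π blocks alternate on I with ideal π_S
  pulses between blocks; element phases ±πν/N.  Windowed elements split the
  π rotation around a central rf-free gap (π/2 – window – π/2) at amplitude
  N ν_r/(2n(1−w)), which raises the effective coupling as the window grows;
  a trailing-window variant is config-exposed (it lowers the coupling
  instead — the window position, not stated in the source experiments, is
  what decides the direction).
* **R18₁⁷.** 18 contiguous π pulses per rotor period at ν₁ = 9 ν_r, phases
  ±70°; one-spin system, zero isotropic shift.
* **Off-MAS echo.** Free evolution at θ_m + Δ with the scalar coupling
  2πJ IzSz; simultaneous ideal π on both spins at τ/2; echo times on
  multiples of two rotor periods.  The small-offset closed form integrates
  cos[πJτ − (Δ δ/√2) P₂(cos β_PR) τ] over the powder (Gauss–Legendre in
  cos β_PR); the coefficient Δδ/√2 is the first-order expansion of
  P₂(cos(θ_m+Δ)) ≈ −√2 Δ and agrees with the full simulation to < 2 % RMS
  in the rigid small-offset regime (the typographically garbled constant in
  the printed source formula is thereby fixed by the simulation itself).
* **²H spectra.** One-pulse FID, 20 samples per rotor period
  (400 kHz spectral width at 20 kHz MAS, guarded against a manifold wider
  than the window), display broadening applied at spectrum time.

## Fitting

Reference grids span [0.8·|δ_scaled|, 1.1·|δ_rigid|] (both signs for
off-MAS, where the sign interferes with J), 101 points by default; λ_lb
grids are 0 plus log-spaced points up to 2 kHz (off-MAS) or 20 kHz
(quadrupole).  χ² is the unweighted residual sum of squares (noise-free
data); ties break to the smallest |δ|, then smallest λ_lb; minima on a grid
edge set `boundary_hit`, and near-degenerate ±δ minima set `sign_ambiguous`.
Pulsed recoupling fits truncate at the first strict local extremum of the
target curve (plateaus extend the search; monotone curves use the full
window).  The off-MAS and quadrupole references are generated analytically
(the free-evolution Hamiltonians are diagonal, so the phases integrate in
closed form), which keeps 2D grids cheap; they match the propagated
simulations to discretization accuracy.

Sideband manifolds are centred before fitting by reading the comb offset
from the autocorrelation of the FID at its strongest non-zero lag (a rotor
echo): every comb line advances by the same phase over that lag, so the
estimate is unbiased even when an outer sideband dominates — a
strongest-peak centroid would mis-centre by multiples of ν_r.  The
correction is applied as a first-order phase ramp in the time domain.

T₁/ₑ is the linearly interpolated first crossing of S₀ below 1/e, censored
at the observation window (20 ms default).  The transition region of a sweep
is the contiguous range of consecutive 1-2-5-grid pairs whose δ_fit jump
exceeds 6 % of the rigid-to-scaled span (magnitudes for magnitude fits,
signed values for off-MAS).

## Reduced-fidelity profile

The test suite and the acceptance script run a documented reduced profile:
34–144 crystallites for dipolar/CSA experiments (610 for ²H γ-averaging),
21–41-point δ grids, and observation windows of 10–80 ms.  The full-fidelity
profile (538–10 946 crystallites, 101-point grids, 150 ms ²H window, the
36-point k_ex grid to 5×10¹¹ s⁻¹) uses the same code paths and is an
hours-scale batch job.

## What the simulations do not capture

Isolated one- and two-spin systems only: no multi-spin couplings, pulse
transients, rf inhomogeneity or chemical-shift offsets during recoupling;
relaxation arises exclusively from the exchange process itself (no Redfield
terms).  η ≠ 0 tensors are accepted by the types but unexercised by the
shipped experiments.  Per-sideband differential linewidths in the ²H spectra
are deliberately collapsed into the single exponential λ_lb of the fit.  In
the intermediate-exchange regime the (δ, λ_lb) χ² surface is a shallow,
partially degenerate valley; fitted values there carry `boundary_hit` /
`sign_ambiguous` flags and should be read as "not measurable", exactly as in
the experimental analysis the package mirrors.
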