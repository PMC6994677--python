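# Methods

This note records the models implemented, the conventions chosen where
the literature offers several, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Units and constants

All interfaces use q in 1/Å, lengths in Å, times in ns, diffusion in
Å²/ns, viscosity in mPa·s, temperature in K.  In this system Boltzmann's
constant is k_B = 13.80649 mPa·s·Å³/(ns·K); it lives in a single
constants module together with the Avogadro and Bjerrum-length scales,
and the unit conversions are covered by round-trip tests (e.g. the
Stokes–Einstein radius of D = 6.18 Å²/ns at η = 1.679 mPa·s, 283.15 K is
20.0 Å).  Files may declare q in 1/nm and times in µs; both are converted
once at parse time.

## Form factors

*Generalized Guinier*, `I = A·exp(−Rg²q²/(3−α))`, valid for qRg < 1.3.
The fit starts from the full curve and iteratively shrinks the upper
window bound until `q_max·Rg ≤ 1.3` (at most 10 iterations) — the
validity bound is standard, the iteration schedule is this package's
choice.  α is held fixed during the fit (default 0, a globular
scatterer).

*Excluded-volume polymer.*  The standard two-term lower-incomplete-gamma
expression with `U = q²Rg²(2ν+1)(2ν+2)/6`:

    P(q) = γ(1/(2ν), U)/(ν·U^{1/(2ν)}) − γ(1/ν, U)/(ν·U^{1/ν})

It reduces to the Debye function at ν = 1/2 (verified to 1e−6 relative
over qRg ∈ [0.01, 10]) and decays as q^{−1/ν} at high q; the asymptotic
log–log slope −1/ν is only reached at qRg ≳ 20, so the Porod-exponent
test probes that regime.  Weighted fits use 1/σ² weights; zero-σ points
receive the curve's median σ to avoid infinite weights on placeholder
errors.

*Infinite-dilution extrapolation* fits I/c linearly in c per q point
(weighted) and returns the intercept with its standard error.  Curves are
first interpolated linearly onto the common q range — the curves are
smooth and 1-D, so linear interpolation adds no model bias.  A degenerate
series (all concentrations equal) falls back to the weighted mean of I/c.

## Structure factors

The experimental S(c,q) is the pointwise ratio of a concentrated curve to
the form factor, smoothed with a centered moving average (default window
5 points; the width is configurable because the appropriate amount of
smoothing depends on counting statistics).

The model S(q) is the MSA closure for hard spheres with a screened-
Coulomb (DLVO) repulsion, the canonical macro-ion model: contact
potential `Z²l_B/((1+κR)²σ)` in k_BT with Bjerrum length l_B(T, ε) and
Debye length 1/κ given directly.  Two implementation notes:

* The solution is computed numerically: the Ornstein–Zernike relation
  with the MSA closure (g = 0 inside the core, c = −βu outside) is solved
  by a Newton–Krylov iteration on a radial sine-transform grid (4096
  points, dr = σ/256).  The result is evaluated *relative to its own
  zero-charge limit on the same grid* and anchored to the analytic
  Percus–Yevick hard-sphere solution, so discretization error cancels and
  the zero-charge limit is exact by construction.  The solver is
  additionally self-validating: the closure residuals vanish at the
  solution, and the uncharged solution agrees with Percus–Yevick to a few
  parts in 10³ before anchoring.
* When the bare MSA yields an unphysical negative contact value g(σ⁺) —
  dilute, strongly coupled systems — the standard rescaled-MSA remedy is
  applied: the system is mapped to an equivalent one with an inflated
  hard core (same number density and physical potential) whose contact
  value vanishes, located by bracketing and bisection on the scale
  factor.

The two hydrodynamic-function estimators are `H_{c,q0} = D_c·S_{q0}/D_0`
(low q) and `H_{c,qL} = η_dilute/η_conc` (high q).  The direction of the
viscosity ratio is fixed by requiring H ≤ 1 for repulsive suspensions and
consistency between the two estimators for weakly interacting solutions.
H(c,q) is treated as q-independent across the fitted window — its low-q
and high-q estimates are close for these systems — and the low-q value is
the one applied in the D_eff correction.

## Spin-echo fits

*Cumulant (initial-slope) fit* `A·exp(−D₁t−D₂t²)` with A ∈ [0.8, 1.2].
D₁ carries inverse-time units as printed; the diffusion-coefficient
reading is D₁/q² in Å²/ns, applied before the S/H correction, which makes
it directly comparable to DLS.  The "initial slope" window keeps times
where the signal is above 0.4 of its amplitude (configurable); with fewer
than five such points the five earliest times are used.  A negative D₁ is
flagged, not raised.

*Stretched exponential* `A·exp(−D′q²t^β)` with β ∈ [0.3, 1.2],
initialized at 0.85.  The exponent β multiplies t only, exactly as the
form is written in the spin-echo literature, so the units of D′ depend on
β; D′ is stored together with β.  The across-q mean β is the unweighted
arithmetic mean.  On single-exponential data the stretched and cumulant
routes agree (β = 1, D′ = D₁/q²), which is a cross-check in the suite.

## Zimm and ZIF dynamics

The chain ISF is the normal-mode dynamic structure factor

    I(q,t) = exp(−q²D·(H/S)·t)/N · Σ_{n,m} exp(−q²B(n,m,t)/6)
    B(n,m,t) = |n−m|^{2ν}l² + (4R_E²/π²) Σ_p A(p)/p^{2ν+1}
               cos(πpn/N)cos(πpm/N)(1 − e^{−t/τ_p})

with bead indices 0..N−1, `|n−m|^{2ν}` (required for non-integer 2ν),
A(p) ≡ 1 for Zimm/ZIF (the array is a hook for damped-amplitude
variants), p_max = N by default, and always evaluated as I(q,t)/I(q,0)
because spin-echo data are normalized.  Implementation is vectorized over
(n, m, p); an independent brute-force double/mode-loop implementation
serves as the oracle for N ≤ 5 chains (agreement to 1e−10).

*Mode times.*  No unique convention exists for the prefactor of the Zimm
spectrum with excluded volume.  This package uses

    τ_p = ηR_E³/(√(3π)·k_BT) · p^{−3ν},   R_E = l·N^ν

with the prefactor exposed as a configurable constant for sensitivity
checks.  Under this convention an acid-unfolded-like chain (ν = 0.55,
l = 13.6 Å, N = 20, η = 1.7 mPa·s) has τ₁ ≈ 50 ns while a GdmCl-like
chain (ν = 0.64, l = 13.4 Å, η = 1.9 mPa·s) has τ₁ ≈ 120 ns; published
per-state values of the first Zimm time are not mutually consistent with
any single prefactor convention we tried, so τ₁ is reported under the
documented convention and is checked only at the level of scalings
(τ₁ ∝ R_E³, order of magnitude) rather than absolute values.

*ZIF* adds a mode-independent internal-friction time, τ_p → τ_p +
τ_intern, damping the fast high-p modes.  τ_intern = 0 reproduces the
Zimm ISF bit-for-bit.

*Center-of-mass diffusion.*  When not supplied, D defaults to the
asymptotic Zimm value `D = 8/(3√(6π³))·k_BT/(ηR_E) ≈ 0.196·k_BT/(ηR_E)`,
the self-consistent choice for a non-draining chain.  The H/S correction
multiplies D inside the ISF exponent as written above; whether a
published fit included that factor during fitting is not always explicit,
and this package applies it as written (H/S = 1 by default).

*Global ZIF fit.*  One weighted least-squares over all (q, t) points
jointly with only (D, τ_intern) free (τ_intern bounded ≥ 0, D ∈ [1e−4,
100] Å²/ns); χ² is the reduced chi-square over all jointly fitted points
(the convention is stated because published χ² values rarely state
theirs).  The reported first Zimm time comes from the input spec, never
from the fit.

## Rigid-body first cumulant and network modes

The first-cumulant formula couples translation and rotation through the
6-vector (q, q×r_j) and the 6×6 generalized diffusion matrix.  The phase
factors are implemented with conjugate phases, `exp(−iq·r_j)…
exp(+iq·r_k)`; a same-sign convention would not give a real orientational
average, and the conjugate form reduces correctly to D in the isotropic
limit and to tr(D_tt)/3 at q → 0.  The diffusion matrix is consumed as
the standard 6×6 layout (translation, rotation, coupling) about the
center of diffusion; bead-shell hydrodynamics outputs must be converted
to this layout by the user (a plain-text 6×6 schema with a units header
is read directly).  Computing the matrix from structure is out of scope —
it is an input.

Orientational averages use a deterministic Fibonacci spherical point set
(default 500 directions).  Every production call doubles the point count
and warns when any value moves by more than 1%; Monte-Carlo averages with
1e5 random orientations agree with the quadrature to better than 0.5% on
the toy systems in the suite.  The form factor itself is evaluated by the
exact Debye double sum `Σ b_j b_k sinc(q·r_jk)` (the quadrature route
exists for cross-checks).

Internal modes come from an anisotropic elastic network (uniform springs
between centers within a 13 Å cutoff, residue-level beads at b-weighted
centroids, uniform mean mass 110 amu) — a deliberately coarse harmonic
model standing in for all-atom force-field normal modes, adequate because
only mode *shapes* enter the observable.  A connected network has exactly
six numerically zero modes; the first internal mode is numbered α = 7.
Eq.-level quantities use the mode amplitude k_α = k_BT/(m̄ω²_α), whose
absolute scale depends on the arbitrary spring constant, and a relaxation
rate λ_α that has no defining equation at this level of theory: λ_α is an
input (default 1/ns), so mode-specific diffusion curves are meaningful in
shape, not magnitude.  Coherent scattering lengths come from a bundled
table; with the deuteration flag, hydrogens within 1.25 Å of N, O or S
take the deuterium value, emulating H/D exchange in heavy water.

## Synthetic data: what it emulates, and what it does not

Generators produce every input the pipeline consumes, with the published
state parameters as generating values (pd2: Rg = 26.7 Å, ν = 0.55,
D = 3.0 Å²/ns, τ_intern = 50.89 ns; pd4: 25.4 Å, 0.46, 1.7, 49.63;
gdmcl: 70.2 Å, 0.64, 1.2, 0; pd6: Rg = 14.8 Å, Guinier α = 0, rigid-body
dynamics plus a single internal mode scaled to ≈20% of D₀).  SANS noise
is 2% relative Gaussian; ISF noise is Gaussian with σ(t) = σ₀(1 +
t/t_max), σ₀ = 0.02, mimicking echo-amplitude loss at long Fourier
times.  Concentration effects enter through a phenomenological structure
factor that is linear in c (screened repulsion for denatured states; a
weak low-q attraction with a minimum near q = 0.07 Å⁻¹ for the native-
like state), so infinite-dilution extrapolation is exact in the noiseless
limit by construction.

What passing tests show: the estimators are unbiased and reach the stated
precision under Gaussian noise of realistic amplitude, the model
implementations agree with independent oracles, and the full generate →
analyze chain closes on its generating parameters.  What they do not
show: robustness to instrument resolution and wavelength smearing,
detector artifacts, buffer-subtraction errors, aggregation, or
inter-state contamination — none of which the generators emulate.

## Problem sizes and tolerances in the suite

The suite runs in well under a minute on one CPU: chains are N = 20
beads (oracle chains N ≤ 5), spin-echo sets use 6 q values × 25
Fourier times, SANS curves 120 q points × 4 concentrations, quadratures
≤ 500 directions with 1e5–2e5-sample Monte-Carlo oracles.  Recovery
tolerances follow the estimator precision at the generating noise level:
(Rg, ν) within (3%, 0.02); (D, τ_intern) within 10% (τ_intern within
±5 ns when the generating value is 0); oracle equivalences at 1e−6
(closed forms), 1e−10 (brute force) and 0.5% (Monte Carlo).  The mean
Zimm stretching exponent for a Gaussian N = 20 chain over q = 0.08–0.15
Å⁻¹, t = 1–100 ns computes to 0.83 under the conventions above (β
crosses 0.85 at q ≈ 0.10, the middle of the window; the long-chain
literature value is 0.85), and the suite checks it to ±0.02.

## Known limitations

* The MSA solver is numerical; extremely strongly coupled dilute systems
  rescale to effective packing fractions near 0.5 where the rescaled-MSA
  ansatz itself is of doubtful physical value (the solver still
  converges).
* τ₁ absolute values inherit the prefactor convention; comparisons
  across conventions require rescaling by the documented constant.
* The ZIF fit assumes the structural parameters (ν, l, N) are known
  exactly from SANS; errors in them propagate into (D, τ_intern) and are
  not included in the reported covariance.
* The elastic network uses a uniform spring constant and residue beads;
  mode frequencies are meaningful only relatively, and λ_α is not
  predicted.
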