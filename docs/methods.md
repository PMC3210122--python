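# Methods

## The model

Each local cortical area is described by the deviation `u_i(t)` of its mean
firing rate from rest, obeying the generalized corticothalamic oscillator

    u_i'' = -2γ u_i' - (γ² - a_i) u_i - b_i u_i(t - τ)
            - c₂ u_i² - c₃ u_i³
            + Σ_j [ ε^u_ij (u_j - u_i) + ε^v_ij (v_j - v_i) ],   v_i = u_i'.

`γ` is the cortical damping rate, `a` the instantaneous cortico-cortical
gain, `b` the delayed cortico-thalamic feedback gain, and `τ` the
transmission delay of the corticothalamic loop.  `c₂` and `c₃` model the
leading nonlinearities of the neuronal firing response.  Pairwise coupling
is diffusive (linearly attractive) through the state and through its
derivative, as two independent channels; it vanishes identically on the
synchronized manifold, and coupling delays between areas are neglected
(the loop delay `τ` is assumed dominant).

We work in units of the damping time (`γ = 1`) with `τ = 3.2`: the delay
is a few damping times, the regime in which the delayed feedback alone
destabilizes the rest state.  We set `c₂ = 0`; a constant shift of `u`
absorbs any quadratic term into redefined gains, so this loses no
generality, and it is also the condition under which the third-order
center-manifold reduction closes without the second-order correction term
(the model then has the odd symmetry `u → -u`, so limit cycles carry only
odd harmonics).  `c₃ > 0` only rescales amplitudes (`u → u/√c₃`), so
`c₃ = 1`.

Internally the equation is the first-order system in `(u, v)` with the
delay acting on `u` only; the linearization about `u = 0` gives the
characteristic equation

    Δ(λ) = λ² + 2γλ + (γ² - a) + b e^{-λτ} = 0.

On the lowest (slow-wave) branch, `Im Δ(iω) = 0` fixes
`b(ω) = 2γω / sin(ωτ)` in closed form and `Re Δ(iω) = 0` becomes a scalar
root problem on `ωτ ∈ (0, π)`; the Hopf point `(ω_c, b_c)` is found by
bracketed bisection to machine precision and transversality
`d Re λ / db > 0` is checked from `dλ/db = -e^{-λτ}/Δ'(λ)`.  Higher
delay-induced branches are deliberately not traced.

### Reference operating points

All studies run at three points of the `(a, b)` plane packaged in
`delayosc/data/params_default.yaml`:

* **A** `(a, b) = (1.2, b_c + 0.01)` — near onset; growth rate
  `μ ≈ 0.0024`, period `≈ 16.8`, nearly sinusoidal.  Used for every
  quantitative comparison between the full model and its reductions, and
  as the center of the population ensembles.
* **B** `(0.0, b_c + 0.01)` — the same offset above the stability
  boundary as A (comparable amplitude) but Hopf frequency 0.630 versus
  A's 0.356.  Partner of A in the amplitude-death study, which requires a
  frequency mismatch large compared with the growth rates.
* **C** `(0.9, b_c + 7.2)` — far above onset; a strongly anharmonic but
  stable and strictly periodic cycle (period ≈ 7.41).  Its phase coupling
  function carries 3rd and 5th harmonics comparable to the fundamental,
  which is what produces multimodal locking.  C sits deliberately close
  to (but below) the offset at which the single-oscillator attractor
  loses simple periodicity; the package verifies regularity by the
  crossing-interval jitter of the converged cycle.

## Numerical integration

Classical RK4 by the method of steps: the step `dt = τ/m` divides the
delay exactly (`m ≥ 20`, default 40; 80 at C where the waveform is
steep), so the derivative discontinuities emanating from the initial time
propagate onto grid nodes and every Runge-Kutta stage's delayed argument
falls on a stored node or segment midpoint.  Dense output is cubic
Hermite using the stored `(u, v)` and `(v, acc)` pairs; delayed lookups
always interpolate.  On the linear fixture the observed convergence order
is ≈ 4.0 and the default step reproduces the exact interval-by-interval
solution to ~6e-9 after three delay intervals.  A guard aborts with the
blow-up time when `|u| > 1e6`.  Default initial history is the constant
0.01 (any history in the basin serves; the rest state is excluded).

Limit cycles are extracted after a transient: amplitude is `max |u|`,
the phase origin is the upward `u = 0` crossing, and the period comes
from a least-squares fit to the origin-crossing comb, geometrically
extrapolated because near onset the crossing intervals converge only at
the Floquet rate `2μ`.  Far from onset a waveform may cross zero more
than once per period; crossings are grouped modulo an FFT period estimate
and the family holding the steepest crossing defines the origin.
Quiescence (amplitude `< 1e-9`, or fewer than 3 crossings) is reported as
a valid outcome, not an error — amplitude death produces exactly that.

## Center-manifold reduction

Following Hale's decomposition, with `φ(θ) = (1, iω)ᵀ e^{iωθ}` on
`[-τ, 0]`, dual `ψ(s) = (iω + 2γ, 1) e^{-iωs} / Δ'(iω)` on `[0, τ]`, the
Hale bilinear pairing of the pair equals `Δ'(iω)` in closed form (the
package also evaluates it by quadrature as a cross-check; the
normalization matrix is the identity to 1e-8).  The bifurcation offset
`ν = b - b_c` is treated as a third, frozen variable of order `|z|²`, so
the unfolding enters through the extended system rather than an ad-hoc
expansion.  Every forcing of the acceleration equation projects through
`κ = 1/Δ'(iω)`, giving the planar (non-averaged) amplitude equations and,
after rotating-frame averaging, the network Stuart-Landau/CGL form

    ż_j = (μ_j + iΩ_j) z_j + c z_j |z_j|² + Σ_k (ε^u_jk κ + iω ε^v_jk κ)(z_k - z_j),

with `μ_j = ν_j Re(dλ/db)`, `Ω_j` including the offset shift, and
`c = -3c₃κ` (supercritical throughout the region used: `Re c < 0`).
`u ≈ 2 Re z`, so the predicted cycle amplitude is `2√(-μ/Re c)`, the
frequency `Ω + Im c · |z|²`, and the relaxation rate `2μ`; all three
match direct simulation at A to a few percent.

Because `c₂ = 0` makes the cubic coefficient proportional to `κ` itself,
the combination `W = (-i - χ)κ` (with shear `χ = Im c / Re c`) is purely
imaginary.  Two structural consequences, both verified numerically: the
analytic phase sensitivity is a pure sinusoid, and the v-channel phase
coupling function is exactly even — derivative-diffusive coupling does
not move phase differences at leading order, which is why the
synchronization and multimodal studies couple through `u` only.

Amplitude death of a pair is decided by the eigenvalues of the coupled
rest state: exactly, from the 4-dimensional real linearization of the
planar equations (which keeps the non-resonant terms), and in closed form
from the averaged pair,
`λ± = mean(m) - dε ± √((dε)² + (Δm/2)²)`, `m_j = μ_j + iΩ_j`,
`d` the projected coupling.  The threshold is the smallest `ε` with
`max Re λ = 0` (bisection on the exact matrix).  With A-B's frequency
mismatch (0.27) far exceeding the growth rates (~0.002), death onset is
controlled by the contraction `ε Re κ` against `μ`.

## Phase reduction

The direct method: start on the converged cycle at a grid phase, kick the
chosen component of the instantaneous state only (the history segment is
untouched — the kick models an additive delta forcing of the acceleration
equation, so the physically relevant component is `v`), integrate 25–70
periods, and read the asymptotic shift of the origin-crossing comb
against an unperturbed control run.  Two estimator details matter near
onset, where the Floquet rate `2μ` is slow: the reference comb is fitted
to the control run itself (cancelling any residual convergence of the
source cycle), and the shift sequence is extrapolated by Aitken's
delta-squared (it settles geometrically at the Floquet ratio).  Default
impulse `1e-3 ×` amplitude; halving it changes Z by well under 1%.

Coupling functions are trapezoid-rule convolutions over the common phase
grid,

    Γ(φ) = (1/2π) ∫ Z(θ) [s(θ - φ) - s(θ)] dθ,

per unit coupling intensity, with `s` the cycle's `u` (or `v`) waveform.
The argument convention is own-phase-minus-partner-phase, so a symmetric
pair obeys `dψ/dt = Δω + ε γ_a(ψ)` with `γ_a(φ) = Γ(φ) - Γ(-φ)`, roots
with negative slope are stable, and diffusive u-coupling makes the
in-phase state stable, as a linearly attractive interaction must.
Fixed points are located by sign-change bracketing plus bisection on the
interpolant; basins of the 1-D circle flow are delimited by the unstable
points.  The critical coupling for locking is
`ε_c = |Δω| / max(∓γ_a)`.  Grid sizes: 64 phases at A, 128 at C (whose Z
has strong harmonic content); locking in simulations is declared when the
frequencies averaged over 1,000 rotations differ by less than
`2π·1e-4 / T`.  That criterion resolves frequency differences down to
`~4e-5`, so the smallest mismatch in the critical-coupling comparison is
kept at `Δω = 0.001`, where the resolution floor is a few percent of the
mismatch rather than comparable to it.

With `c₂ = 0` the odd symmetry forces `γ_a(φ + π) = -γ_a(φ)`: only odd
harmonics, an odd number of stable locked states, and a stable point at
`φ*` paired with an unstable one at `φ* + π`.  At C the measured mix is
roughly `γ_a ∝ 0.01·sin φ + 0.88·sin 3φ + sin 5φ`, which has ten zeros —
five stable locked states.  The multimodal experiment launches the
coupled identical pair (`ε = 0.05`, weak relative to the attraction of
the cycle) from 20 uniformly spaced initial phase differences; the grid
is offset by 0.1 rad so that no run starts exactly on the in-phase
separatrix, which is an unstable equilibrium and would simply stay put.

## Population studies

Ensembles are built by drawing per-oscillator targets `(μ_j, Ω_j)`
uniformly and independently around A — growth-rate half-width 10% of
`μ_A`, frequency half-width 0.0015 — and inverting the reduction for
`(a_j, b_j)` (the same inversion supplies the equal-amplitude detuned
partner in the critical-coupling study).  The frequency half-width is
chosen well below `μ/Re κ` so that the Kuramoto transition completes at
couplings far from the collective-death regime of strong mean-field
contraction.  Coupling is all-to-all through `u`, normalized by `n`
(default `n = 50`).  Phases are read from origin-crossing combs by linear
interpolation, and the order parameter `R(t) = |mean_j e^{iθ_j}|` is
averaged over ~150 periods after a `30/μ` transient.  The same drawn
frequencies drive the reduced phase model
`θ̇_j = Ω_j + (ε/n) Σ_k Γ(θ_j - θ_k)` (fixed-step RK4 on the interpolated
Γ), for the DDE-versus-phase-model comparison.  All randomness flows from
one master seed through `numpy.random.SeedSequence`.

## Design choices and limitations

* The study conditions (operating points, coupling strengths, ensemble
  widths) are fixed in one packaged defaults file; everything downstream
  is deterministic given the seed.
* The analytic reduction path requires `c₂ = 0` and rejects anything else
  explicitly; it is leading-order in `μ`, and its accuracy degrades as
  `O(√μ)` — at A (amplitude ≈ 0.18) the measured PRC agrees with the
  analytic sinusoid to ~6% normalized RMS, and moving A further from
  onset would degrade that roughly linearly in amplitude.
* Only the lowest Hopf branch and simple periodic attractors are
  handled; the chaotic/quasiperiodic bands above C's offset are detected
  (crossing-interval jitter) but not analysed.
* The death-threshold bisection classifies a run as dying from the decay
  of its amplitude envelope over a `30/μ` window; exactly at threshold
  the rate vanishes, so the simulated threshold carries a small (<2%)
  upward bias controlled by the window length.
* No state-dependent or distributed delays, no delayed coupling, no
  stochastic forcing, no spatially continuous fields.  Synthetic
  ensembles emulate heterogeneity only through `(μ_j, Ω_j)`; real
  corticothalamic populations differ in ways (noise, connectivity
  structure, delay dispersion) that these tests do not probe.
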