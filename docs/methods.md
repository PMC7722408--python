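# Methods

## Model and conventions

Four populations — STN (`S`), GPe (`G`), cortical excitatory (`E`) and
inhibitory (`I`) — evolve as leaky sigmoid-driven firing rates with one
membrane time constant τ and one shared transmission delay `T`
(reduced, homogeneous form; the heterogeneous-constant variant is out
of scope for analysis).  Units: time in ms, rates in spk/s, angular
frequency ω in rad/ms; reported frequencies are `f = 1000·ω/(2π)` Hz.
The sigmoid `F(x) = M/(1 + (M−B)/B·e^{−4x/M})` satisfies `F(0) = B`,
range `(0, M)`, and the exact identities

    F'   = 4F(M−F)/M²
    F''  = 16F(M−F)(M−2F)/M⁴
    F''' = 64F(M−F)(M² + 6F² − 6MF)/M⁶,

which give the linearization entries `a_ij = ±(w/τ)F'` and the
quadratic/cubic drive coefficients `c_X = F''/(2τ)`, `e_X = F'''/(6τ)`
in closed form.  All of these are validated in the test suite by
central differences and complex-step differentiation of the raw
sigmoid vector field.

Because the cortex receives no basal-ganglia feedback, the
characteristic function of `du/dt = B1·u + B2·u(t−T)` factorizes,

    Δ(λ) = Δ1(λ)·Δ2(λ),
    Δ1 = (λ+1/τ)² − (λ+1/τ)a22·e^{−λT} − a12a21·e^{−2λT}   (STN–GPe)
    Δ2 = (λ+1/τ)² − a34a43·e^{−2λT}                        (cortex E–I),

verified against the explicit 4×4 determinant at random complex points.

## Crossing search

Imaginary roots of `Δ1` satisfy a quartic in `z = ω²` whose
coefficients follow from eliminating the delay with
`sin² + cos² = 1`.  The quartic is solved by companion-matrix
eigenvalues; near-real roots are polished by real Newton iteration and
accepted only if the polynomial residual vanishes, which keeps
near-double roots (branch collisions along parameter scans) from being
silently dropped.  For each frequency the delay is recovered from the
unit-circle root `x = e^{−iωT}` of the quadratic
`a12a21·x² + a22(iω+1/τ)x − (iω+1/τ)² = 0`.  This enforces the sine
*and* cosine conditions simultaneously — a single-valued arccos misses
crossings with negative sine — and remains well-defined in the
degenerate case where the rational sine/cosine forms become 0/0 (both
quadratic roots on the unit circle).  `Δ2` crosses iff
`−a34a43 > 1/τ²`, at `ω = √(−a34a43 − 1/τ²)`, with delays from the two
square roots of `(iω+1/τ)²/(a34a43)`.  Every reported crossing must
pass `|Δ_loop(iω)| < 1e−8`.  The minimal positive delay `T0` carries a
loop attribution (basal-ganglia resonance vs. cortical resonance);
ties keep the largest frequency and set a flag.

A brute-force oracle — a dense `(ω, T)` sweep of `|Δ(iω, T)|` with
Nelder-Mead refinement of every candidate minimum — reproduces the
closed-form `T0` to better than 1e−3 ms on random admissible sets.  An
earlier Newton-continuation oracle (tracking the four zero-delay roots
in `T`) proved unreliable: near root collisions the iteration jumps
branches and can fabricate or miss crossings, so the scan oracle
replaced it.

Transversality uses `λ'(T) = −(∂Δ/∂T)/(∂Δ/∂λ)` with the loop-factor
partials assembled explicitly; the same formula serves crossings of
either factor because the off-factor term carries a `Δ_other` weight
that vanishes on the crossing factor.  Zero-delay stability expands
the product of the two `T = 0` quadratics into a quartic and applies
the Routh–Hurwitz inequalities; the verdict is tested against direct
eigenvalues of `B1 + B2`.

## Normal form

At a crossing the flow on the two-dimensional center manifold is
reduced in the time-rescaled frame (`t → t/T`, delay at θ = −1).  The
right eigenvector is `(1, χ, β, γ)` with each component solved from
one row of the characteristic matrix; for a basal-ganglia crossing
`β = γ = 0` exactly (no feedback into the cortex), and the adjoint
eigenvector is full, while a cortical crossing reverses the pattern
(adjoint supported on `(E, I)` only).  The normalization `ρ` comes
from the delay bilinear form with
`η(θ) = T0[B1δ(θ) + B2δ(θ+1)]`; the tests verify `⟨q*, q⟩ = 1` and
`⟨q*, q̄⟩ = 0` to 1e−9.

The Taylor coefficients of the projected dynamics are *derived in
code* from the exact quadratic/cubic expansion of the nonlinearity —
each population's drive is `c_X(l_X·v)² + e_X(l_X·v)³` with `l_X` the
row of synaptic input weights — rather than transcribed term by term.
With `a_X = l_X·q0·e^{−iω0T0}`:

    g20 = 2T0 Σ w_X c_X a_X²,  g11 = 2T0 Σ w_X c_X |a_X|²,
    g02 = 2T0 Σ w_X c_X ā_X²,
    g21 = 2T0 Σ w_X [3 e_X a_X²ā_X + c_X(2 a_X w11_X + ā_X w20_X)],

where `w_X` are the adjoint projection weights and `w20/w11` contract
`l_X` with the center-manifold terms `W20(−1)`, `W11(−1)`.  The
corrections solve
`(2iω0 − B1 − B2e^{−2iω0T0})E1 = 2e^{−2iω0T0}F2` and
`−(B1+B2)E2 = 2F11` (so `E2`, and `W11(−1)`, are real).  Complex-step
directional-derivative oracles reproduce every g-coefficient from the
raw vector field to 1e−5, and the full chain is cross-validated by
simulation (below).  `W20/W11` are evaluated only at θ = −1; the
operator-theoretic derivation scaffolding has no runtime
representation.

### The two c1 scalings, and a known discrepancy

Two conventions for the cubic normal-form coefficient appear in the
delay-Hopf literature, differing in whether the cross term divides by
the physical frequency or the rescaled one:

* `c1 = i/(2ω0)·(g20g11 − 2|g11|² − |g02|²/3) + g21/2`, paired with
  the physical `λ' = dλ/dT`.  The package's reported `μ2 = −Re c1/Re λ'`,
  `β2 = 2Re c1` and `T2 = −(Im c1 + μ2 Im λ')/ω0` use this form.
* the time-rescaled (Hassard) form `c1s` with `1/(2ω0T0)`, paired with
  the rescaled eigenvalue slope `T0·Re λ'`.  This is the form with a
  direct dynamical meaning: near onset the stationary
  center-coordinate amplitude obeys `|ξ|² ≈ (T − T0)/mu2_amp` with
  `mu2_amp = −Re c1s/(T0·Re λ')`.  Euler simulations at the bundled
  point give an empirical `(T−T0)/|ξ|²` of ≈1.7e−3 against the
  predicted 1.698e−3 (|ξ| read as peak-to-peak of S over 4), which is
  the strongest end-to-end check of the g-chain.

Both scalings always agree in sign, so the classification
(supercritical / stable orbit / growing period) is convention-free.
Previously reported magnitudes for this circuit
(μ2 ≈ 5.5e−4, β2 ≈ −1.5e−5, T2 ≈ 8.6e−6) could not be reproduced
under either convention, although the transversality value implied by
their ratio (−β2/(2μ2) = Re λ' = 0.013460 ms⁻²) matches this
implementation to five digits, and the signs agree.  For a
basal-ganglia crossing the coefficients depend on the cortical
constants only through the equilibrium rate `E*` (the eigenvector's
cortical components vanish, so every cortex-specific term drops out),
and `E*` is pinned by the critical delay — there is no remaining
freedom with which to reconcile the magnitudes.  The
simulation-measured amplitude law sides with the values computed here.

## Calibration of the cortical constants

`M_E, B_E, M_I, B_I` are specified only as physiological ranges.
`calibrate_cortical_constants` sweeps a coarse grid over the ranges,
brackets sign changes of `T0 − target` along the `B_E` axis (the
cortical equilibrium rate, and hence the critical delay, is monotone
in `B_E`), and bisects each bracket.  Among completions hitting the
target, those whose minimal crossing is the STN–GPe loop and whose
cortical loop also crosses at some larger delay are preferred: the
first property matches the beta-band basal-ganglia onset under study,
the second lets the cortex oscillate at long delays, as the full
nonlinear simulations show.  The bundled default
(`M_E = 80, B_E = 20, M_I = 100, B_I ≈ 0.4722`) gives
`E* ≈ 63.309` spk/s, `T0 = 3.6807` ms at 27.94 Hz, with the cortical
loop crossing at 4.85 ms.  Because only `E*` matters for the
basal-ganglia normal form, every admissible completion at the same
target delay yields identical μ2/β2/T2 (verified: an independently
calibrated completion agrees to six digits).

## Simulation

Explicit Euler with step `h = 0.01` ms (first-order convergence
verified by step-halving; at `h = 0.01` the effective onset shifts by
less than 0.01 ms).  The delay is a ring buffer of `round(T/h)`
samples, so `T` is rounded to the step grid.  The default initial
history holds the equilibrium with `S` *and* `E` kicked by +1 spk/s —
the cortical pair must be kicked separately because it receives no
basal-ganglia feedback and would otherwise balance on an unstable
equilibrium indefinitely.  Attractor summaries discard a transient
(default half the run), measure peak-to-trough of `S`, estimate the
frequency from inter-peak intervals with a periodogram cross-check
(discrepancy >5% flags the summary), and label bands as alpha
[8,13) Hz, beta [13,30] Hz (boundaries inclusive), gamma >30 Hz.

Ramped scans carry each grid point's final history into the next and
re-inject a 0.5 spk/s kick.  Near a Hopf point, critical slowing makes
raw amplitude thresholds unreliable in both directions — a slowly
decaying transient looks like a small orbit, a slowly growing mode
looks like rest — so points with excursion below 5 spk/s are
classified by the sign of the envelope growth rate of the deviation
from the analytic fixed point: clear decay (more than ≈20% per
1000 ms) means fixed point; growth or a flat (saturated) envelope
means oscillation.  This resolves the onset to about one grid step.
Codimension-two maps evaluate the linear analysis per cell (stable iff
the cell's delay is below its minimal critical delay; with zero-delay
stability, roots reach the right half-plane only through the
imaginary axis) and refine the boundary by bisection; the
simulation-mode map agrees within one boundary cell.

## Problem sizes and defaults

Analysis calls are closed-form and run in milliseconds.  The shipped
study sizes: the acceptance calibration uses a 4×5×10×6 coarse grid
(1200 points) plus bisection; the delay-onset scan uses 200 points on
[1, 10] ms at `h = 0.01` with 1 s settle + 1 s measure per point; the
scaling checks use 11-point ramps with 3 s settle; the band profile
covers [2.2, 15] ms with finer sampling near onset.  The fixture
generator draws weights within ±50% of the fitted values, inputs
within ±20%, cortical constants within their ranges and delays on
[1, 15] ms, rejection-sampling enough members to keep at least 30%
with a Hopf crossing.

## Known limitations

* Analysis covers only the equal-delay, equal-τ reduced model; the
  simulator accepts the same reduced form.
* No periodic-orbit continuation (collocation/shooting); diagrams come
  from simulation plus analytic onset points, so far-from-onset orbit
  amplitudes carry Euler bias of order `h`.
* No Bautin/generalized-Hopf handling: μ2 ≈ 0 degeneracies raise
  errors rather than expanding to fifth order.
* The envelope-trend classifier assumes a single dominant mode near
  onset; exactly at the critical delay the fixed-point/orbit
  distinction is ill-posed within one grid step by construction.
* Synthetic parameter draws are independent and uniform; real fitted
  parameter sets are correlated, so fixture coverage does not imply
  coverage of physiological co-variation.
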