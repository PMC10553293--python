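# Methods

## Waveform model

A diffusion encoding is an ordered set of trapezoidal gradient lobes on
one axis around an instantaneous refocusing pulse. Each lobe is
(start, duration, ramp, amplitude) with the duration including both
ramps; ramp = 0 degenerates to an ideal rectangle (represented with
repeated breakpoints), duration = 2·ramp to a triangle. The *effective*
waveform negates every lobe that ends before the refocusing time and is
the object all phase quantities are computed on.

Moments Mn = γ∫G(t)·tⁿ dt (n = 0, 1, 2) and the diffusion weighting
b = ∫q(t)² dt with q = γ∫G dt are evaluated segment by segment through
polynomial antiderivatives: G is linear on each segment, so G·tⁿ is a
polynomial of degree n+1 and q is piecewise quadratic. Each segment is
integrated in local coordinates u = t − t₀, which keeps the arithmetic
well-conditioned even for microsecond ramps. γ defaults to
2.678×10⁸ rad/s/T. Internally everything is SI-consistent (s, T/mm, so
M1 is s/mm, M2 s²/mm, b s/mm²); constructors and file formats use the
conventional ms and mT/m.

**Time origin.** t = 0 is placed at the start of the first gradient lobe,
not at excitation. M1 of a refocused (M0 = 0) waveform is
origin-independent, but M2 is not (it shifts by 2·Δt·M1 under a
translation Δt); the encoding-start convention is the one under which the
reference second-moment magnitudes of this design are quoted, and it is
recorded in the `EffectiveWaveform.origin` marker. Where within the echo
time the encoding sits is irrelevant to every origin-invariant quantity
(b, concomitant balance, M1, and M2 of the compensated schemes).

**Refocusing pulse.** Treated as instantaneous and centred in the
inter-side pause (refocus at pre-duration + pause/2). Any symmetric
placement inside the pause gives identical results because no lobe may
straddle it (enforced at construction).

**Concomitant (Maxwell) balance.** First-order concomitant phase scales
with ∫G² dt; the reported imbalance is the pre-180° integral minus the
post-180° integral of the *physical* waveform. All schemes built here are
mirror-symmetric in |G| about the refocusing pulse, so the imbalance is
zero to rounding; the builders' tests assert ≤10⁻¹² of the natural scale.

## The scheme family

All builders share the 56 ms envelope — 23 ms of gradient per side,
10 ms pause, 1.3 ms ramps — and one absolute amplitude per scheme,
re-solved exactly (√(b_target/b_current), closed form) for the requested
b-value. The 1.3 ms ramp is stated only for the velocity-compensated
pulse in the source protocol and is extended to all lobes for want of
other data; the rectangular limit (ramp = 0) is retained as an analytic
oracle.

* *Monopolar*: one lobe filling each window, same polarity (the spin-echo
  flip balances M0).
* *Velocity-compensated*: four 11.5 ms lobes by the concatenation rule —
  effective pattern G, −G, (pause), −G, G, which is even about the
  midpoint with zero net area, hence M1 = 0 for any pause length.
* *Acceleration-compensated*: per side a short outer lobe (duration a)
  and long inner lobe (duration b), opposite polarity, a + b = 23 ms.
  The effective pattern (+a, −b | +b, −a) is odd about the midpoint, so
  M2 = (2a+2b+c)·M1 identically (time origin at the start); driving
  M1 → 0 by bisection over a (bracket (2·ramp, side/2), xtol 10⁻¹² s on
  the exact engine M1, never the rectangular approximation) nulls both.
  Solved timings at the default envelope: a = 8.263 ms, b = 14.737 ms
  (rectangular limit: a = 7.888 ms, the root of
  (a+b+c)(b−a) = 2ab).
* *Partially compensated*: a → a + t_S, b → b − t_S on all four lobes,
  pause and total duration unchanged, amplitude re-solved to hold b. Both
  residual fractions |M1|/M1max and |M2|/M2max (reference: the monopolar
  scheme with the same side/pause lengths and b-value) rise together; at
  the default timings the tangent slope at t_S = 0 is 0.3469 /ms
  (rectangular closed form: 0.3247 /ms). The map t_S ↦ fraction is
  monotone and inverted by bisection (`solve_shift_for_fraction`).

**Naming.** "84%-compensated" denotes compensation *level*
1 − |M1|/M1max = 0.84, i.e. residual fraction 0.16 (t_S = 0.45 ms);
"67%" likewise (t_S = 0.95 ms, fraction ≈ 0.34). The inverse convention
(quoting the residual fraction itself with the same numerals) circulates
as shorthand; the CLI report prints a footnote stating which convention
is in force. Family labels come from the nominal linear model
(level = 1 − 0.348·t_S); exact fractions are always reported separately.

**Linearity caveat.** The fractions are linear in t_S only to first
order: against the tangent line at t_S = 0 the exact values deviate by up
to ≈2.5% at t_S = 1.5 ms (quadratic term of the exact M1 polynomial plus
the amplitude re-solve). Tests assert a 3% envelope; the tuning
coefficient itself is defined by the central difference at ±0.01 ms of
the *signed* M1 fraction (|M1| has a kink at zero).

## Rectangular closed forms

For ideal rectangles the engine quantities collapse to polynomials
(γG the gamma-scaled amplitude, times in consistent units):
M1 = γG·[(a+b+c)(b−a) − 2ab]; M2 = γG·[−2a³+2b³−6a²b−3a²c+3b²c−2ab²
−ac²+bc²−2abc], which factors exactly as (2a+2b+c)·M1; and
b = (γG)²·D/3 with D = 2a³+3a²(2b+c)−6ab(b+c)+b²(2b+3c). The b-value
identity fixes the amplitude, giving the first-order coefficients
|dM1/dt_S| = 2γG(2b+c) and dM2/dt_S = (2a+2b+c)·dM1/dt_S — the ratio of
the two is the total encoding duration (56 ms here), which is also the
monopolar M2/M1 ratio. These forms were derived from first principles
and are verified symbolically (sympy) and against the engine in the test
suite; they serve as the independent oracle for the numeric path, which
they must match to 10⁻¹⁰ relative in the zero-ramp limit.

## Motion / IVIM signal model

* Phase of a coherently moving spin packet: φ = M0·x0 + M1·v + ½·M2·a
  (Taylor expansion of the trajectory against the moment definitions).
  The M0 term is kept for diagnosing unbalanced waveforms.
* Ballistic blood: plug flow at speed v through isotropically oriented
  vessels, attenuation = |orientation average of cos(M1·v·cosθ)| =
  |sin(M1·v)/(M1·v)|. The isotropic sinc closure is the simplest
  ballistic-limit model; real vascular trees have orientation structure
  and a speed distribution, so the factor is a mechanism illustration,
  not a fitted IVIM model. It depends on M1 only — not on b — which is
  the signature separating perfusion dephasing from diffusion decay.
* Two-compartment liver: S(b)/S(0) = (1−f)·e^(−b·D_liver) +
  f·e^(−b·D_blood)·attenuation(M1, v_blood). Defaults f = 0.3,
  D_blood = 1.6 µm²/ms, D_liver = 0.95 µm²/ms; v_blood = 3 mm/s is a
  representative microvascular speed giving strong (but not total)
  monopolar blood suppression. With unattenuated blood the two-point ADC
  of this mixture is 1.110 µm²/ms, close to the first-order estimate
  f·D_blood + (1−f)·D_liver = 1.145 µm²/ms.
* Two-point ADC = ln(S_low/S_high)/(b_high − b_low), b = 50/800 s/mm² by
  default — the only estimator consistent with a two-b protocol; it
  exactly inverts monoexponential decays. Error on non-positive signals.
* Trace-weighted combination: arithmetic mean over repetitions within
  each diffusion direction, then geometric mean across directions; a
  zero direction-mean yields zero, documented rather than raised. ROI
  normalization divides by a positive reference mean.

The model reproduces the *direction* of the encoding-dependent ADC bias
(monopolar below velocity-compensated) deterministically; in-vivo
magnitudes depend on physiology the desk model does not contain and are
out of scope.

## Numerical choices

* Bisection (`scipy.optimize.brentq`) everywhere a scalar root is
  needed; brackets stated above; tolerances 10⁻¹² s (timings) and
  10⁻⁹ ms (shift solve).
* Moments and b agree with an adaptive-quadrature oracle to ≤10⁻⁸
  relative on randomized schemes (test suite).
* Waveform CSV sampling at a 10 µs dwell loses ≤10⁻³ relative on the
  moments (round-trip tested); the breakpoint JSON format is exact to
  its 10⁻⁹ ms/mT-per-m rounding.
* Degenerate inputs: zero waveform has b = 0; unbalanced waveforms
  (M0 ≠ 0) warn on b-value evaluation and fail `diffenc check`;
  infeasible geometry (ramps longer than lobes, unreachable fractions,
  no M1 root) raises `InvalidSchemeError`.

## Scope and limitations

Slew-rate/PNS/acoustic optimization, oblique multi-axis concomitant
cross-terms, finite RF-pulse effects, EPI image formation and
cardiac-cycle-resolved motion are out of scope. The builders assume one
shared amplitude magnitude per scheme; numerically optimized waveforms
with per-lobe amplitudes can differ from this family by a few per cent
in the partially compensated moments. Whether bright-blood suppression
is driven more by the M1 or the M2 increase cannot be decided by this
model and no function claims to decide it.
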