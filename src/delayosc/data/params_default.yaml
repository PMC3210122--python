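# Packaged reference operating points of the corticothalamic
# delay-oscillator model
#
#   u'' = -2*damping*u' - (damping^2 - gain_a)*u - gain_b*u(t - delay)
#         - nl2*u^2 - nl3*u^3 + coupling
#
# Time is measured in units of the damping time (damping = 1); the
# corticothalamic transmission delay is 3.2 damping times, the regime in
# which the delayed feedback itself induces the oscillation.  gain_b is
# the Hopf control parameter: the rest state destabilizes when gain_b
# exceeds the critical value b_c(gain_a) of the characteristic equation
#   lambda^2 + 2*damping*lambda + (damping^2 - gain_a)
#     + gain_b*exp(-lambda*delay) = 0.
# nl2 = 0: a shift of u absorbs any quadratic term, and only then does the
# cubic-order center-manifold reduction close without the second-order
# correction.  nl3 > 0 rescales the oscillation amplitude only.
#
# A: near onset, b = b_c(1.2) + 0.01 = 0.784366209603778 + 0.01.
#    Small near-sinusoidal cycle (period ~ 16.8); reference point for all
#    reduction-validity comparisons and the population studies.
# B: same offset above the boundary, b = b_c(0.0) + 0.01
#    = 1.3972317383168265 + 0.01; Hopf frequency 0.630 vs A's 0.356, so B
#    oscillates markedly faster at a comparable amplitude: the partner of
#    A in the amplitude-death study.
# C: far above onset, b = b_c(0.9) + 7.2 = 0.9150608733632576 + 7.2.
#    Strongly anharmonic stable cycle (period ~ 7.41) whose antisymmetric
#    phase coupling function carries 3rd and 5th harmonics strong enough
#    to support five stable locked states of an identical pair.
sets:
  - label: A
    delay: 3.2
    damping: 1.0
    gain_a: 1.2
    gain_b: 0.794366209603778
    nl2: 0.0
    nl3: 1.0
  - label: B
    delay: 3.2
    damping: 1.0
    gain_a: 0.0
    gain_b: 1.4072317383168265
    nl2: 0.0
    nl3: 1.0
  - label: C
    delay: 3.2
    damping: 1.0
    gain_a: 0.9
    gain_b: 8.115060873363257
    nl2: 0.0
    nl3: 1.0
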