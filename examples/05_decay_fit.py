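"""Fit the log-space single-exponential decay model to a miR-7 time course.

The probe:loading-control ratio y(t) = A exp(-k t) + B is fit in log space
with chained, bounded L-BFGS-B; the half-life ln(2)/k folds together
molecular decay and dilution by cell division.
"""

import math

from tddseq import DecaySimParams, fit_decay, simulate_decay_course
from tddseq.decay import loglinear_reference_fit

true_half_life = 20.0
params = DecaySimParams(rate_k=math.log(2) / true_half_life, amplitude_A=1.5,
                        baseline_B=0.05, times_h=(24, 32, 48, 80),
                        noise_sigma=0.05, seed=11, label="miR-7 2'-O-Me")
course = simulate_decay_course(params)
print("time (h)   miR-7 : miR-11 ratio")
for t, y in zip(course.times_h, course.ratios):
    print(f"  {t:5.0f}     {y:.4f}")

fit = fit_decay(course)
print(f"\nfitted rate k        = {fit.rate_k:.4f} /h")
print(f"fitted amplitude A   = {fit.amplitude_A:.3f}")
print(f"fitted baseline B    = {fit.baseline_B:.4f}")
print(f"half-life ln(2)/k    = {fit.half_life_h:.1f} h  (simulated: "
      f"{true_half_life:.0f} h)")
print(f"chain converged after {fit.n_iterations} warm-started rounds")

k_ols, _ = loglinear_reference_fit(course)
print(f"\nlog-linear reference (B=0 assumption) half-life: "
      f"{math.log(2) / k_ols:.1f} h")
print("-> the fitted half-life encapsulates both decay and culture "
      "dilution; the B term absorbs the endogenous steady-state signal.")
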