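"""Fit the five free parameters to synthetic dose-response data.

Plasma time courses of unbound trap and VEGF/trap complex are simulated at
the canonical parameters across four doses, corrupted with 10% lognormal
noise, and refit by bounded multi-start weighted least squares.  Three
trials are used here for speed; the validation suite runs the full 20.
"""

from vegfmouse import (OPTIMAL_FREE_PARAMETERS, asymptotic_standard_errors,
                       fit_multistart, generate_synthetic_dataset)

data = generate_synthetic_dataset(noise_cv=0.10, seed=7)
print(f"synthetic dataset: {data.n} records over doses {data.doses()} mg/kg")

result = fit_multistart(data, n_trials=3, seed=7)
print(f"\nbest of {len(result.trials)} trials: WSSR = {result.wssr:.3f}")
print(f"{'parameter':14s} {'estimate':>12s} {'truth':>12s} {'error':>8s}")
for name, truth in OPTIMAL_FREE_PARAMETERS.items():
    est = result.estimates[name]
    print(f"{name:14s} {est:12.4g} {truth:12.4g} "
          f"{abs(est - truth) / truth * 100:7.1f}%")

sd = asymptotic_standard_errors(data, noise_cv=0.10)
print("\nexpected sampling SD of each estimate at this design "
      "(delta method):")
for name, s in sd.items():
    print(f"  {name:14s} {100 * s / OPTIMAL_FREE_PARAMETERS[name]:6.1f}% "
          "of truth")
print("lymphatic drainage is effectively unidentifiable from plasma data;")
print("errors above are noise-realisation draws against those SDs.")
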