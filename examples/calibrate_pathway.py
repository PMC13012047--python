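"""Recover the generating parameters from synthetic cruises.

Samples noisy cruise transects from a known-truth run (phosphate-
inhibited production), then reoptimizes the five free parameters —
oxidation rate and threshold plus the three production parameters —
from a twofold-perturbed start, and compares the recovered values with
the truth.  Takes a couple of minutes (~300 forward solutions); the test
suite runs the same experiment at the full budget.
"""

from oceanch4.calibrate import optimize
from oceanch4.pipeline import make_truth

exp = make_truth(seed=7, dt=1.0)
print(f"{len(exp.cruises)} synthetic cruises, "
      f"{sum(c.n_samples for c in exp.cruises)} samples, "
      f"noise sd {exp.world.config.noise_sd} nM")

init = {k: 2 * v for k, v in exp.truth_params.items()}
res = optimize("po4", init, exp.cruises, exp.world,
               max_forward=300, n_restarts=2, dt=1.0, seed=7)
print(f"cost: {res.initial_cost:.3f} nM (perturbed start) -> {res.cost:.3f} nM "
      f"after {res.n_forward} forward solves")
print(f"{'parameter':>8} {'recovered':>10} {'truth':>8} {'error':>7}")
for k, truth in exp.truth_params.items():
    v = res.params[k]
    print(f"{k:>8} {v:10.4g} {truth:8.4g} {100 * abs(v - truth) / truth:6.1f}%")
print("-> the optimized cost approaches the observation-noise floor and "
      "the parameters close in on the values that generated the data.")
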