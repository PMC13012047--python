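"""Spin up the preindustrial methane field and run 1700 -> 2014.

Solves the 1700 steady state (706 ppb atmosphere) by Newton's method,
then integrates the tracer equation against the rising atmospheric CH4
record with phosphate-inhibited production switched on, and prints how
the dissolved methane distribution responds.
"""

import numpy as np

from oceanch4 import WorldConfig, build_world
from oceanch4.pipeline import TRUTH_OXIDATION, TRUTH_PRODUCTION, run_model

world = build_world(WorldConfig(seed=0))
run = run_model(world, TRUTH_PRODUCTION, TRUTH_OXIDATION, dt=0.25)
g = world.grid


def area_mean(field2d):
    return float((field2d * g.area).sum() / g.area.sum())


c0 = run.spinup.c.reshape(g.shape)
c1 = run.states[-1].c.reshape(g.shape)
print(f"atmosphere: {world.atmosphere.value(1700):.0f} ppb (1700) -> "
      f"{world.atmosphere.value(2014):.0f} ppb (2014)")
print(f"surface mean [CH4]: {area_mean(c0[0]):.2f} nM (1700) -> {area_mean(c1[0]):.2f} nM (2014)")
print(f"deep (>2000 m) mean: {c0[-2:].mean():.2f} nM -> {c1[-2:].mean():.2f} nM")
print(f"oxidation threshold floor: min [CH4] = {c1.min():.2f} nM "
      f"(threshold {run.ox.c_crit} nM)")
print("-> the surface tracks the rising atmosphere almost in lockstep; "
      "the deep ocean lags by centuries because it only feels the "
      "atmosphere through high-latitude ventilation.")
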