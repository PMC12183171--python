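"""Simulate one growing season and inspect states, outcomes and constraints.

Rolls the default two-field environment forward under a simple threshold
irrigation/fertilization rule, then prints the season totals and the
constraint audit for the executed plan.
"""

import numpy as np

import agroplan as ap
from agroplan import evaluate as ev
from agroplan import simulator as sim

env = ap.make_environment({"noise_scale": 0.5}, seed=42)
rng = np.random.default_rng(42)

traj = sim.rollout(env, lambda s: ev.rule_based_policy(s, env), rng=rng)
outcomes = traj.outcome_array()          # (fields, steps, [Y, C, E])

print(f"{env.n_fields} fields, {env.horizon} steps, noise x{env.noise_scale}")
for i in range(env.n_fields):
    y, c, e = outcomes[i].sum(axis=0)
    water = traj.actions[i, :, sim.WATER].sum()
    fert = traj.actions[i, :, sim.FERT].sum()
    print(f"field {i}: yield {y:7.1f} kg/ha   cost {c:6.2f} $/ha   "
          f"env impact {e:5.3f}   water {water:6.0f} L/ha   fert {fert:5.1f} kg/ha")

plan = sim.ControlPlan.zeros(env)
plan.actions = traj.actions
report = ap.check_constraints(plan, outcomes[:, :, 2])
print(f"plan feasible: {report.feasible} "
      f"(budget margin {report.budget.worst_margin:.0f} of {env.budget:.0f})")

w = sim.ObjectiveWeights(1.0, 1.0, 1.0)
print(f"season objective J = {sim.objective(traj.outcomes, w):.1f} "
      "(sum over fields and steps of yield - cost - impact)")
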