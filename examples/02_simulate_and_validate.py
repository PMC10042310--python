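"""Generate a synthetic five-task dataset and validate its schema.

The generator mirrors the study design (ages 3-5, 16 familiar items,
16/12/16/16/8+8 trials per task) with responses drawn from the model under
known ground-truth parameters.
"""

from pragint.simulate import SimConfig, simulate
from pragint.validate import validate

trials, roster, truth = simulate(SimConfig(n_children=8, seed=42))

print(f"children: {len(roster)}, trials: {len(trials)}")
print("\ntrials per task (first child):")
first = trials[trials.child_id == roster.child_id[0]]
print(first.task.value_counts().to_string())

print("\nground truth for the first three children:")
for i in range(3):
    print(
        f"  {roster.child_id[i]} (age {roster.age_years[i]:.2f}): "
        f"alpha={truth.alpha[i]:.2f} rho={truth.rho[i]:.2f} "
        f"mean theta={truth.theta[i].mean():.2f}"
    )

report = validate(trials, roster)
print(f"\nschema validation: {report}")
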