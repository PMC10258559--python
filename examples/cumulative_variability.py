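"""Cumulative variability over the design hierarchy, with a control.

Enumerates all consistent subdatasets with 2 or 3 replicates,
experiments, persons or laboratories, computes the variance of the
per-replicate feature means in each, and compares the resulting curve
against a label-randomised control.
"""

from migvar import (
    DesignSpec,
    GenerativeParams,
    cumulative_curve,
    generate_hierarchical_dataset,
    level_means,
    randomized_control,
)

design = DesignSpec(n_cells_per_replicate=5, n_timepoints=12, conditions=("control",))
params = GenerativeParams(
    beta0=1.0,
    sigma2_lab=4.0, sigma2_person=1.0, sigma2_experiment=0.5,
    sigma2_replicate=0.25, sigma2_cell=2.0, sigma2_residual=2.0,
    seed=3,
)
table, _ = generate_hierarchical_dataset(design, params)

real = cumulative_curve(table, "ics")
ctrl = randomized_control(table, "ics", seed=3)
print(f"{len(real)} subdatasets enumerated "
      f"(e.g. {sum(real.level == 'replicate')} at the replicate level)")

print("\nmean cumulative variance per level (real vs randomised control):")
rm, cm = level_means(real), level_means(ctrl)
for level in rm.index:
    print(f"  {level:10s} real {rm[level]:6.3f}   control {cm[level]:6.3f}")
print("\nwith laboratory variance dominant the real curve jumps when labs "
      "are combined; the randomised control is flat because permuting the "
      "replicate means destroys the hierarchy.")
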