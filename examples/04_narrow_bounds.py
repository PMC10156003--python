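"""Narrow parameter bounds with the nearest training simulations.

A target snapshot is generated at a known killing probability.  Forty
training simulations with random killing probabilities are projected by
a small ensemble, and the bounds are set to the min/max parameter values
of the 8 simulations nearest the target in embedding space.
"""

import numpy as np

from abmcal import (
    EX1_SCHEMA,
    EncoderConfig,
    ParameterRanges,
    ProcessConfig,
    SimConfig,
    build_training_set,
    estimate_bounds,
    nominal_parameters_ex1,
    process,
    sample_parameters,
    simulate,
    train_ensemble,
)

sim_cfg = SimConfig(n_steps=40, initial_tumor_radius=60.0)
proc = ProcessConfig(schema=EX1_SCHEMA, cell_diameter=20.0,
                     tumor_channels=("tumor",), target=(16, 16))
ranges = ParameterRanges.from_dict({"kill_prob": (0.001, 0.1)})
nominal = nominal_parameters_ex1()  # kill_prob = 0.02

target = process(simulate(nominal, sim_cfg, seed=11), proc)
matrix = sample_parameters(ranges, 40, seed=1)
ts = build_training_set(matrix, ranges.names, nominal, sim_cfg, proc,
                        replicates=1, seed=2)
ens = train_ensemble(ts.images[~ts.failed],
                     EncoderConfig(conv_channels=(4, 8), hidden=16,
                                   batch_size=16, epochs=40), 3, seed=3)

nb = estimate_bounds(ens, target, ts, n_closest=8)
print(f"widest range:    [{ranges.lower[0]:.4f}, {ranges.upper[0]:.4f}]")
print(f"narrowed bounds: [{nb.lower[0]:.4f}, {nb.upper[0]:.4f}]")
print(f"true value 0.02 inside: {nb.lower[0] <= 0.02 <= nb.upper[0]}")
print(f"selected kill_probs: {np.round(ts.params[nb.selected_rows, 0], 4)}")
# The narrowed interval concentrates the subsequent GA search on the region
# of parameter space whose simulations resemble the target image.
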