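"""Simulate the fitted fast-spiking model and extract its firing features.

Runs the four fitting protocols (long depolarizing/hyperpolarizing steps,
brief strong pulse, distal synapse volley) on the packaged re-fit model and
prints each feature next to its optimization objective.  The model should fire
a brief-AP fast-spiking train at 200 pA and initiate its AP in the axon
initial segment ~0.05 ms before the soma.
"""

from fsin import build_cell, generate_morphology
from fsin.fitting import (evaluate_fitness, extract_model_features,
                          run_fitting_protocols, reference_objectives)
from fsin.presets import AVERAGED_MORPHO, FITTED_DENSITIES

cell = build_cell(generate_morphology(AVERAGED_MORPHO), FITTED_DENSITIES)
traces = run_fitting_protocols(cell)
fv = extract_model_features(traces)
objectives = reference_objectives()
scores = evaluate_fitness(fv, objectives)

print(f"{'feature':30s} {'model':>10s} {'target':>8s} {'SD':>7s} {'z':>6s}")
for o in objectives:
    v = fv.values.get(o.name, float("nan"))
    print(f"{o.name:30s} {v:10.4f} {o.target:8.3g} {o.sd:7.3g} {scores[o.name]:6.2f}")
print(f"\ntotal SD-scaled deviation: {scores['total']:.2f} "
      "(z is the deviation from target in SDs; z <= 1 is within one SD)")
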