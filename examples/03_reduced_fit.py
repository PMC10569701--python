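"""Run a miniature evolutionary fit of the 13 channel parameters.

A very short run (8 generations x 10 offspring, warm-started from the
packaged re-fit) on the averaged-species morphology, to show the optimization
loop end to end.  The per-generation best score is non-increasing; a full fit
uses hundreds of generations.
"""

from fsin import build_cell, generate_morphology
from fsin.cable import PARAM_NAMES
from fsin.fitting import (EAConfig, ParamSpace, make_evaluator, optimize,
                          reference_objectives)
from fsin.presets import AVERAGED_MORPHO, FITTED_DENSITIES, REFERENCE_DENSITIES

cell = build_cell(generate_morphology(AVERAGED_MORPHO), REFERENCE_DENSITIES)
space = ParamSpace.around_reference(REFERENCE_DENSITIES)
ea = EAConfig(n_generations=8, offspring_size=10, seed=0)
res = optimize(space, reference_objectives(), ea, make_evaluator(cell, fast=True),
               seed_individuals=[FITTED_DENSITIES])

print(res.log.to_string(index=False))
print("\nbest parameter set (pS/µm²; shift in mV):")
for name, value in zip(PARAM_NAMES, res.best.to_vector()):
    print(f"  {name:16s} {value:10.3f}")
print(f"\nbest total SD-scaled deviation: {res.best_score:.2f} "
      "(sum over the 20 feature objectives)")
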