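"""Turn a monomeric contact prediction into interchain predictions.

A contact predictor run on a self-assembling monomer sees intrachain and
interchain signal superimposed.  Knowing the monomer structure, the true
intrachain contacts are subtracted with a tolerance window ("relax
removal"); what survives is ranked as interchain candidates.
"""

from homointer import (RelaxParams, SyntheticSpec, TopKSpec,
                       fabricate_prediction, filter_short_range, make_complex,
                       rank_topk, relax_remove)

spec = SyntheticSpec(seed=1)
chains, intra, inter = make_complex(spec)
pred = fabricate_prediction(intra, inter, spec)  # stands in for a predictor

print(f"raw monomer prediction: {len(pred)} scored pairs")
filtered = filter_short_range(pred)
print(f"after short-range filter (separation >= 6): {len(filtered)}")

for n_r in (0, 1, 2):
    surv = relax_remove(filtered, intra, RelaxParams(n_removal=n_r))
    print(f"relax removal n={n_r}: {len(surv)} candidate interchain pairs")

surv = relax_remove(filtered, intra, RelaxParams(n_removal=2))
top = rank_topk(surv, TopKSpec.resolve("Top-L/10", chains[0].L))
print(f"\nTop-L/10 (k={len(top)}) interchain predictions (i, j, score):")
for i, j, s in top:
    truth = "true" if (i, j) in inter.entries or (j, i) in inter.entries \
        else "false"
    print(f"  {i:3d} {j:3d}  {s:.3f}  -> {truth} interchain contact")
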