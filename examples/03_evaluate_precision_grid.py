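"""Relaxed Top-k precision of inferred interchain contacts.

Precision is TP/k over the k best-scored predictions; a prediction counts
as correct if a true interchain contact lies within the (2n+1) x (2n+1)
window around it or its index-swapped mirror ("relaxation" n).
"""

from homointer import (RelaxParams, SyntheticSpec, density_report,
                       fabricate_prediction, filter_short_range, make_complex,
                       precision_grid, relax_remove)

reports = []
for seed in range(4):
    spec = SyntheticSpec(seed=seed)
    chains, intra, inter = make_complex(spec)
    pred = fabricate_prediction(intra, inter, spec)
    surv = relax_remove(filter_short_range(pred), intra,
                        RelaxParams(n_removal=2))
    ranked = sorted(surv.items, key=lambda t: (-t[2], t[0], t[1]))
    rep = precision_grid(ranked, inter, RelaxParams(2, 0), L=chains[0].L,
                         target=f"synth{seed}")
    reports.append(rep)

print("target synth0, relax removal 2 — precision by relaxation and Top-k:")
df = reports[0].to_frame()
print(df.pivot(index="k_label", columns="n_e", values="precision").round(3))
print("\nprecision rises with relaxation (wider matching window) and falls")
print("for large k (the denominator outgrows the interface size).\n")

print("mean precision per contact-density bin (all 4 targets):")
table = density_report(reports)
sel = table[table.k_label == "Top-L/10"]
print(sel[["bin_lo", "bin_hi", "n_e", "mean_precision", "n_targets"]]
      .to_string(index=False))
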