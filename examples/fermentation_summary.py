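"""Derive yields, find the substrate optimum and rank pretreatments.

Uses the packaged substrate-loading series (25-200 g/L spoiled date fruit)
and the pretreatment screen.
"""

from mycorefinery import datasets
from mycorefinery.fermentation import derive_table, find_optimum, rank_treatments

series = datasets.load_substrate_series()
derived = derive_table(series)
cols = ["substrate_conc", "lipid_content", "lipid_yield_mg_g", "consumed_sugar"]
print(derived[cols].round(2).to_string(index=False))

opt = find_optimum(list(zip(series["substrate_conc"], series["lipid_conc"])))
print(f"\nlipid optimum: {opt.substrate_conc:g} g/L SDF ({opt.response:.1f} g/L lipid)")
# lipid titer peaks at moderate loading; higher loadings inhibit the culture

ranking = rank_treatments(datasets.load_pretreatment_observations(), "lipid_conc")
print("\npretreatments by lipid titer:")
for obs, value in ranking[:3]:
    print(f"  {obs.treatment_label:26s} {value:.1f} g/L")
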