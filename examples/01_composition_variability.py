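"""Survey the chemical-composition variability of the ingredient panel.

Loads the packaged ten-sample enzymolytic soybean meal (ESBM) panel,
summarizes each analyte (mean, range, CV with the population-SD
convention), and converts one sample to the dry-matter basis.
"""

from feedval import Basis, convert_basis, load_compositions, summarize_table

comps = load_compositions("table6")
summary = summarize_table(comps).round(2)

print("As-fed composition summary across the 10 ESBM samples:")
print(summary.loc[["DM", "GE", "CP", "EE", "CF", "NDF", "ADF", "Ash", "Trp"]])
print()
print("A CV near 5% (GE) means the panel is energetically homogeneous;")
print("CVs above 10% (CP, fibre, ash) flag analytes a buyer should assay")
print("batch by batch before formulating with this ingredient.")
print()

esbm5 = next(c for c in comps if c.ingredient_id == "ESBM 5")
dm5 = convert_basis(esbm5, Basis.DRY_MATTER)
print(f"ESBM 5 gross energy: {esbm5.ge:.2f} MJ/kg as-fed "
      f"-> {dm5.ge:.2f} MJ/kg DM (DM {esbm5.dm_pct:.2f}%)")
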