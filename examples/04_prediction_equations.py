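"""Predict nutritional value from chemical composition.

Screens DM-basis composition against ingredient energy with Pearson
correlations, fits prediction equations by best-subset selection, and
applies one to a new batch.
"""

from feedval import fit_linear, pearson_matrix, predict, stepwise_select
from feedval.pipeline import build_ingredient_table, default_bundle

table = build_ingredient_table(default_bundle())

corr = pearson_matrix(table, ["DE", "ME", "CP", "CF", "ADF", "NDF", "Ash", "GE"])
print("Correlation screen (lower triangle, * p<0.05, ** p<0.01):")
print(corr.annotated())
print()

ranked = stepwise_select(
    table["DE"], table[["GE", "CP", "Ash", "NDF", "CF", "ADF", "EE"]],
    max_terms=2, response="DE(MJ/kg DM)",
)
print("Best energy prediction equations (by R2, then RMSE):")
for eq in ranked[:3]:
    print(" ", eq)
print()

ash_eq = fit_linear(table["DE"], table[["Ash"]], response="DE(MJ/kg DM)")
print("Single-assay alternative:", ash_eq)
new_batch = {"Ash": 9.17}  # a high-ash batch, DM basis
print(f"Predicted DE for a batch with {new_batch['Ash']}% ash: "
      f"{predict(ash_eq, new_batch):.2f} MJ/kg DM")
print("Ash is the cheap single predictor: mineral dilution of organic")
print("matter tracks energy loss, at the cost of a lower R2.")
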