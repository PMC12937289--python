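"""Packaged study tables and bundle loading.

The package ships the study's printed tables as small CSVs: diet
formulations and analyzed compositions for both experiments, the
ingredient survey panel (proximates, amino acids, minerals,
anti-nutritional factors), the diet/ingredient energy means, and the
per-diet SID means with the basal endogenous-loss column.  ``<0.01``
p-values are stored as their bound, 0.01.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ._text import read_csv_clean
from .composition import IngredientComposition, frame_to_compositions
from .exceptions import FixtureLookupError
from .ileal import EndogenousLossTable

__all__ = ["load_fixture", "load_compositions", "load_endogenous_table",
           "FIXTURES"]

#: Fixture name -> packaged CSV file.
FIXTURES = {
    "table2": "table2_diet_formulation_exp1.csv",
    "table3": "table3_diet_composition.csv",
    "table4": "table4_diet_formulation_exp2.csv",
    "table5": "table5_diet_aa.csv",
    "table6": "table6_esbm_composition.csv",
    "table7": "table7_minerals.csv",
    "table8": "table8_anti_nutritional.csv",
    "table9": "table9_energy.csv",
    "table12": "table12_sid.csv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged study table by name.

    Names are ``table2 ... table9, table12`` plus the derived view
    ``table12_iaa`` (amino acid and basal endogenous loss only).
    """
    if name == "table12_iaa":
        t12 = load_fixture("table12")
        return t12[["amino_acid", "iaa_g_per_kg_dmi"]].copy()
    try:
        filename = FIXTURES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; known: {sorted(FIXTURES)} + ['table12_iaa']"
        ) from None
    path = resources.files("feedval.data").joinpath(filename)
    with path.open("r", encoding="utf-8") as fh:
        return read_csv_clean(fh)


def load_compositions(name: str = "table6") -> list[IngredientComposition]:
    """Load an ingredient-panel fixture as composition objects (as-fed)."""
    df = load_fixture(name)
    if "GE" not in df.columns:
        df = df.assign(GE=float("nan"))
    return frame_to_compositions(df)


def load_endogenous_table(scale_factor: float = 1.0) -> EndogenousLossTable:
    """Basal ileal endogenous AA losses shipped with the SID table."""
    iaa = load_fixture("table12_iaa")
    return EndogenousLossTable(
        iaa_g_per_kg_dmi=dict(zip(iaa["amino_acid"], iaa["iaa_g_per_kg_dmi"])),
        source="companion endogenous-loss study (nitrogen-free diet)",
        scale_factor=scale_factor,
    )
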