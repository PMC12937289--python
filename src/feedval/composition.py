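"""Ingredient and diet chemical compositions.

Feed compositions are reported either *as-fed* (per kg of material as it is
consumed, water included) or on a *dry-matter* (DM) basis.  Both express the
same sample, rescaled by the dry-matter fraction:

    value_dm = value_as_fed * 100 / DM%

The module also provides the variability summary used throughout the
ingredient-survey tables: mean, range and coefficient of variation (CV).
The CV here uses the **population** standard deviation (denominator ``n``),
which is the convention the reference tables follow; the sample-SD variant
is available for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._text import read_csv_clean
from .exceptions import (
    InsufficientDataError,
    InvalidCompositionError,
    UndefinedStatisticError,
)

__all__ = [
    "Basis",
    "IngredientComposition",
    "CompositionSummary",
    "canonical_analyte",
    "convert_basis",
    "summarize_analyte",
    "summarize_table",
    "read_composition_csv",
    "write_composition_csv",
    "compositions_to_frame",
]


class Basis(str, Enum):
    """Reporting basis of a composition."""

    AS_FED = "as_fed"
    DRY_MATTER = "dry_matter"


#: Controlled vocabulary of analyte names.  Matching is case-insensitive;
#: unknown analytes are carried through untouched under their given name.
_ANALYTE_VOCABULARY = (
    "DM", "GE", "CP", "EE", "CF", "NDF", "ADF", "Ash", "Starch",
    "IDF", "SDF", "TDF",
    "Lys", "Met", "Thr", "Trp", "Val", "Ile", "Leu", "Arg", "His", "Phe",
    "Ala", "Asp", "Cys", "Glu", "Gly", "Pro", "Ser", "Tyr", "TAA",
    "Ca", "P", "Cu", "Zn", "Fe", "Mn", "Na", "Mg", "K",
)
_CANONICAL = {name.lower(): name for name in _ANALYTE_VOCABULARY}


def canonical_analyte(name: str) -> str:
    """Return the canonical spelling of an analyte name.

    Matching is case-insensitive against the controlled vocabulary
    (proximate analytes, fibre fractions, amino acids, minerals); names not
    in the vocabulary are returned stripped but otherwise unchanged.
    """
    return _CANONICAL.get(name.strip().lower(), name.strip())


@dataclass(frozen=True)
class IngredientComposition:
    """One ingredient's analyte panel with an explicit reporting basis.

    Parameters
    ----------
    ingredient_id
        Sample label, e.g. ``"ESBM 5"``.
    basis
        Reporting basis of ``ge`` and every analyte.
    dm_pct
        Dry-matter content in percent, in ``(0, 100]``.  Basis-free: the DM
        fraction of the sample does not change when the panel is rescaled.
    ge
        Gross energy, MJ/kg on ``basis``.
    analytes
        Mapping analyte name -> percent of mass on ``basis`` (mg/kg for
        trace minerals; the conversion rule is the same single rescaling).
    """

    ingredient_id: str
    basis: Basis
    dm_pct: float
    ge: float
    analytes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.dm_pct <= 100.0:
            raise InvalidCompositionError(
                f"{self.ingredient_id}: dm_pct must be in (0, 100], got {self.dm_pct}"
            )
        clean = {}
        for name, value in self.analytes.items():
            if value < 0:
                raise InvalidCompositionError(
                    f"{self.ingredient_id}: analyte {name!r} is negative ({value})"
                )
            clean[canonical_analyte(name)] = float(value)
        object.__setattr__(self, "analytes", clean)
        object.__setattr__(self, "basis", Basis(self.basis))

    def analyte(self, name: str) -> float:
        return self.analytes[canonical_analyte(name)]


@dataclass(frozen=True)
class CompositionSummary:
    """Mean / range / CV summary of one analyte across samples."""

    analyte: str
    mean: float
    min: float
    max: float
    cv_pct: float


def convert_basis(
    comp: IngredientComposition, target: Basis | str
) -> IngredientComposition:
    """Re-express a composition on the requested basis.

    Gross energy and every analyte are rescaled by the single factor
    ``100 / dm_pct`` (to dry matter) or ``dm_pct / 100`` (to as-fed);
    ``dm_pct`` itself is unchanged.  A no-op when already on ``target``.
    """
    target = Basis(target)
    if comp.basis is target:
        return comp
    if target is Basis.DRY_MATTER:
        factor = 100.0 / comp.dm_pct
    else:
        factor = comp.dm_pct / 100.0
    return replace(
        comp,
        basis=target,
        ge=comp.ge * factor,
        analytes={k: v * factor for k, v in comp.analytes.items()},
    )


def summarize_analyte(
    values: Sequence[float],
    analyte: str = "",
    *,
    population: bool = True,
) -> CompositionSummary:
    """Mean, range and CV of one analyte across samples.

    ``cv_pct = 100 * sd / mean`` with the population SD (``n`` denominator)
    by default; pass ``population=False`` for the sample SD (``n - 1``).

    Raises
    ------
    InsufficientDataError
        Fewer than two values.
    UndefinedStatisticError
        Mean is zero, so the CV is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"need at least 2 values to summarize, got {x.size}"
        )
    mean = float(x.mean())
    if mean == 0.0:
        raise UndefinedStatisticError("CV undefined: mean is zero")
    sd = float(x.std(ddof=0 if population else 1))
    return CompositionSummary(
        analyte=analyte,
        mean=mean,
        min=float(x.min()),
        max=float(x.max()),
        cv_pct=100.0 * sd / abs(mean),
    )


def summarize_table(
    comps: Iterable[IngredientComposition],
    analytes: Sequence[str] | None = None,
    *,
    population: bool = True,
) -> pd.DataFrame:
    """Summarize every analyte (plus DM and GE) across a set of ingredients.

    Returns a frame indexed by analyte with columns ``mean, min, max, cv_pct``,
    full precision (round for display).  All compositions must share a basis.
    """
    comps = list(comps)
    bases = {c.basis for c in comps}
    if len(bases) > 1:
        raise InvalidCompositionError(
            "cannot summarize compositions on mixed bases; convert first"
        )
    if analytes is None:
        seen: dict[str, None] = {}
        for c in comps:
            for k in c.analytes:
                seen.setdefault(k)
        analytes = ["DM", "GE", *seen]
    rows = []
    for name in analytes:
        cname = canonical_analyte(name)
        if cname == "DM":
            values = [c.dm_pct for c in comps]
        elif cname == "GE":
            values = [c.ge for c in comps]
        else:
            values = [c.analytes[cname] for c in comps if cname in c.analytes]
        s = summarize_analyte(values, cname, population=population)
        rows.append((cname, s.mean, s.min, s.max, s.cv_pct))
    return pd.DataFrame(
        rows, columns=["analyte", "mean", "min", "max", "cv_pct"]
    ).set_index("analyte")


# ---------------------------------------------------------------------------
# CSV interface: one row per ingredient, columns ingredient_id, basis, DM, GE,
# then analytes.
# ---------------------------------------------------------------------------

def read_composition_csv(path_or_buf) -> list[IngredientComposition]:
    df = read_csv_clean(path_or_buf)
    return frame_to_compositions(df)


def frame_to_compositions(df: pd.DataFrame) -> list[IngredientComposition]:
    reserved = {"ingredient_id", "basis", "DM", "GE"}
    analyte_cols = [c for c in df.columns if c not in reserved]
    out = []
    for _, row in df.iterrows():
        out.append(
            IngredientComposition(
                ingredient_id=str(row["ingredient_id"]),
                basis=Basis(row.get("basis", Basis.AS_FED)),
                dm_pct=float(row["DM"]),
                ge=float(row["GE"]) if "GE" in df.columns else math.nan,
                analytes={c: float(row[c]) for c in analyte_cols},
            )
        )
    return out


def compositions_to_frame(comps: Iterable[IngredientComposition]) -> pd.DataFrame:
    rows = []
    for c in comps:
        rows.append(
            {"ingredient_id": c.ingredient_id, "basis": c.basis.value,
             "DM": c.dm_pct, "GE": c.ge, **c.analytes}
        )
    return pd.DataFrame(rows)


def write_composition_csv(comps: Iterable[IngredientComposition], path) -> None:
    compositions_to_frame(comps).to_csv(path, index=False)
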