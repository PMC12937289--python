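"""Digestible and metabolizable energy from total-collection balance trials.

A balance trial measures, for each pig in each period, total gross-energy
(GE) intake and total fecal and urinary GE over a collection window.  Diet
digestible energy (DE) and metabolizable energy (ME), per kg of dry-matter
intake, are

    DE_d = (GE_i - GE_f) / F
    ME_d = (GE_i - GE_f - GE_u) / F

With the difference (substitution) method, a test ingredient replaces a
fixed fraction ``X`` of the energy-supplying part of a basal diet.  The
basal diet's energy is first rescaled to its energy-supplying fraction
(default 0.97 — the remainder is minerals and premix, assumed inert):

    DE_dc = DE_d(basal) / 0.97

and the ingredient energy follows by subtracting the basal contribution:

    DE_ingredient = [DE_d(test) - DE_dc * (1 - X)] / X

ME is treated identically.  ``X`` defaults to 0.30: the test ingredient
replaces 29.10 of the 97.00 parts of energy-supplying ingredients
(29.10 / 97.00 = 0.30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._text import read_csv_clean
from .exceptions import (
    ConfigError,
    InvalidRecordError,
    InvalidSubstitutionError,
    MissingTreatmentError,
)

__all__ = [
    "BalanceRecord",
    "DietEnergy",
    "CorrectedBasalEnergy",
    "IngredientEnergy",
    "diet_energy",
    "correct_basal",
    "ingredient_energy_by_difference",
    "estimate_ingredient_energies",
    "treatment_energy_summary",
    "read_balance_csv",
    "write_balance_csv",
]

DEFAULT_SUBSTITUTION_X = 0.30
DEFAULT_ENERGY_FRACTION = 0.97


@dataclass(frozen=True)
class BalanceRecord:
    """One pig-period total-collection observation.

    ``feed_intake_kg_dm`` is kg of dry matter eaten over the collection
    window; the three energies are MJ totals over the same window.
    """

    pig_id: str
    period: int
    diet_id: str
    feed_intake_kg_dm: float
    ge_intake_mj: float
    fecal_ge_mj: float
    urine_ge_mj: float

    def __post_init__(self) -> None:
        if self.feed_intake_kg_dm <= 0:
            raise InvalidRecordError(
                f"{self.pig_id}/p{self.period}: feed intake must be > 0"
            )
        if self.ge_intake_mj <= 0:
            raise InvalidRecordError(
                f"{self.pig_id}/p{self.period}: GE intake must be > 0"
            )
        if self.fecal_ge_mj < 0 or self.urine_ge_mj < 0:
            raise InvalidRecordError(
                f"{self.pig_id}/p{self.period}: output energies must be >= 0"
            )


@dataclass(frozen=True)
class DietEnergy:
    """Diet DE/ME on a dry-matter-intake basis (MJ/kg DM)."""

    diet_id: str
    de_d: float
    me_d: float

    @property
    def me_de_ratio_pct(self) -> float:
        return 100.0 * self.me_d / self.de_d


@dataclass(frozen=True)
class CorrectedBasalEnergy:
    """Basal-diet energy rescaled to its energy-supplying fraction."""

    de_dc: float
    me_dc: float
    energy_fraction: float = DEFAULT_ENERGY_FRACTION


@dataclass(frozen=True)
class IngredientEnergy:
    """Difference-method estimate of an ingredient's DE and ME (MJ/kg)."""

    ingredient_id: str
    de: float
    me: float
    substitution_x: float


def diet_energy(rec: BalanceRecord) -> DietEnergy:
    """DE_d and ME_d of the diet in one balance observation.

    Negative digestibility (fecal GE exceeding intake) is reported with a
    warning rather than clipped, so aberrant collections stay visible.
    """
    if rec.fecal_ge_mj > rec.ge_intake_mj:
        warnings.warn(
            f"{rec.pig_id}/p{rec.period} ({rec.diet_id}): fecal GE exceeds "
            "GE intake; negative digestibility",
            stacklevel=2,
        )
    de_d = (rec.ge_intake_mj - rec.fecal_ge_mj) / rec.feed_intake_kg_dm
    me_d = (
        rec.ge_intake_mj - rec.fecal_ge_mj - rec.urine_ge_mj
    ) / rec.feed_intake_kg_dm
    return DietEnergy(diet_id=rec.diet_id, de_d=de_d, me_d=me_d)


def correct_basal(
    e: DietEnergy, energy_fraction: float = DEFAULT_ENERGY_FRACTION
) -> CorrectedBasalEnergy:
    """Rescale basal-diet DE/ME to the energy-supplying ingredient fraction."""
    if not 0.0 < energy_fraction <= 1.0:
        raise ConfigError(
            f"energy_fraction must be in (0, 1], got {energy_fraction}"
        )
    return CorrectedBasalEnergy(
        de_dc=e.de_d / energy_fraction,
        me_dc=e.me_d / energy_fraction,
        energy_fraction=energy_fraction,
    )


def ingredient_energy_by_difference(
    test: DietEnergy,
    basal: CorrectedBasalEnergy,
    x: float = DEFAULT_SUBSTITUTION_X,
    ingredient_id: str | None = None,
) -> IngredientEnergy:
    """Ingredient DE/ME by the difference method at substitution fraction ``x``."""
    if not 0.0 < x < 1.0:
        raise InvalidSubstitutionError(f"X must be in (0, 1), got {x}")
    de = (test.de_d - basal.de_dc * (1.0 - x)) / x
    me = (test.me_d - basal.me_dc * (1.0 - x)) / x
    return IngredientEnergy(
        ingredient_id=ingredient_id if ingredient_id is not None else test.diet_id,
        de=de,
        me=me,
        substitution_x=x,
    )


def estimate_ingredient_energies(
    records: Sequence[BalanceRecord],
    basal_diet_id: str,
    *,
    x: float = DEFAULT_SUBSTITUTION_X,
    energy_fraction: float = DEFAULT_ENERGY_FRACTION,
    basal_by_period: bool = False,
) -> pd.DataFrame:
    """Per-observation ingredient DE/ME from a full balance trial.

    Diet energy is computed per pig-period observation; the corrected basal
    energy is the mean over all basal-diet observations (optionally computed
    within each period); each test-diet observation then yields one
    ingredient-energy estimate.  Returns one row per test observation with
    columns ``pig_id, period, diet_id, de_d, me_d, de, me``.
    """
    rows = []
    for rec in records:
        e = diet_energy(rec)
        rows.append(
            {"pig_id": rec.pig_id, "period": rec.period, "diet_id": rec.diet_id,
             "de_d": e.de_d, "me_d": e.me_d}
        )
    df = pd.DataFrame(rows)
    basal_obs = df[df["diet_id"] == basal_diet_id]
    if basal_obs.empty:
        raise MissingTreatmentError(
            f"no observations for basal diet {basal_diet_id!r}"
        )
    test = df[df["diet_id"] != basal_diet_id].copy()

    def _basal_for(period: int) -> CorrectedBasalEnergy:
        pool = basal_obs[basal_obs["period"] == period] if basal_by_period else basal_obs
        if pool.empty:
            raise MissingTreatmentError(
                f"no basal-diet observations in period {period}"
            )
        e = DietEnergy(basal_diet_id, pool["de_d"].mean(), pool["me_d"].mean())
        return correct_basal(e, energy_fraction)

    de, me = [], []
    for _, row in test.iterrows():
        basal = _basal_for(int(row["period"]))
        ing = ingredient_energy_by_difference(
            DietEnergy(row["diet_id"], row["de_d"], row["me_d"]), basal, x
        )
        de.append(ing.de)
        me.append(ing.me)
    test["de"] = de
    test["me"] = me
    return test.reset_index(drop=True)


def treatment_energy_summary(
    observations: pd.DataFrame,
    value_cols: Sequence[str] = ("de", "me"),
    group_col: str = "diet_id",
) -> pd.DataFrame:
    """Per-diet means with a pooled standard error of the mean.

    SEM uses the pooled residual standard deviation across diets divided by
    the square root of the replicate count per diet (the crossover design's
    nominal replication); multiple-comparison letter groupings are out of
    scope here.
    """
    if observations.empty:
        raise MissingTreatmentError("no observations to summarize")
    groups = observations.groupby(group_col)
    out = groups[list(value_cols)].mean()
    for col in value_cols:
        resid = observations[col] - groups[col].transform("mean")
        df_resid = len(observations) - groups.ngroups
        pooled_sd = (
            np.sqrt((resid**2).sum() / df_resid) if df_resid > 0 else 0.0
        )
        n_rep = groups.size()
        out[f"{col}_sem"] = pooled_sd / np.sqrt(n_rep)
    return out


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

_BALANCE_COLUMNS = [
    "pig_id", "period", "diet_id",
    "feed_intake_kg_dm", "ge_intake_mj", "fecal_ge_mj", "urine_ge_mj",
]


def read_balance_csv(path_or_buf) -> list[BalanceRecord]:
    df = read_csv_clean(path_or_buf)
    return [
        BalanceRecord(
            pig_id=str(r.pig_id), period=int(r.period), diet_id=str(r.diet_id),
            feed_intake_kg_dm=float(r.feed_intake_kg_dm),
            ge_intake_mj=float(r.ge_intake_mj),
            fecal_ge_mj=float(r.fecal_ge_mj),
            urine_ge_mj=float(r.urine_ge_mj),
        )
        for r in df.itertuples()
    ]


def write_balance_csv(records: Iterable[BalanceRecord], path) -> None:
    pd.DataFrame(
        [{c: getattr(r, c) for c in _BALANCE_COLUMNS} for r in records]
    ).to_csv(path, index=False)
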