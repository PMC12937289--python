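"""Apparent and standardized ileal amino-acid digestibility.

Digestibility at the terminal ileum is measured with an indigestible marker
(here titanium dioxide, TiO2, included at 0.20% of the diet).  Because the
marker is not absorbed, its concentration rise between diet and digesta
quantifies dry-matter disappearance, and for each amino acid (AA)

    AID% = [1 - (AA1/AA2) * (IM2/IM1)] * 100

where AA1/IM1 are AA/marker concentrations in ileal digesta and AA2/IM2 in
the diet (all mg/kg DM).  Apparent digestibility is biased downward by
endogenous AA secretions; the basal endogenous loss, measured by feeding a
nitrogen-free diet, is

    IAA (g/kg DM intake) = AA3 * (IM4/IM3) / 1000

and standardized ileal digestibility corrects AID upward:

    SID% = AID% + 100 * IAA / AA2      (AA2 in g/kg DM)

SID above 100% is legal and occurs in practice for proline, whose
endogenous secretion is stimulated by the nitrogen-free diet itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .composition import canonical_analyte
from ._text import read_csv_clean
from .exceptions import (
    MarkerRecoveryError,
    SchemaError,
    UndefinedDigestibilityError,
)

__all__ = [
    "DigestaRecord",
    "DietAminoProfile",
    "EndogenousLossTable",
    "apparent_ileal_digestibility",
    "basal_endogenous_loss",
    "standardized_ileal_digestibility",
    "digestibility_table",
    "diet_profile_from_percent",
    "read_digesta_csv",
    "write_digesta_csv",
]

TOTAL_AA = "TAA"


@dataclass(frozen=True)
class DigestaRecord:
    """One pig-period ileal-digesta observation (concentrations in mg/kg DM)."""

    pig_id: str
    period: int
    diet_id: str
    marker_mg_per_kg: float
    aa_mg_per_kg: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.marker_mg_per_kg <= 0:
            raise MarkerRecoveryError(
                f"{self.pig_id}/p{self.period}: digesta marker must be > 0"
            )
        clean = {}
        for name, v in self.aa_mg_per_kg.items():
            if v < 0:
                raise SchemaError(f"negative AA concentration for {name!r}")
            clean[canonical_analyte(name)] = float(v)
        object.__setattr__(self, "aa_mg_per_kg", clean)


@dataclass(frozen=True)
class DietAminoProfile:
    """Diet AA and marker concentrations (mg/kg DM)."""

    diet_id: str
    marker_mg_per_kg: float
    aa_mg_per_kg: Mapping[str, float] = field(default_factory=dict)
    is_nitrogen_free: bool = False

    def __post_init__(self) -> None:
        if self.marker_mg_per_kg <= 0:
            raise MarkerRecoveryError(f"{self.diet_id}: diet marker must be > 0")
        object.__setattr__(
            self,
            "aa_mg_per_kg",
            {canonical_analyte(k): float(v) for k, v in self.aa_mg_per_kg.items()},
        )


@dataclass(frozen=True)
class EndogenousLossTable:
    """Basal ileal endogenous AA losses, g per kg of dry-matter intake.

    ``scale_factor`` rescales every entry on use; the default 1.0 applies
    the table verbatim.
    """

    iaa_g_per_kg_dmi: Mapping[str, float]
    source: str = ""
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        clean = {}
        for k, v in self.iaa_g_per_kg_dmi.items():
            if v < 0:
                raise SchemaError(f"negative endogenous loss for {k!r}")
            clean[canonical_analyte(k)] = float(v)
        object.__setattr__(self, "iaa_g_per_kg_dmi", clean)

    def loss(self, aa: str) -> float:
        return self.iaa_g_per_kg_dmi[canonical_analyte(aa)] * self.scale_factor


def apparent_ileal_digestibility(
    aa1: float, aa2: float, im1: float, im2: float
) -> float:
    """AID% of one amino acid from digesta/diet concentration ratios.

    May be negative (endogenous secretion exceeding disappearance is not
    clipped); exactly 100 when the digesta concentration is zero.
    """
    if aa2 <= 0:
        raise UndefinedDigestibilityError("diet AA concentration must be > 0")
    if im1 <= 0 or im2 <= 0:
        raise MarkerRecoveryError("marker concentrations must be > 0")
    aid = 100.0 * (1.0 - (aa1 / aa2) * (im2 / im1))
    if aid < 0:
        warnings.warn(f"negative apparent ileal digestibility ({aid:.1f}%)",
                      stacklevel=2)
    return aid


def basal_endogenous_loss(aa3: float, im3: float, im4: float) -> float:
    """Basal endogenous AA loss (g/kg DMI) from nitrogen-free-diet digesta.

    ``aa3``/``im3`` are AA/marker concentrations (mg/kg DM) in digesta from
    the nitrogen-free diet, ``im4`` the marker concentration in that diet.
    """
    if im3 <= 0:
        raise MarkerRecoveryError("digesta marker concentration must be > 0")
    return aa3 * (im4 / im3) / 1000.0


def standardized_ileal_digestibility(
    aid_pct: float, iaa_g_per_kg_dmi: float, aa2_g_per_kg: float
) -> float:
    """SID% = AID% + 100 * IAA / AA2, with AA2 in g/kg DM.

    Values above 100% are legal and are not clipped.
    """
    if aa2_g_per_kg <= 0:
        raise UndefinedDigestibilityError("diet AA concentration must be > 0")
    if iaa_g_per_kg_dmi < 0:
        raise SchemaError("endogenous loss must be >= 0")
    return aid_pct + 100.0 * iaa_g_per_kg_dmi / aa2_g_per_kg


def diet_profile_from_percent(
    diet_id: str,
    aa_pct_as_fed: Mapping[str, float],
    dm_pct: float,
    marker_mg_per_kg_dm: float,
    *,
    is_nitrogen_free: bool = False,
) -> DietAminoProfile:
    """Build a DM-basis diet profile from as-fed AA percentages.

    Converts percent as-fed -> mg/kg DM via ``pct * 10_000 * 100 / DM``.
    """
    factor = 10_000.0 * 100.0 / dm_pct
    return DietAminoProfile(
        diet_id=diet_id,
        marker_mg_per_kg=marker_mg_per_kg_dm,
        aa_mg_per_kg={k: v * factor for k, v in aa_pct_as_fed.items()},
        is_nitrogen_free=is_nitrogen_free,
    )


def digestibility_table(
    digesta: Sequence[DigestaRecord],
    diets: Sequence[DietAminoProfile],
    endo: EndogenousLossTable,
    amino_acids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-diet mean AID/SID for each amino acid, plus grand means.

    AID and SID are computed per pig-period observation and averaged by
    diet; nitrogen-free-diet observations are excluded from the treatment
    table (they exist to measure endogenous losses).  The total-AA row uses
    total-AA concentrations, not an average of the per-AA rows.  The grand
    mean row (diet label ``"mean"``) is the unweighted mean of the per-diet
    means.

    Returns a long-format frame with columns
    ``diet_id, amino_acid, aid_pct, sid_pct``.
    """
    profiles = {d.diet_id: d for d in diets}
    rows = []
    for rec in digesta:
        if rec.diet_id not in profiles:
            raise SchemaError(f"no diet profile for {rec.diet_id!r}")
        prof = profiles[rec.diet_id]
        if prof.is_nitrogen_free:
            continue
        names = amino_acids or list(rec.aa_mg_per_kg)
        for aa in names:
            aa = canonical_analyte(aa)
            if aa not in prof.aa_mg_per_kg:
                raise SchemaError(
                    f"amino acid {aa!r} missing from diet profile {prof.diet_id!r}"
                )
            aa1 = rec.aa_mg_per_kg[aa]
            aa2 = prof.aa_mg_per_kg[aa]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aid = apparent_ileal_digestibility(
                    aa1, aa2, rec.marker_mg_per_kg, prof.marker_mg_per_kg
                )
            sid = standardized_ileal_digestibility(
                aid, endo.loss(aa), aa2 / 1000.0
            )
            rows.append(
                {"diet_id": rec.diet_id, "amino_acid": aa,
                 "aid_pct": aid, "sid_pct": sid}
            )
    obs = pd.DataFrame(rows)
    per_diet = (
        obs.groupby(["diet_id", "amino_acid"], sort=False)[["aid_pct", "sid_pct"]]
        .mean()
        .reset_index()
    )
    grand = (
        per_diet.groupby("amino_acid", sort=False)[["aid_pct", "sid_pct"]]
        .mean()
        .reset_index()
    )
    grand.insert(0, "diet_id", "mean")
    return pd.concat([per_diet, grand], ignore_index=True)


# ---------------------------------------------------------------------------
# CSV interface: wide rows, one per pig-period, marker column plus one
# column per amino acid (mg/kg DM).
# ---------------------------------------------------------------------------

def read_digesta_csv(path_or_buf) -> list[DigestaRecord]:
    df = read_csv_clean(path_or_buf)
    reserved = {"pig_id", "period", "diet_id", "marker_mg_per_kg"}
    aa_cols = [c for c in df.columns if c not in reserved]
    return [
        DigestaRecord(
            pig_id=str(row["pig_id"]), period=int(row["period"]),
            diet_id=str(row["diet_id"]),
            marker_mg_per_kg=float(row["marker_mg_per_kg"]),
            aa_mg_per_kg={c: float(row[c]) for c in aa_cols},
        )
        for _, row in df.iterrows()
    ]


def write_digesta_csv(records: Iterable[DigestaRecord], path) -> None:
    pd.DataFrame(
        [
            {"pig_id": r.pig_id, "period": r.period, "diet_id": r.diet_id,
             "marker_mg_per_kg": r.marker_mg_per_kg, **r.aa_mg_per_kg}
            for r in records
        ]
    ).to_csv(path, index=False)
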