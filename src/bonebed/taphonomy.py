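"""NISP/MNI and taphonomic accounting with explicit denominator conventions.

The profile reproduces the standard zooarchaeological summary tables for a
bonebed assemblage:

* NISP (Number of Identified Specimens) per taxon, as a percentage of the
  trophic group (herbivores and carnivores each against their own total)
  and of all macrovertebrates;
* MNI (Minimum Number of Individuals) from element laterality and
  ontogenetic age, with mortality profiles (senile/adult/juvenile/infantile
  and the "% not adult" column);
* fragmentation (maximum-length classes over all specimens; green vs dry
  fracture over fractured long bones; shaft-circumference types over
  green-fractured long bones only);
* surface state and biogenic modification frequencies, each with its own
  denominator: weathering, abrasion and diagenetic stains against all
  specimens; poor preservation against specimens excluding teeth; carnivore
  tooth marks against well-preserved non-dental specimens; tooth-mark
  typology, furrowing, taphotypes and notches against their own totals.

All percentages are printed to one decimal with round-half-up; counts stay
exact integers.  Every computation is a pure function of the table: row
order never matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .specimens import (
    AGE_CLASSES,
    LONG_BONE_ELEMENTS,
    NOTCH_TYPES,
    LENGTH_CLASSES,
    SpecimenTable,
    taxon_vocabulary,
)

__all__ = [
    "pct",
    "compute_nisp",
    "compute_mni",
    "mortality_profile",
    "fragmentation_profile",
    "surface_modification_profile",
    "toothmark_by_size_class",
    "TaphonomicProfile",
    "compute_profile",
]


def pct(num: float, den: float, decimals: int = 1) -> float:
    """Percentage ``100*num/den`` rounded half-up to ``decimals`` places.

    Returns NaN for a zero denominator (an undefined percentage is reported
    as missing, never as 0).
    """
    if den == 0:
        return math.nan
    q = Decimal(1).scaleb(-decimals)
    val = Decimal(str(num)) * 100 / Decimal(str(den))
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


def _df(table: SpecimenTable | pd.DataFrame) -> pd.DataFrame:
    return table.df if isinstance(table, SpecimenTable) else table


def _long_bone_mask(df: pd.DataFrame) -> pd.Series:
    return df["element"].isin(LONG_BONE_ELEMENTS)


def _marked_mask(df: pd.DataFrame) -> pd.Series:
    return (df[["tm_pits", "tm_scores", "tm_punctures"]].sum(axis=1) > 0) & ~df[
        "is_tooth"
    ]


# ---------------------------------------------------------------------------
# NISP
# ---------------------------------------------------------------------------


def compute_nisp(table: SpecimenTable, group: str = "taxon") -> pd.DataFrame:
    """Specimen counts per ``group`` (taxon, size_class or element).

    For taxon grouping, ``pct_trophic`` is the share within the record's
    trophic group (herbivore NISP over total herbivore NISP, likewise for
    carnivores; missing for the minor groups) and ``pct_total`` the share
    of all macrovertebrates.
    """
    df = _df(table)
    if df.empty:
        return pd.DataFrame(columns=[group, "trophic_group", "nisp", "pct_trophic", "pct_total"])
    counts = (
        df.groupby([group, "trophic_group"], sort=False, observed=True)
        .size()
        .reset_index(name="nisp")
    )
    total = len(df)
    troph_totals = df.groupby("trophic_group").size()
    out = []
    for _, row in counts.iterrows():
        tg = row["trophic_group"]
        p_tg = (
            pct(row["nisp"], troph_totals[tg]) if tg in ("herbivore", "carnivore") else math.nan
        )
        out.append(
            {
                group: row[group],
                "trophic_group": tg,
                "nisp": int(row["nisp"]),
                "pct_trophic": p_tg,
                "pct_total": pct(row["nisp"], total),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# MNI
# ---------------------------------------------------------------------------


def _mni_for_element(sub: pd.DataFrame) -> int:
    left = int((sub["side"] == "left").sum())
    right = int((sub["side"] == "right").sum())
    unsided = len(sub) - left - right
    return max(left, right, math.ceil(unsided / 2))


def compute_mni(table: SpecimenTable) -> pd.DataFrame:
    """Minimum number of individuals per taxon.

    Within each taxon the records are partitioned by ontogenetic age class
    (unknown age forms its own class); within an age class each skeletal
    element contributes ``max(n_left, n_right, ceil(n_unsided / 2))`` and
    the class MNI is the maximum over elements.  The taxon MNI is the sum
    over age classes — individuals of different ages cannot be the same
    animal.  Deterministic and monotone: adding a record never decreases
    any MNI.
    """
    df = _df(table)
    cols = ["mni", *AGE_CLASSES]
    if df.empty:
        return pd.DataFrame(columns=cols)
    rows = {}
    for taxon, sub in df.groupby("taxon", sort=False):
        per_age = {}
        for age, asub in sub.groupby("age_class", sort=False):
            per_age[age] = max(
                (_mni_for_element(esub) for _, esub in asub.groupby("element", sort=False)),
                default=0,
            )
        rec = {a: per_age.get(a, 0) for a in AGE_CLASSES}
        rec["mni"] = sum(rec.values())
        rows[taxon] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")[cols]
    out.index.name = "taxon"
    return out


def mortality_profile(table: SpecimenTable | pd.DataFrame) -> pd.DataFrame:
    """Per-taxon mortality structure from the MNI age partition.

    Columns: senile/adult/juvenile/infantile individual counts, total MNI,
    and ``pct_not_adult`` = 100*(juvenile+infantile)/MNI to one decimal
    (missing when MNI is zero).  Taxa too indeterminate for an individual
    count (per the faunal-list vocabulary) are excluded.
    """
    mni = (
        table
        if isinstance(table, pd.DataFrame) and "mni" in getattr(table, "columns", [])
        else compute_mni(table)
    )
    vocab = taxon_vocabulary()
    eligible = [
        t
        for t in mni.index
        if t not in vocab.index or vocab.loc[t, "mni_eligible"]
    ]
    mni = mni.loc[eligible]
    out = mni[["senile", "adult", "juvenile", "infantile", "mni"]].copy()
    out["pct_not_adult"] = [
        pct(r["juvenile"] + r["infantile"], r["mni"]) if r["mni"] > 0 else math.nan
        for _, r in mni.iterrows()
    ]
    return out


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------


def fragmentation_profile(table: SpecimenTable) -> dict[str, pd.DataFrame]:
    """Length-class, fracture-state and shaft-circumference accounting.

    Length classes are counted over every specimen.  Green/dry percentages
    are taken over long bones with a recorded fracture.  Circumference
    types (1: <25%, 2: 25-50%, 3: >50% of the shaft circumference) are
    taken over green-fractured long bones only.
    """
    df = _df(table)
    n = len(df)
    length = pd.DataFrame(
        {
            "length_class": LENGTH_CLASSES,
            "count": [int((df["length_class"] == c).sum()) for c in LENGTH_CLASSES],
        }
    )
    length["pct_total"] = [pct(c, n) for c in length["count"]]

    lb = df[_long_bone_mask(df)]
    fractured = lb[lb["fracture_type"].isin(["green", "dry"])]
    nfrac = len(fractured)
    fracture = pd.DataFrame(
        {
            "fracture_type": ["green", "dry"],
            "count": [
                int((fractured["fracture_type"] == t).sum()) for t in ("green", "dry")
            ],
        }
    )
    fracture["pct_fractured_long_bones"] = [pct(c, nfrac) for c in fracture["count"]]

    green = fractured[fractured["fracture_type"] == "green"]
    ngreen = len(green)
    circumference = pd.DataFrame(
        {
            "circumference_type": ["1", "2", "3"],
            "description": ["<25%", "25-50%", ">50%"],
            "count": [
                int((green["circumference_type"] == t).sum()) for t in ("1", "2", "3")
            ],
        }
    )
    circumference["pct_green_long_bones"] = [pct(c, ngreen) for c in circumference["count"]]
    return {"length": length, "fracture": fracture, "circumference": circumference}


# ---------------------------------------------------------------------------
# Surface state / biogenic modification
# ---------------------------------------------------------------------------


def surface_modification_profile(table: SpecimenTable) -> dict:
    """Surface-state and modification frequencies with their conventional
    denominators (see module docstring)."""
    df = _df(table)
    n = len(df)
    non_teeth = df[~df["is_tooth"]]
    n_nt = len(non_teeth)
    badly = int((non_teeth["surface_preservation"] == "poor").sum())
    well_nt = non_teeth[non_teeth["surface_preservation"] == "good"]
    n_well = len(well_nt)

    weath_12 = int(df["weathering_stage"].isin([1, 2]).sum())
    abraded = df[df["abrasion_stage"] != "none"]
    n_abr = len(abraded)

    marked = df[_marked_mask(df)]
    n_marked = len(marked)
    pits = marked["tm_pits"] > 0
    scores = marked["tm_scores"] > 0
    punct = marked["tm_punctures"] > 0
    lb_mask = _long_bone_mask(df)
    n_lb = int(lb_mask.sum())
    furrow_total = int(df["furrowing"].sum())
    furrow_lb = int((df["furrowing"] & lb_mask).sum())

    tapho = df[df["taphotype"].notna() & lb_mask]
    tapho_counts = (
        tapho.groupby(tapho["taphotype"].astype(int)).size().rename("count").reset_index()
    )
    tapho_counts["pct"] = [pct(c, len(tapho)) for c in tapho_counts["count"]]

    notches = df[df["notch_type"] != "none"]
    notch_counts = pd.DataFrame(
        {
            "notch_type": [t for t in NOTCH_TYPES if t != "none"],
            "count": [
                int((notches["notch_type"] == t).sum()) for t in NOTCH_TYPES if t != "none"
            ],
        }
    )
    notch_counts["pct"] = [pct(c, len(notches)) for c in notch_counts["count"]]

    return {
        "n_total": n,
        "n_excluding_teeth": n_nt,
        "badly_preserved": {"count": badly, "pct_excluding_teeth": pct(badly, n_nt)},
        "weathering_stage_1_2": {"count": weath_12, "pct_total": pct(weath_12, n)},
        "abrasion": {
            "count": n_abr,
            "pct_total": pct(n_abr, n),
            "stages": {
                stage: {
                    "count": int((abraded["abrasion_stage"] == stage).sum()),
                    "pct_abraded": pct(int((abraded["abrasion_stage"] == stage).sum()), n_abr),
                }
                for stage in ("light", "intermediate", "intense")
            },
        },
        "calcitic_concretion": {
            "count": int(df["calcitic_concretion"].sum()),
            "pct_total": pct(int(df["calcitic_concretion"].sum()), n),
        },
        "oxide_staining": {
            "count": int(df["oxide_staining"].sum()),
            "pct_total": pct(int(df["oxide_staining"].sum()), n),
        },
        "biochemical_alteration": {
            "count": int(df["biochemical_alteration"].sum()),
            "pct_total": pct(int(df["biochemical_alteration"].sum()), n),
        },
        "tooth_marks": {
            "denominator_well_preserved_non_teeth": n_well,
            "marked_bones": {"count": n_marked, "pct_well_preserved": pct(n_marked, n_well)},
            "pits_only": {
                "count": int((pits & ~scores & ~punct).sum()),
                "pct_marked": pct(int((pits & ~scores & ~punct).sum()), n_marked),
            },
            "scores_only": {
                "count": int((scores & ~pits & ~punct).sum()),
                "pct_marked": pct(int((scores & ~pits & ~punct).sum()), n_marked),
            },
            "pits_and_scores": {
                "count": int((pits & scores).sum()),
                "pct_marked": pct(int((pits & scores).sum()), n_marked),
            },
            "punctures_only": {
                "count": int((punct & ~pits & ~scores).sum()),
                "pct_marked": pct(int((punct & ~pits & ~scores).sum()), n_marked),
            },
            "furrowing": {
                "count": furrow_total,
                "pct_marked": pct(furrow_total, n_marked),
            },
            "long_bone_furrowing": {
                "count": furrow_lb,
                "pct_long_bones": pct(furrow_lb, n_lb),
            },
        },
        "taphotypes": tapho_counts,
        "notches": notch_counts,
    }


def toothmark_by_size_class(table: SpecimenTable) -> pd.DataFrame:
    """Cross-tabulation of tooth-marked bones: skeletal element by the
    specimen's size class (anatomical distribution of carnivore damage)."""
    df = _df(table)
    marked = df[_marked_mask(df)].copy()
    if marked.empty:
        return pd.DataFrame()
    marked["size_class"] = marked["size_class"].replace("", "indet")
    tab = pd.crosstab(marked["element"], marked["size_class"])
    tab.loc["total"] = tab.sum(axis=0)
    return tab


# ---------------------------------------------------------------------------
# Aggregate
# ---------------------------------------------------------------------------


@dataclass
class TaphonomicProfile:
    """The full quantitative accounting of an assemblage."""

    nisp: pd.DataFrame
    mni: pd.DataFrame
    mortality: pd.DataFrame
    fragmentation: dict[str, pd.DataFrame]
    surface: dict
    toothmarks_by_size: pd.DataFrame

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, pd.DataFrame):
                return obj.reset_index().to_dict(orient="records")
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        return {
            "nisp": conv(self.nisp),
            "mni": conv(self.mni),
            "mortality": conv(self.mortality),
            "fragmentation": conv(self.fragmentation),
            "surface": conv(self.surface),
            "toothmarks_by_size": conv(self.toothmarks_by_size),
        }


def compute_profile(table: SpecimenTable) -> TaphonomicProfile:
    """Compute every summary table for one assemblage."""
    mni = compute_mni(table)
    return TaphonomicProfile(
        nisp=compute_nisp(table),
        mni=mni,
        mortality=mortality_profile(mni),
        fragmentation=fragmentation_profile(table),
        surface=surface_modification_profile(table),
        toothmarks_by_size=toothmark_by_size_class(table),
    )
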