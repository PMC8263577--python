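"""Domain types, specimen-table I/O and the classification maps.

A *specimen* is one catalogued fossil find: planar site-grid coordinates
(x, y in metres), stratigraphic height above the site datum (z in cm,
increasing upward), taxonomic and anatomical identification, and the coded
taphonomic observations (fragmentation, fracture state, weathering,
abrasion, carnivore tooth marks, taphotypes, notches) that the profiling
module aggregates.  Everything downstream — level detection, point-pattern
statistics, fabric statistics, NISP/MNI accounting — consumes the table
defined here.

Controlled vocabularies (skeletal elements with their anatomical region and
limb portion, and the site faunal list with trophic group and body-size
class) ship as editable tab-separated files under ``bonebed/data``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenRecord",
    "SpecimenTable",
    "SIZE_CLASS_MAP",
    "CARNIVORE_SIZE_CLASS_MAP",
    "LENGTH_CLASSES",
    "LONG_BONE_ELEMENTS",
    "element_vocabulary",
    "taxon_vocabulary",
    "assign_size_class",
    "assign_skeletal_region",
    "derive_length_class",
    "read_specimen_table",
    "write_specimen_table",
]

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

SIDES = ("left", "right", "axial", "unknown")
AGE_CLASSES = ("infantile", "juvenile", "adult", "senile", "unknown")
FRACTURE_TYPES = ("green", "dry", "none")
CIRCUMFERENCE_TYPES = ("1", "2", "3", "n/a")
ABRASION_STAGES = ("none", "light", "intermediate", "intense")
PRESERVATION = ("good", "poor")
TROPHIC_GROUPS = ("herbivore", "carnivore", "other")
NOTCH_TYPES = (
    "single",
    "opposing",
    "incomplete A",
    "incomplete B",
    "incomplete C",
    "double",
    "double opposing",
    "pseudonotch",
    "micronotch",
    "multiple",
    "none",
)
LENGTH_CLASSES = ("<3 cm", "3.1-5 cm", "5.1-10 cm", ">10 cm")

REGIONS = (
    "cranial",
    "axial",
    "upper appendicular",
    "intermediate appendicular",
    "lower appendicular",
    "unclassified",
)


def _load_vocab(name: str) -> pd.DataFrame:
    with resources.files("bonebed.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


_ELEMENTS: pd.DataFrame | None = None
_TAXA: pd.DataFrame | None = None


def element_vocabulary() -> pd.DataFrame:
    """Skeletal-element vocabulary (region, limb portion, long-bone and
    paired flags), indexed by element code."""
    global _ELEMENTS
    if _ELEMENTS is None:
        df = _load_vocab("elements.tsv")
        df["is_long_bone"] = df["is_long_bone"].astype(int).astype(bool)
        df["paired"] = df["paired"].astype(int).astype(bool)
        _ELEMENTS = df.set_index("element")
    return _ELEMENTS


def taxon_vocabulary() -> pd.DataFrame:
    """Site faunal list: trophic group, body-size class, and whether the
    taxon is determinate enough for an MNI estimate."""
    global _TAXA
    if _TAXA is None:
        df = _load_vocab("taxa.tsv")
        df["mni_eligible"] = df["mni_eligible"].astype(int).astype(bool)
        _TAXA = df.set_index("taxon")
    return _TAXA


LONG_BONE_ELEMENTS = (
    "humerus",
    "radius",
    "ulna",
    "femur",
    "tibia",
    "metacarpal",
    "metatarsal",
    "metapodial",
    "long_bone",
)

# ---------------------------------------------------------------------------
# Size classes
# ---------------------------------------------------------------------------

#: Herbivore body-mass intervals (kg) -> size-class label.  Intervals are
#: half-open [lower, upper) so shared printed boundaries are unambiguous;
#: class "3" is the union of "3a" and "3b".
SIZE_CLASS_MAP: tuple[tuple[float, float, str], ...] = (
    (0.0, 25.0, "0"),
    (25.0, 50.0, "1"),
    (50.0, 125.0, "2"),
    (125.0, 250.0, "3a"),
    (250.0, 500.0, "3b"),
    (500.0, 1000.0, "4"),
    (1000.0, math.inf, "5"),
)

#: Carnivore exemplar classes: small (fox-sized), intermediate (wolf-sized),
#: large (lion-sized and above).  Cut points are conventional.
CARNIVORE_SIZE_CLASS_MAP: tuple[tuple[float, float, str], ...] = (
    (0.0, 20.0, "small"),
    (20.0, 120.0, "intermediate"),
    (120.0, math.inf, "large"),
)


def assign_size_class(mass_kg: float, trophic_group: str = "herbivore") -> str:
    """Map a body mass (kg) to the weight/size class used in skeletal-part
    accounting.

    Herbivores (and the minor non-carnivore groups) use the seven-class
    scheme 0/1/2/3a/3b/4/5; carnivores use small/intermediate/large.
    Intervals are half-open ``[lower, upper)``.
    """
    if not (mass_kg > 0):
        raise ValueError(f"mass must be positive, got {mass_kg!r}")
    table = (
        CARNIVORE_SIZE_CLASS_MAP if trophic_group == "carnivore" else SIZE_CLASS_MAP
    )
    for lo, hi, label in table:
        if lo <= mass_kg < hi:
            return label
    raise AssertionError("size-class intervals do not partition (0, inf)")


def assign_skeletal_region(element: str) -> tuple[str, str]:
    """Return ``(anatomical region, limb portion)`` for an element code.

    Regions: cranial / axial / upper appendicular / intermediate
    appendicular / lower appendicular.  Limb portion is anterior
    (scapula, humerus, radius, ulna, carpals, metacarpals), posterior
    (pelvis, femur, tibia, patella, tarsals, metatarsals) or n/a.
    Unknown elements are reported as ``("unclassified", "n/a")`` with a
    warning, never dropped.
    """
    vocab = element_vocabulary()
    if element not in vocab.index:
        warnings.warn(f"unknown skeletal element {element!r}; left unclassified")
        return ("unclassified", "n/a")
    row = vocab.loc[element]
    return (row["region"], row["limb_portion"])


def derive_length_class(length_cm: float) -> str:
    """Four-way maximum-length category: <3 cm / 3.1-5 cm / 5.1-10 cm /
    >10 cm.  Lengths are recorded to 0.1 cm; exactly 3.0 (5.0, 10.0) falls
    in the lower class, closing the printed gaps.
    """
    if not (length_cm > 0):
        raise ValueError(f"length must be positive, got {length_cm!r}")
    if length_cm <= 3.0:
        return LENGTH_CLASSES[0]
    if length_cm <= 5.0:
        return LENGTH_CLASSES[1]
    if length_cm <= 10.0:
        return LENGTH_CLASSES[2]
    return LENGTH_CLASSES[3]


# ---------------------------------------------------------------------------
# Specimen record / table
# ---------------------------------------------------------------------------


@dataclass
class SpecimenRecord:
    """One catalogued fossil specimen with coordinates, identifications and
    taphonomic codes.  ``None``/NaN marks a missing value; categorical
    fields use the sentinel noted in their default."""

    specimen_id: str
    x: float | None = None
    y: float | None = None
    z: float | None = None
    taxon: str = "indet"
    trophic_group: str = "other"
    element: str = "indeterminate"
    side: str = "unknown"
    size_class: str = ""
    age_class: str = "unknown"
    length_cm: float | None = None
    length_class: str = ""
    fracture_type: str = "none"
    circumference_type: str = "n/a"
    weathering_stage: int = 0
    surface_preservation: str = "good"
    abrasion_stage: str = "none"
    oxide_staining: bool = False
    calcitic_concretion: bool = False
    biochemical_alteration: bool = False
    tm_pits: int = 0
    tm_scores: int = 0
    tm_punctures: int = 0
    furrowing: bool = False
    taphotype: int | None = None
    notch_type: str = "none"
    is_tooth: bool = False
    trend_deg: float | None = None
    plunge_deg: float | None = None
    level: str = ""

    @property
    def tooth_marks(self) -> dict[str, int]:
        return {"pit": self.tm_pits, "score": self.tm_scores, "puncture": self.tm_punctures}


_FLOAT_COLS = ("x", "y", "z", "length_cm", "trend_deg", "plunge_deg", "taphotype")
_INT_COLS = ("weathering_stage", "tm_pits", "tm_scores", "tm_punctures")
_BOOL_COLS = (
    "oxide_staining",
    "calcitic_concretion",
    "biochemical_alteration",
    "furrowing",
    "is_tooth",
)
COLUMNS = tuple(f.name for f in dc_fields(SpecimenRecord))
_STR_COLS = tuple(c for c in COLUMNS if c not in _FLOAT_COLS + _INT_COLS + _BOOL_COLS)


class SpecimenTable:
    """Ordered collection of specimens backed by a :class:`pandas.DataFrame`.

    Iteration order is stable and ``specimen_id`` is unique.  ``provenance``
    carries free-text metadata (source file, generator seed).
    """

    def __init__(self, df: pd.DataFrame, provenance: dict | None = None):
        df = df.reset_index(drop=True).copy()
        for col in COLUMNS:
            if col not in df.columns:
                default = getattr(SpecimenRecord("_"), col, None)
                df[col] = default
        df = df[list(COLUMNS) + [c for c in df.columns if c not in COLUMNS]]
        for col in _FLOAT_COLS:
            if df[col].dtype == object:
                # per-element float(): correctly-rounded, unlike to_numeric
                df[col] = df[col].map(_parse_float).astype(float)
            else:
                df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        for col in _INT_COLS:
            df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
        for col in _BOOL_COLS:
            df[col] = df[col].map(_to_bool).astype(bool)
        for col in _STR_COLS:
            df[col] = df[col].fillna("").astype(str)
        dup = df["specimen_id"].duplicated(keep=False)
        if dup.any():
            rows = df.index[dup].tolist()
            ids = sorted(set(df.loc[dup, "specimen_id"]))
            raise ValueError(f"duplicate specimen_id {ids} in rows {rows}")
        self.df = df
        self.provenance = dict(provenance or {})

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[SpecimenRecord], provenance: dict | None = None
    ) -> "SpecimenTable":
        rows = [vars(r).copy() for r in records]
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        return cls(df, provenance)

    @property
    def records(self) -> list[SpecimenRecord]:
        out = []
        for row in self.df[list(COLUMNS)].itertuples(index=False):
            d = dict(zip(COLUMNS, row))
            for col in ("x", "y", "z", "length_cm", "trend_deg", "plunge_deg"):
                if pd.isna(d[col]):
                    d[col] = None
            d["taphotype"] = None if pd.isna(d["taphotype"]) else int(d["taphotype"])
            out.append(SpecimenRecord(**d))
        return out

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.records)

    def equals(self, other: "SpecimenTable") -> bool:
        return self.df[list(COLUMNS)].equals(other.df[list(COLUMNS)])

    # -- validation --------------------------------------------------------
    def validate(self) -> list[str]:
        """Field-level consistency checks; returns one message per violation
        (empty list = clean table)."""
        df, errs = self.df, []
        vocab = element_vocabulary()

        def bad(mask, msg):
            for i in df.index[mask.fillna(False)]:
                errs.append(f"row {i} ({df.at[i, 'specimen_id']}): {msg}")

        bad(~df["side"].isin(SIDES), "side not in vocabulary")
        bad(~df["age_class"].isin(AGE_CLASSES), "age_class not in vocabulary")
        bad(~df["fracture_type"].isin(FRACTURE_TYPES), "bad fracture_type")
        bad(~df["circumference_type"].isin(CIRCUMFERENCE_TYPES), "bad circumference_type")
        bad(~df["abrasion_stage"].isin(ABRASION_STAGES), "bad abrasion_stage")
        bad(~df["surface_preservation"].isin(PRESERVATION), "bad surface_preservation")
        bad(~df["notch_type"].isin(NOTCH_TYPES), "bad notch_type")
        bad(~df["element"].isin(list(vocab.index) + ["unknown"]), "element not in vocabulary")
        bad((df["weathering_stage"] < 0) | (df["weathering_stage"] > 5),
            "weathering stage outside 0-5")
        for col in ("tm_pits", "tm_scores", "tm_punctures"):
            bad(df[col] < 0, f"negative {col}")
        t = df["trend_deg"]
        bad(t.notna() & ((t < 0) | (t >= 360)), "trend out of range [0, 360)")
        p = df["plunge_deg"]
        bad(p.notna() & ((p < 0) | (p > 90)), "plunge out of range [0, 90]")
        has_both = df["length_cm"].notna() & (df["length_class"] != "")
        for i in df.index[has_both]:
            expect = derive_length_class(df.at[i, "length_cm"])
            if df.at[i, "length_class"] != expect:
                errs.append(
                    f"row {i} ({df.at[i, 'specimen_id']}): length_class "
                    f"{df.at[i, 'length_class']!r} inconsistent with length "
                    f"{df.at[i, 'length_cm']} (expected {expect!r})"
                )
        return errs


def _parse_float(v) -> float:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return math.nan
    try:
        return float(v)
    except (TypeError, ValueError):
        return math.nan


def _to_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes", "t")
    if pd.isna(v):
        return False
    return bool(v)


# ---------------------------------------------------------------------------
# I/O — UTF-8 CSV, header row, missing = empty field
# ---------------------------------------------------------------------------


def write_specimen_table(table: SpecimenTable, path: str | Path) -> None:
    """Write a specimen table as UTF-8 CSV (angles in decimal degrees, x/y
    in m, z in cm; missing values as empty fields)."""
    df = table.df[list(COLUMNS)].copy()
    for col in _BOOL_COLS:
        df[col] = df[col].map({True: "true", False: "false"})
    df["taphotype"] = df["taphotype"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    for col in _FLOAT_COLS:
        if col == "taphotype":
            continue
        # repr guarantees an exact binary round trip for doubles
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False, encoding="utf-8")


def read_specimen_table(path: str | Path, dialect: dict | None = None) -> SpecimenTable:
    """Read a specimen CSV.

    Rows failing field validation (out-of-range angles, malformed numbers,
    vocabulary violations) are dropped and reported on the returned table's
    ``errors`` list; a duplicated ``specimen_id`` is a hard failure naming
    both rows.  Unknown columns are preserved.
    """
    kw = dict(dialect or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8", **kw)
    if "specimen_id" not in raw.columns:
        raise ValueError(f"{path}: missing required column 'specimen_id'")
    errors: list[str] = []
    drop: list[int] = []
    for col in _FLOAT_COLS:
        if col not in raw.columns:
            continue
        vals = pd.to_numeric(raw[col].mask(raw[col] == "", np.nan), errors="coerce")
        malformed = vals.isna() & (raw[col] != "")
        for i in raw.index[malformed]:
            errors.append(f"row {i}: malformed {col} value {raw.at[i, col]!r}")
            drop.append(i)
    clean = raw.drop(index=sorted(set(drop))).copy()
    for col in _FLOAT_COLS:
        if col in clean.columns:
            clean[col] = clean[col].mask(clean[col] == "", np.nan)
    table = SpecimenTable(clean, provenance={"source": str(path)})
    row_errors = table.validate()
    if row_errors:
        bad_ids = {msg.split("(")[1].split(")")[0] for msg in row_errors}
        keep = ~table.df["specimen_id"].isin(bad_ids)
        errors.extend(row_errors)
        table = SpecimenTable(table.df[keep], provenance={"source": str(path)})
    table.errors = errors  # type: ignore[attr-defined]
    return table
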