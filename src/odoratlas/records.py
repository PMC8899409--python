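"""Canonical record schema and flat-file I/O.

The in-memory container for a standardized database is a pandas
DataFrame in the flat-file schema (:data:`RECORD_COLUMNS`), one response
measurement per row.  Four data types share the schema:

* ``OR``       — odorant-receptor responses (spikes/s in the empty-neuron
  system, nA in the oocyte expression system),
* ``SSR``      — single-sensillum recordings from native neurons (spikes/s),
* ``EAG``      — electroantennogram responses, normalized to a reference
  odorant (dimensionless),
* ``BEHAVIOR`` — two-choice preference indices in [-1, 1].

Small typed views (:class:`OdorantIdentity`, :class:`Concentration`,
:class:`ResponseRecord`) exist for code that manipulates single
measurements; bulk operations work on the DataFrame directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RangeError

#: Data types a record may carry.
DATA_TYPES = ("OR", "SSR", "EAG", "BEHAVIOR")

#: Measurement techniques.
TECHNIQUES = ("empty_neuron", "oocyte", "ssr_native", "eag", "behavior")

#: Behavioral assay categories.
ASSAY_CATEGORIES = (
    "y_tube", "dual_port", "wind_tunnel", "tip", "landing", "y_maze", "t_maze",
)

BEHAVIORAL_CONTEXTS = ("host_seeking_foraging", "oviposition")

#: Standardized concentration unit kinds (post-conversion).
STANDARD_UNITS = ("vv_fraction", "wv_g_per_ml", "dry_amount_g")

#: Raw-input concentration unit kinds accepted by the standardizer.
RAW_UNITS = STANDARD_UNITS + ("molar", "ppm", "mass_per_area_with_volume")

#: Column order of the flat-file schema (CSV / spreadsheet compatible).
RECORD_COLUMNS = [
    "data_type",
    "species",
    "odorant_canonical",
    "compound_id",
    "concentration_value",
    "concentration_unit",
    "response_value",
    "response_unit",
    "technique",
    "receptor_or_sensillum",
    "assay_category",
    "behavioral_context",
    "age_days_min",
    "age_days_max",
    "sex",
    "study_id",
    "eag_reference",
    "background_subtracted",
]

_TEXT_COLUMNS = [
    "data_type", "species", "odorant_canonical", "concentration_unit",
    "response_unit", "technique", "receptor_or_sensillum", "assay_category",
    "behavioral_context", "sex", "study_id", "eag_reference",
]
_FLOAT_COLUMNS = [
    "concentration_value", "response_value", "age_days_min", "age_days_max",
]


@dataclass(frozen=True)
class OdorantIdentity:
    """One odorant under its canonical name.

    ``synonyms`` always contains the canonical name itself; ``compound_id``
    plays the role of a PubChem CID and may be absent; ``molecular_weight``
    is g/mol and is required for molarity conversions.
    """

    canonical_name: str
    synonyms: frozenset[str] = field(default_factory=frozenset)
    compound_id: int | None = None
    molecular_weight: float | None = None

    def __post_init__(self):
        if not self.canonical_name:
            raise ValueError("canonical_name must be non-empty")
        if self.molecular_weight is not None and not self.molecular_weight > 0:
            raise ValueError("molecular_weight must be positive when present")
        object.__setattr__(
            self, "synonyms", frozenset(self.synonyms) | {self.canonical_name}
        )


@dataclass(frozen=True)
class Concentration:
    """A reported concentration with its unit kind.

    ``aux`` carries ``(area_cm2, volume_ml)`` and is present exactly when
    ``unit_kind == "mass_per_area_with_volume"`` (odorant spread over a
    substrate of known area, then referenced to an application volume).
    """

    value: float
    unit_kind: str
    aux: tuple[float, float] | None = None
    raw_text: str = ""

    def __post_init__(self):
        if self.unit_kind not in RAW_UNITS:
            raise RangeError(f"unknown concentration unit kind {self.unit_kind!r}")
        if self.value < 0:
            raise RangeError(f"concentration value must be >= 0, got {self.value}")
        if (self.aux is not None) != (self.unit_kind == "mass_per_area_with_volume"):
            raise RangeError(
                "aux (area, volume) present iff unit_kind is mass_per_area_with_volume"
            )
        if self.aux is not None and (self.aux[0] <= 0 or self.aux[1] <= 0):
            raise RangeError("area and volume must be positive")

    @property
    def is_dry(self) -> bool:
        return self.unit_kind == "dry_amount_g"


@dataclass
class ResponseRecord:
    """One standardized response measurement (a typed view of a schema row)."""

    data_type: str
    species: str
    odorant: OdorantIdentity
    concentration: Concentration
    response_value: float
    technique: str
    study_id: str
    response_unit: str = ""
    receptor_or_sensillum: str | None = None
    assay_category: str | None = None
    behavioral_context: str | None = None
    age_days: tuple[float, float] | None = None
    sex: str | None = None
    eag_reference: str | None = None
    background_subtracted: bool = False

    def __post_init__(self):
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown data_type {self.data_type!r}")
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if self.data_type == "BEHAVIOR" and not -1 <= self.response_value <= 1:
            raise ValueError("BEHAVIOR response_value must lie in [-1, 1]")
        if self.assay_category is not None and self.data_type != "BEHAVIOR":
            raise ValueError("assay_category is only valid for BEHAVIOR records")
        if self.data_type == "OR" and not self.receptor_or_sensillum:
            raise ValueError("OR records require a receptor")

    def to_row(self) -> dict:
        return {
            "data_type": self.data_type,
            "species": self.species,
            "odorant_canonical": self.odorant.canonical_name,
            "compound_id": self.odorant.compound_id,
            "concentration_value": self.concentration.value,
            "concentration_unit": self.concentration.unit_kind,
            "response_value": self.response_value,
            "response_unit": self.response_unit,
            "technique": self.technique,
            "receptor_or_sensillum": self.receptor_or_sensillum or "",
            "assay_category": self.assay_category or "",
            "behavioral_context": self.behavioral_context or "",
            "age_days_min": self.age_days[0] if self.age_days else np.nan,
            "age_days_max": self.age_days[1] if self.age_days else np.nan,
            "sex": self.sex or "",
            "study_id": self.study_id,
            "eag_reference": self.eag_reference or "",
            "background_subtracted": bool(self.background_subtracted),
        }


def normalize_name(name: str) -> str:
    """Lower-case and collapse internal/leading/trailing whitespace."""
    return " ".join(name.lower().split())


def round_significant(x: float, digits: int = 10) -> float:
    """Round ``x`` to ``digits`` significant decimal digits.

    Applied to every converted numeric output so unit conversions are
    exactly invertible at typical reporting precision.
    """
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - math.floor(math.log10(abs(x))))


def empty_records() -> pd.DataFrame:
    """An empty DataFrame in the flat-file schema with correct dtypes."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in RECORD_COLUMNS})
    return _coerce_dtypes(df)


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for c in _TEXT_COLUMNS:
        df[c] = df[c].fillna("").astype(str)
    for c in _FLOAT_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
    df["compound_id"] = pd.array(
        pd.to_numeric(df["compound_id"], errors="coerce"), dtype="Int64"
    )
    df["background_subtracted"] = (
        df["background_subtracted"]
        .map({True: True, False: False, "True": True, "False": False, "": False})
        .astype(bool)
    )
    return df[RECORD_COLUMNS]


def records_from_list(records: list[ResponseRecord]) -> pd.DataFrame:
    """Assemble typed records into the flat-file schema."""
    if not records:
        return empty_records()
    return _coerce_dtypes(pd.DataFrame([r.to_row() for r in records]))


def write_records(df: pd.DataFrame, path) -> None:
    """Write a record table as UTF-8 CSV with one header row."""
    out = df.copy()
    out.to_csv(path, index=False, encoding="utf-8")


def read_records(path) -> pd.DataFrame:
    """Read a record table written by :func:`write_records`.

    Round-trip contract: ``read_records(write_records(df))`` is
    field-identical to ``df`` for any table in the schema.
    """
    df = pd.read_csv(path, dtype=object, keep_default_na=False, encoding="utf-8")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file missing columns: {missing}")
    for c in _FLOAT_COLUMNS + ["compound_id"]:
        df[c] = df[c].replace("", np.nan)
    return _coerce_dtypes(df)


def read_synonym_table(path) -> dict[str, OdorantIdentity]:
    """Load a synonym table (TSV/CSV) into a normalized-name lookup.

    Expected columns: ``synonym``, ``canonical_name``, and optionally
    ``compound_id`` and ``molecular_weight`` (taken from any row of the
    canonical group; the identity table is the source of MW, which is
    never computed from structure here).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False)
    return synonym_table_from_frame(df)


def synonym_table_from_frame(df: pd.DataFrame) -> dict[str, OdorantIdentity]:
    """Build the synonym lookup from a two-column (plus metadata) frame."""
    out: dict[str, OdorantIdentity] = {}
    identities: dict[str, OdorantIdentity] = {}
    for canonical, group in df.groupby("canonical_name", sort=False):
        syns = frozenset(normalize_name(s) for s in group["synonym"])
        cid = None
        mw = None
        if "compound_id" in group:
            vals = [v for v in group["compound_id"] if str(v) != ""]
            if vals:
                cid = int(float(vals[0]))
        if "molecular_weight" in group:
            vals = [v for v in group["molecular_weight"] if str(v) != ""]
            if vals:
                mw = float(vals[0])
        identities[canonical] = OdorantIdentity(
            canonical_name=str(canonical), synonyms=syns,
            compound_id=cid, molecular_weight=mw,
        )
    for ident in identities.values():
        for syn in ident.synonyms:
            out[normalize_name(syn)] = ident
    return out


def read_property_table(path) -> pd.DataFrame:
    """Read an odorant -> physicochemical property table.

    CSV with ``odorant_canonical`` as key column and one numeric column
    per property; blanks are missing values.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if "odorant_canonical" not in df.columns:
        raise ValueError("property table requires an odorant_canonical column")
    df = df.set_index("odorant_canonical")
    if df.columns.duplicated().any():
        raise ValueError("duplicate property names in property table")
    return df.astype(float)


def concentration_decade(values: pd.Series, units: pd.Series) -> pd.Series:
    """log10 decade of each solution concentration; NaN for dry/invalid rows.

    Dry amounts deliberately get NaN so they can never match a solution
    concentration in any decade-keyed join.
    """
    vals = pd.to_numeric(values, errors="coerce")
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log10(vals.to_numpy(dtype=float))
    # ties at x.5 round toward the lower exponent
    dec = np.ceil(np.round(logs, 9) - 0.5)
    dec = pd.Series(dec, index=values.index)
    dec[(units == "dry_amount_g") | ~np.isfinite(logs)] = np.nan
    return dec
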