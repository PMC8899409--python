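"""Curation rules: heterogeneous reported measurements -> uniform records.

Published odorant-response measurements arrive in incompatible
conventions: preference reported as an index, as percent attraction or
percent repellency, or as raw choice counts; concentrations in V/V or
W/V fractions, molarity, ppm, mass per substrate area, or dry amounts;
EAG responses raw or pre-normalized; firing rates with or without the
solvent background subtracted.  This module implements the
standardization rules that map all of them onto the flat-file record
schema, plus :func:`standardize_table`, the bulk driver that applies
them row by row and logs every conversion and rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from . import records as rec
from .errors import (
    MissingMolecularWeightError,
    MissingReferenceError,
    RangeError,
    UndefinedIndexError,
    UnmappedOdorantError,
)
from .records import (
    Concentration,
    OdorantIdentity,
    normalize_name,
    round_significant,
)

#: Preferred EAG reference odorant when a study has to be normalized.
DEFAULT_EAG_REFERENCE = "1-octen-3-ol"


def canonicalize_odorant(
    name: str, synonym_table: dict[str, OdorantIdentity]
) -> OdorantIdentity:
    """Resolve a free-text odorant name to its canonical identity.

    Matching is case- and whitespace-insensitive but never fuzzy: a name
    absent from the synonym table raises :class:`UnmappedOdorantError`
    instead of passing through, because a silently mis-mapped odorant
    corrupts every downstream join.
    """
    key = normalize_name(name)
    try:
        return synonym_table[key]
    except KeyError:
        raise UnmappedOdorantError(f"unmapped odorant name: {name!r}") from None


def compute_preference_index(n_test: float, n_control: float) -> float:
    """Two-choice preference index (n_test - n_control)/(n_test + n_control).

    +1 means every animal chose the test odor, -1 every animal chose the
    control.  Undefined when no animal made a choice.
    """
    if n_test < 0 or n_control < 0:
        raise RangeError("choice counts must be non-negative")
    total = n_test + n_control
    if total == 0:
        raise UndefinedIndexError("preference index undefined: zero total count")
    return (n_test - n_control) / total


def convert_percent_metric(kind: str, value: float) -> float:
    """Map percent attraction / percent repellency onto the PI scale.

    Under the two-alternative reading, percent attraction ``a`` is the
    share of animals in the test arm, giving PI ``2a/100 - 1``; percent
    repellency ``r`` is its mirror image, ``1 - 2r/100``.  Protective
    efficacy is imported with the repellency map (flagged upstream in
    provenance so an alternative mapping can be substituted).
    """
    if not 0 <= value <= 100:
        raise RangeError(f"percent value outside [0, 100]: {value}")
    if kind == "percent_attraction":
        return 2 * value / 100 - 1
    if kind in ("percent_repellency", "protective_efficacy"):
        return 1 - 2 * value / 100
    raise RangeError(f"unknown percent metric {kind!r}")


def convert_concentration(
    conc: Concentration, odorant: OdorantIdentity | None = None
) -> Concentration:
    """Convert a reported concentration to a standardized unit kind.

    Targets: ``vv_fraction`` and ``wv_g_per_ml`` pass through; molarity
    becomes g/mL via the molecular weight (m mol/L x MW g/mol / 1000
    mL/L); ppm is read as mg/L = 1e-6 g/mL; a surface density d g/cm^2
    spread over A cm^2 and referenced to an application volume V mL
    becomes d*A/V g/mL; dry amounts pass through flagged as dry.
    """
    kind = conc.unit_kind
    if kind in rec.STANDARD_UNITS:
        return conc
    if kind == "molar":
        mw = odorant.molecular_weight if odorant is not None else None
        if mw is None:
            raise MissingMolecularWeightError(
                f"molar concentration for {getattr(odorant, 'canonical_name', '?')!r} "
                "requires a molecular weight"
            )
        value = round_significant(conc.value * mw / 1000.0)
        return Concentration(value, "wv_g_per_ml", raw_text=conc.raw_text)
    if kind == "ppm":
        return Concentration(
            round_significant(conc.value * 1e-6), "wv_g_per_ml", raw_text=conc.raw_text
        )
    if kind == "mass_per_area_with_volume":
        area, volume = conc.aux
        value = round_significant(conc.value * area / volume)
        return Concentration(value, "wv_g_per_ml", raw_text=conc.raw_text)
    raise RangeError(f"unknown concentration unit kind {kind!r}")


def subtract_background(
    odor_response: float, solvent_response: float, already_subtracted: bool = False
) -> float:
    """Remove the solvent (e.g. paraffin oil) response from a firing rate.

    Idempotent on flagged records; the result may be negative — an
    odorant can inhibit an OR below its spontaneous rate.
    """
    if already_subtracted:
        return odor_response
    return odor_response - solvent_response


def normalize_eag(
    df: pd.DataFrame, reference_odorant: OdorantIdentity | str
) -> pd.DataFrame:
    """Normalize one study's EAG responses to a reference odorant.

    Each unnormalized response is divided by the study's mean response to
    the reference odorant; the ``eag_reference`` field records which
    odorant was used.  Rows already carrying an ``eag_reference`` flag
    are left untouched (idempotence).
    """
    ref_name = (
        reference_odorant.canonical_name
        if isinstance(reference_odorant, OdorantIdentity)
        else reference_odorant
    )
    studies = set(df["study_id"])
    if len(studies) > 1:
        raise ValueError(f"normalize_eag expects a single study, got {sorted(studies)}")
    out = df.copy()
    todo = out["eag_reference"] == ""
    if not todo.any():
        return out
    ref_rows = todo & (out["odorant_canonical"] == ref_name)
    if not ref_rows.any():
        raise MissingReferenceError(
            f"study {next(iter(studies))!r}: no record for reference "
            f"odorant {ref_name!r}"
        )
    ref_mean = out.loc[ref_rows, "response_value"].mean()
    if ref_mean == 0:
        raise ZeroDivisionError(
            f"reference odorant {ref_name!r} has zero mean response"
        )
    out.loc[todo, "response_value"] = [
        round_significant(v / ref_mean) for v in out.loc[todo, "response_value"]
    ]
    out.loc[todo, "response_unit"] = "normalized"
    out.loc[todo, "eag_reference"] = ref_name
    return out


def round_concentration_decade(c: float) -> float:
    """Round a solution concentration to the nearest power of ten.

    Used to pool measurements across studies that used nearby
    concentrations.  Half-cases on the log scale (c = x * 10^(k+0.5))
    round toward the lower exponent.
    """
    if not c > 0 or not math.isfinite(c):
        raise RangeError(f"decade rounding requires c > 0, got {c}")
    exponent = math.ceil(round(math.log10(c), 9) - 0.5)
    return 10.0 ** exponent


# ---------------------------------------------------------------------------
# Bulk standardization of a raw table
# ---------------------------------------------------------------------------

#: Columns of the raw input schema (superset; absent columns are treated
#: as empty).  ``response_metric`` selects the conversion applied.
RAW_COLUMNS = [
    "data_type", "species", "odorant", "concentration_value",
    "concentration_unit", "area_cm2", "volume_ml", "response_metric",
    "response_value", "n_test", "n_control", "solvent_response", "technique",
    "receptor_or_sensillum", "assay_category", "behavioral_context",
    "age_days_min", "age_days_max", "sex", "study_id", "eag_reference",
    "background_subtracted",
]

#: Accepted response_metric values and the response_unit they produce.
RESPONSE_METRICS = {
    "preference_index": "PI",
    "percent_attraction": "PI",
    "percent_repellency": "PI",
    "protective_efficacy": "PI",
    "choice_counts": "PI",
    "spikes_per_s": "spikes/s",
    "spikes_per_s_raw": "spikes/s",
    "current_nA": "nA",
    "eag_normalized": "normalized",
    "eag_raw": "mV",
}


@dataclass
class StandardizationReport:
    """Audit trail of a standardization run."""

    n_input: int = 0
    n_output: int = 0
    conversions: list[dict] = dataclass_field(default_factory=list)
    rejected: list[dict] = dataclass_field(default_factory=list)

    def add_conversion(self, row_index: int, kind: str, detail: str) -> None:
        self.conversions.append(
            {"row": int(row_index), "kind": kind, "detail": detail}
        )

    def add_rejection(self, row_index: int, error: Exception) -> None:
        self.rejected.append(
            {"row": int(row_index), "error": type(error).__name__,
             "message": str(error)}
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_rejected": len(self.rejected),
            "conversions": self.conversions,
            "rejected": self.rejected,
        }


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value)
    if s == "":
        return None
    return float(s)


def _standardize_row(
    row: pd.Series, idx, synonyms: dict[str, OdorantIdentity],
    report: StandardizationReport,
) -> dict:
    identity = canonicalize_odorant(str(row["odorant"]), synonyms)
    if normalize_name(str(row["odorant"])) != normalize_name(identity.canonical_name):
        report.add_conversion(
            idx, "synonym", f"{row['odorant']!r} -> {identity.canonical_name!r}"
        )

    unit = str(row["concentration_unit"])
    cval = _opt_float(row["concentration_value"])
    if cval is None:
        conc_value, conc_unit = np.nan, unit
    else:
        aux = None
        if unit == "mass_per_area_with_volume":
            area, volume = _opt_float(row.get("area_cm2")), _opt_float(row.get("volume_ml"))
            if area is None or volume is None:
                raise RangeError("mass_per_area_with_volume requires area_cm2 and volume_ml")
            aux = (area, volume)
        conc = convert_concentration(
            Concentration(cval, unit, aux=aux, raw_text=f"{cval} {unit}"), identity
        )
        if conc.unit_kind != unit or conc.value != cval:
            report.add_conversion(
                idx, "concentration",
                f"{cval} {unit} -> {conc.value} {conc.unit_kind}",
            )
        conc_value, conc_unit = conc.value, conc.unit_kind

    metric = str(row["response_metric"])
    if metric not in RESPONSE_METRICS:
        raise RangeError(f"unknown response_metric {metric!r}")
    background_subtracted = str(row.get("background_subtracted", "")) in ("True", "true", "1")

    if metric == "choice_counts":
        value = compute_preference_index(
            float(row["n_test"]), float(row["n_control"])
        )
        report.add_conversion(
            idx, "preference_index",
            f"counts ({row['n_test']}, {row['n_control']}) -> PI {value}",
        )
    elif metric in ("percent_attraction", "percent_repellency", "protective_efficacy"):
        value = convert_percent_metric(metric, float(row["response_value"]))
        report.add_conversion(idx, "preference_index", f"{metric} -> PI {value}")
    elif metric == "spikes_per_s_raw":
        solvent = _opt_float(row.get("solvent_response")) or 0.0
        value = subtract_background(float(row["response_value"]), solvent, False)
        background_subtracted = True
        report.add_conversion(
            idx, "background_subtraction", f"solvent {solvent} subtracted"
        )
    else:
        value = float(row["response_value"])
        if metric == "spikes_per_s":
            background_subtracted = True
    value = round_significant(value)

    return {
        "data_type": str(row["data_type"]),
        "species": str(row["species"]),
        "odorant_canonical": identity.canonical_name,
        "compound_id": identity.compound_id,
        "concentration_value": conc_value,
        "concentration_unit": conc_unit,
        "response_value": value,
        "response_unit": RESPONSE_METRICS[metric],
        "technique": str(row["technique"]),
        "receptor_or_sensillum": str(row.get("receptor_or_sensillum", "")),
        "assay_category": str(row.get("assay_category", "")),
        "behavioral_context": str(row.get("behavioral_context", "")),
        "age_days_min": _opt_float(row.get("age_days_min")),
        "age_days_max": _opt_float(row.get("age_days_max")),
        "sex": str(row.get("sex", "")),
        "study_id": str(row["study_id"]),
        "eag_reference": str(row.get("eag_reference", "")),
        "background_subtracted": background_subtracted,
    }


def standardize_table(
    raw: pd.DataFrame,
    synonyms: dict[str, OdorantIdentity],
    eag_reference: str = DEFAULT_EAG_REFERENCE,
) -> tuple[pd.DataFrame, StandardizationReport]:
    """Standardize a raw table into the flat-file record schema.

    Applies, per row: synonym canonicalization, concentration conversion,
    preference-metric conversion, solvent-background subtraction; then,
    per EAG study, reference normalization (preferring ``eag_reference``,
    falling back to any odorant flagged in the raw ``eag_reference``
    column).  Rows that violate a rule are rejected and logged, never
    silently passed through.  Returns the standardized table and the
    report.
    """
    report = StandardizationReport(n_input=len(raw))
    rows, keep_index = [], []
    for idx, row in raw.iterrows():
        try:
            rows.append(_standardize_row(row, idx, synonyms, report))
            keep_index.append(idx)
        except Exception as exc:  # logged, row dropped
            report.add_rejection(idx, exc)
    if rows:
        df = rec._coerce_dtypes(pd.DataFrame(rows, index=keep_index))
    else:
        df = rec.empty_records()

    # per-study EAG normalization
    is_eag = df["data_type"] == "EAG"
    raw_eag = is_eag & (df["response_unit"] == "mV")
    for study in df.loc[raw_eag, "study_id"].unique():
        mask = is_eag & (df["study_id"] == study)
        sub = df.loc[mask]
        present = set(sub["odorant_canonical"])
        ref = eag_reference if eag_reference in present else None
        if ref is None:
            flagged = [
                r for r in sub.loc[sub["eag_reference"] != "", "eag_reference"]
                if r in present
            ]
            ref = flagged[0] if flagged else None
        try:
            if ref is None:
                raise MissingReferenceError(
                    f"EAG study {study!r} has no usable reference odorant"
                )
            sub = sub.copy()
            sub["eag_reference"] = ""
            df.loc[mask] = normalize_eag(sub, ref)
            report.add_conversion(
                sub.index[0], "eag_normalization",
                f"study {study!r} normalized to {ref!r}",
            )
        except (MissingReferenceError, ZeroDivisionError) as exc:
            for i in sub.index:
                report.add_rejection(i, exc)
            df = df.drop(index=sub.index)
            is_eag = df["data_type"] == "EAG"

    df = df.reset_index(drop=True)
    report.n_output = len(df)
    return df, report
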