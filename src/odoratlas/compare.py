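"""Cross-dataset comparisons over a standardized response database.

Six analyses, each answering one question about heterogeneity in the
literature:

* :func:`crosstab_techniques` — is the oocyte expression system less
  sensitive than the empty-neuron system for the same OR-odor pairs?
* :func:`pair_by_assay_category` — do some behavioral assay categories
  (e.g. landing assays) report systematically lower preference indices?
* :func:`correlate_pi_oviposition` — are preferences during egg-laying
  related to preferences during host-seeking/foraging?
* :func:`cross_species_correlation` — how similar are odor preferences
  between species?
* :func:`concentration_pair_deltas` — does a 10-fold concentration
  increase shift the preference index, and in which direction?
* :func:`or_activation_vs_pi` — is the number of ORs an odor activates
  related to how attractive the odor is?

All matching is done on concentrations rounded to the nearest power of
ten ("decades"); dry amounts carry no decade and never match solution
records.  Matching results embed the matched-item lists so every
reported statistic is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, SkippedComparison
from .records import concentration_decade
from .stats import pearson, sign_rank_test

#: Assay-category split presets for the landing-vs-choice comparison.
ASSAY_SPLIT_PRESETS = {
    "mosquito": ({"landing"}, {"dual_port", "y_tube"}),
    "fly": ({"t_maze"}, {"dual_port", "y_maze"}),
}

#: Firing-rate increase that counts an OR as activated by an odor.
DEFAULT_ACTIVATION_THRESHOLD = 10.0


def _with_decade(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["decade"] = concentration_decade(
        out["concentration_value"], out["concentration_unit"]
    )
    return out


# ---------------------------------------------------------------------------
# Technique sensitivity
# ---------------------------------------------------------------------------

@dataclass
class TechniqueCrosstab:
    """Zero/non-zero cross-tabulation of paired OR measurements.

    "Zero" means a response recorded as exactly 0 after standardization
    (non-responses in the oocyte literature are reported as 0); there is
    no epsilon band.
    """

    n_pairs: int
    en_nonzero_oo_zero: int
    en_zero_oo_nonzero: int
    oo_zero_breakdown: tuple[int, int, int]  # (en positive, en zero, en negative)
    mean_sd_en_given_oo_zero_negative: tuple[float, float]
    mean_sd_en_given_oo_nonzero_negative: tuple[float, float]
    pairs: pd.DataFrame = dataclass_field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "en_nonzero_oo_zero": self.en_nonzero_oo_zero,
            "en_zero_oo_nonzero": self.en_zero_oo_nonzero,
            "oo_zero_breakdown": list(self.oo_zero_breakdown),
            "mean_sd_en_given_oo_zero_negative":
                list(self.mean_sd_en_given_oo_zero_negative),
            "mean_sd_en_given_oo_nonzero_negative":
                list(self.mean_sd_en_given_oo_nonzero_negative),
        }


def crosstab_techniques(
    en_records: pd.DataFrame, oo_records: pd.DataFrame
) -> TechniqueCrosstab:
    """Compare empty-neuron and oocyte measurements of the same pairs.

    Joins the two datasets on (receptor, odorant, concentration decade),
    averaging replicate measurements within a dataset, and counts the
    asymmetric cells: pairs detected by the empty-neuron system but not
    the oocyte system and vice versa.  Among oocyte-zero pairs, the
    empty-neuron responses are broken down by sign, and the mean +/- SD
    of the negative (inhibitory) empty-neuron responses is reported for
    oocyte-zero vs oocyte-non-zero pairs — if oocyte zeros were simply
    inhibition, those two subgroups would differ sharply.
    """
    key = ["receptor_or_sensillum", "odorant_canonical", "decade"]
    sides = []
    for df, name in ((en_records, "en"), (oo_records, "oo")):
        d = _with_decade(df)
        d = d[d["decade"].notna()]
        sides.append(
            d.groupby(key, as_index=False)["response_value"]
            .mean()
            .rename(columns={"response_value": name})
        )
    merged = sides[0].merge(sides[1], on=key, how="inner").sort_values(key)
    if merged.empty:
        raise EmptySelectionError("no shared (OR, odorant, decade) keys")
    en, oo = merged["en"].to_numpy(), merged["oo"].to_numpy()
    oo_zero = oo == 0
    neg = en < 0

    def mean_sd(values: np.ndarray) -> tuple[float, float]:
        if values.size == 0:
            return (float("nan"), float("nan"))
        return (
            float(np.mean(values)),
            float(np.std(values, ddof=1)) if values.size > 1 else float("nan"),
        )

    return TechniqueCrosstab(
        n_pairs=len(merged),
        en_nonzero_oo_zero=int(((en != 0) & oo_zero).sum()),
        en_zero_oo_nonzero=int(((en == 0) & ~oo_zero).sum()),
        oo_zero_breakdown=(
            int(((en > 0) & oo_zero).sum()),
            int(((en == 0) & oo_zero).sum()),
            int(((en < 0) & oo_zero).sum()),
        ),
        mean_sd_en_given_oo_zero_negative=mean_sd(en[neg & oo_zero]),
        mean_sd_en_given_oo_nonzero_negative=mean_sd(en[neg & ~oo_zero]),
        pairs=merged.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Paired comparisons (assay categories, concentration deltas)
# ---------------------------------------------------------------------------

@dataclass
class PairedComparison:
    """A set of matched value pairs with their sign-rank comparison."""

    pairs: pd.DataFrame  # annotated (value_a, value_b) or delta rows
    n: int
    p_value: float | None
    mean_delta: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "p_value": self.p_value,
            "mean_delta": self.mean_delta,
            "pairs": self.pairs.to_dict(orient="records"),
        }


def pair_by_assay_category(
    behavior_records: pd.DataFrame,
    split: tuple[set[str], set[str]],
) -> PairedComparison:
    """Pair preference indices across two assay-category groups.

    For every (odorant, decade, species) measured in both groups, the
    PIs within each group are averaged into a single data point and one
    (group A, group B) pair is emitted; the paired differences A - B are
    sign-rank tested against zero.  Swapping the groups negates every
    delta.
    """
    cat_a, cat_b = (set(s) for s in split)
    df = _with_decade(behavior_records)
    df = df[(df["data_type"] == "BEHAVIOR") & df["decade"].notna()]
    key = ["odorant_canonical", "decade", "species"]
    means = {}
    for name, cats in (("value_a", cat_a), ("value_b", cat_b)):
        sub = df[df["assay_category"].isin(cats)]
        means[name] = sub.groupby(key)["response_value"].mean()
    merged = pd.concat(means, axis=1, join="inner").reset_index()
    if merged.empty:
        raise EmptySelectionError("no (odor, decade, species) present in both groups")
    merged = merged.sort_values(key).reset_index(drop=True)
    deltas = merged["value_a"] - merged["value_b"]
    res = sign_rank_test(deltas)
    return PairedComparison(
        pairs=merged, n=len(merged), p_value=res.p_value,
        mean_delta=float(deltas.mean()),
    )


def concentration_pair_deltas(
    behavior_records: pd.DataFrame,
    lower_pi_sign: str | None = None,
) -> PairedComparison:
    """PI change over adjacent concentration decades.

    An (odorant, assay category, species, decade) cell is eligible when
    it holds at least two data points, which are averaged; for every
    pair of eligible cells one decade apart, the delta PI(higher) -
    PI(lower) is emitted and the deltas are sign-rank tested against
    zero.  ``lower_pi_sign`` ("negative"/"positive") restricts to pairs
    whose lower-decade PI has that sign, for the sub-analyses asking
    whether aversive odors get more aversive and attractive ones less
    attractive.
    """
    df = _with_decade(behavior_records)
    df = df[(df["data_type"] == "BEHAVIOR") & df["decade"].notna()]
    key = ["odorant_canonical", "assay_category", "species"]
    cells = (
        df.groupby(key + ["decade"])["response_value"]
        .agg(["mean", "size"])
        .reset_index()
    )
    cells = cells[cells["size"] >= 2]
    rows = []
    for _, group in cells.groupby(key, sort=True):
        by_decade = group.set_index("decade")["mean"].sort_index()
        for dec in by_decade.index:
            if dec + 1 in by_decade.index:
                low, high = by_decade[dec], by_decade[dec + 1]
                rows.append(
                    {
                        "odorant_canonical": group.iloc[0]["odorant_canonical"],
                        "assay_category": group.iloc[0]["assay_category"],
                        "species": group.iloc[0]["species"],
                        "decade_low": dec,
                        "decade_high": dec + 1,
                        "pi_low": low,
                        "pi_high": high,
                        "delta": high - low,
                    }
                )
    pairs = pd.DataFrame(rows)
    if lower_pi_sign is not None and not pairs.empty:
        if lower_pi_sign == "negative":
            pairs = pairs[pairs["pi_low"] < 0]
        elif lower_pi_sign == "positive":
            pairs = pairs[pairs["pi_low"] > 0]
        else:
            raise ValueError("lower_pi_sign must be 'negative', 'positive' or None")
    if pairs.empty:
        raise EmptySelectionError("no eligible adjacent-decade pairs")
    pairs = pairs.reset_index(drop=True)
    res = sign_rank_test(pairs["delta"])
    return PairedComparison(
        pairs=pairs, n=len(pairs), p_value=res.p_value,
        mean_delta=float(pairs["delta"].mean()),
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """A Pearson correlation over matched items, with the item list."""

    n: int
    pearson_r: float
    p_value: float
    matched_items: pd.DataFrame = dataclass_field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "matched_items": self.matched_items.to_dict(orient="records"),
        }


def _correlate(matched: pd.DataFrame, col_a: str, col_b: str) -> CorrelationResult:
    r, p = pearson(matched[col_a], matched[col_b])
    return CorrelationResult(
        n=len(matched), pearson_r=r, p_value=p,
        matched_items=matched.reset_index(drop=True),
    )


def correlate_pi_oviposition(
    behavior_records: pd.DataFrame, species: str, min_items: int = 5
) -> CorrelationResult:
    """Correlate host-seeking/foraging PI with the oviposition index.

    Indices are matched per (odorant, decade) — both must have been
    measured at the same rounded concentration — with replicates
    averaged.  A species with fewer than ``min_items`` matched items is
    skipped with an explicit signal rather than yielding a noise
    correlation.
    """
    df = _with_decade(behavior_records)
    df = df[
        (df["data_type"] == "BEHAVIOR")
        & (df["species"] == species)
        & df["decade"].notna()
    ]
    key = ["odorant_canonical", "decade"]
    pi = (
        df[df["behavioral_context"] == "host_seeking_foraging"]
        .groupby(key)["response_value"].mean()
    )
    ovi = (
        df[df["behavioral_context"] == "oviposition"]
        .groupby(key)["response_value"].mean()
    )
    matched = pd.concat(
        {"preference_index": pi, "oviposition_index": ovi}, axis=1, join="inner"
    ).reset_index().sort_values(key)
    if len(matched) < min_items:
        raise SkippedComparison(
            f"species {species!r}: {len(matched)} matched items < {min_items}",
            n=len(matched),
        )
    return _correlate(matched, "preference_index", "oviposition_index")


def cross_species_correlation(
    behavior_records: pd.DataFrame,
    species_a: str,
    species_b: str,
    min_common_odors: int = 10,
) -> CorrelationResult:
    """Correlate preference indices between two species.

    For each odorant tested in both species, the pair of PIs at equal
    decades is used; failing that, the closest decades within a factor
    of 10 of each other (pairs two or more decades apart are excluded).
    When two candidate matches are equally close, the one at the lower
    decade wins.  Species pairs with fewer than ``min_common_odors``
    matched odorants are skipped with an explicit signal.
    """
    df = _with_decade(behavior_records)
    df = df[(df["data_type"] == "BEHAVIOR") & df["decade"].notna()]
    key = ["odorant_canonical", "decade"]
    tables = {
        s: df[df["species"] == s].groupby(key)["response_value"].mean().unstack()
        for s in (species_a, species_b)
    }
    rows = []
    common = tables[species_a].index.intersection(tables[species_b].index)
    for odor in sorted(common):
        decs_a = tables[species_a].loc[odor].dropna()
        decs_b = tables[species_b].loc[odor].dropna()
        # candidate decade pairs within one decade, closest first;
        # ties broken toward the lower decade pair
        candidates = [
            (abs(da - db), min(da, db), da, db)
            for da in decs_a.index
            for db in decs_b.index
            if abs(da - db) <= 1
        ]
        if not candidates:
            continue
        _, _, da, db = min(candidates)
        rows.append(
            {
                "odorant_canonical": odor,
                "decade_a": da,
                "decade_b": db,
                "pi_a": decs_a[da],
                "pi_b": decs_b[db],
            }
        )
    matched = pd.DataFrame(rows)
    if len(matched) < min_common_odors:
        raise SkippedComparison(
            f"{species_a} vs {species_b}: {len(matched)} common odors "
            f"< {min_common_odors}",
            n=len(matched),
        )
    return _correlate(matched, "pi_a", "pi_b")


def or_activation_vs_pi(
    or_records: pd.DataFrame,
    behavior_records: pd.DataFrame,
    threshold: float = DEFAULT_ACTIVATION_THRESHOLD,
) -> CorrelationResult:
    """Correlate the number of activated ORs with the preference index.

    An OR counts as activated by an odor when its (replicate-averaged)
    response at the matched decade is at least ``threshold`` spikes/s;
    the count per (odorant, decade) is correlated against the averaged
    PI at the same (odorant, decade).
    """
    orr = _with_decade(or_records)
    orr = orr[(orr["data_type"] == "OR") & orr["decade"].notna()]
    key = ["odorant_canonical", "decade"]
    per_or = orr.groupby(key + ["receptor_or_sensillum"])["response_value"].mean()
    counts = (per_or >= threshold).groupby(key).sum()

    beh = _with_decade(behavior_records)
    beh = beh[(beh["data_type"] == "BEHAVIOR") & beh["decade"].notna()]
    pis = beh.groupby(key)["response_value"].mean()
    matched = pd.concat(
        {"n_activated": counts, "preference_index": pis}, axis=1, join="inner"
    ).reset_index().sort_values(key)
    if len(matched) < 3:
        raise SkippedComparison(
            f"only {len(matched)} odors have both an activation count and a PI",
            n=len(matched),
        )
    matched["n_activated"] = matched["n_activated"].astype(int)
    return _correlate(matched, "n_activated", "preference_index")
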