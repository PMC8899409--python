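"""Synthetic odorant-response database with planted, recoverable effects.

Every analysis in the package is validated closed-loop: this module
generates a database whose statistical structure mirrors a curated
literature compilation — four response data types over multiple species
and studies — with known planted parameters, so each analysis stage can
be checked for recovering what was planted:

* OR empty-neuron responses are Gaussian-tuned to one molecular
  property (center b*, width sigma*, amplitude a*, additive noise), with
  a random inhibitory offset for a configurable fraction of OR-odor
  pairs;
* oocyte recordings of the same OR-odor pairs pass through a
  sensitivity threshold theta: responses below it are recorded as 0,
  emulating a less sensitive second technique;
* behavioral preference indices combine a per-odor base valence, a
  planted decline beta per 10-fold concentration increase, an
  assay-category offset delta, a negative loading gamma on the number
  of ORs the odor activates, and Gaussian noise, clipped to [-1, 1];
* oviposition indices are drawn independently of (or coupled to) the
  host-seeking base valence;
* the descriptor matrix contains the tuning-relevant property, highly
  correlated nuisance copies, pure-noise columns, a constant column and
  columns with missing entries, so the descriptor filter has something
  to do.

:func:`generate_raw_variants` re-exports a standardized table in messy
"as published" conventions (synonyms, molarity/ppm/mass-per-area
concentrations, percent metrics, raw EAG, unsubtracted firing rates)
such that the standardizer recovers the original table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field, asdict

import numpy as np
import pandas as pd

from . import records as rec
from .errors import ConfigError
from .records import OdorantIdentity

#: Assay categories used by mosquito-like vs fly-like species, as
#: (landing-style, choice-style-1, choice-style-2).
_SPECIES_ASSAYS = [
    ("landing", "dual_port", "y_tube"),
    ("t_maze", "y_maze", "dual_port"),
]
_SPECIES_NAMES = [
    "Aedes_aegypti", "Drosophila_melanogaster", "Anopheles_gambiae",
    "Culex_quinquefasciatus", "Aedes_albopictus",
]


@dataclass
class SyntheticConfig:
    """All planted-effect parameters of the generator."""

    seed: int = 0
    n_odorants: int = 200
    n_ors: int = 30
    n_species: int = 2
    n_studies: int = 12

    #: (name, mean, SD) of each Gaussian-distributed property.
    property_spec: tuple = (
        ("molecular_weight", 130.0, 40.0),
        ("log_p", 2.0, 1.2),
        ("polar_surface_area", 30.0, 15.0),
        ("complexity", 120.0, 60.0),
    )
    tuning_property: str = "molecular_weight"
    tuning_center: float = 130.0       # b*, property units
    tuning_width: float = 30.0         # sigma*, property units
    tuning_amplitude: float = 100.0    # a*, spikes/s
    response_noise_sd: float = 10.0    # spikes/s (0.1 * a* by default)
    inhibitory_fraction: float = 0.2   # OR-odor pairs given a negative offset
    inhibitory_max: float = 30.0       # spikes/s, uniform offset magnitude cap

    oocyte_threshold: float = 20.0     # theta, spikes/s
    oocyte_gain: float = 1.0           # nA per spikes/s above threshold

    assay_offsets: dict = dataclass_field(
        default_factory=lambda: {"landing": -0.3, "t_maze": -0.2}
    )
    concentration_slope: float = 0.2   # beta, PI decline per 10-fold increase
    reference_decade: int = -3         # decade where the base valence applies
    pi_noise_sd: float = 0.1
    or_count_loading: float = 0.01     # gamma, PI per activated OR
    activation_threshold: float = 10.0  # spikes/s, defines "activated"
    behavior_odor_fraction: float = 0.6
    oviposition_mode: str = "independent"  # or "coupled"
    oviposition_rho: float = 0.8

    missing_property_rate: float = 0.05
    n_noise_descriptors: int = 20
    n_correlated_descriptors: int = 6
    n_missing_descriptors: int = 4

    def validate(self) -> None:
        positive = {
            "n_odorants": self.n_odorants, "n_ors": self.n_ors,
            "n_species": self.n_species, "n_studies": self.n_studies,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        nonneg = {
            "response_noise_sd": self.response_noise_sd,
            "pi_noise_sd": self.pi_noise_sd,
            "oocyte_threshold": self.oocyte_threshold,
            "tuning_width": self.tuning_width,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        for name, v in (
            ("inhibitory_fraction", self.inhibitory_fraction),
            ("missing_property_rate", self.missing_property_rate),
            ("behavior_odor_fraction", self.behavior_odor_fraction),
        ):
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.oviposition_mode not in ("independent", "coupled"):
            raise ConfigError(
                f"oviposition_mode must be 'independent' or 'coupled', "
                f"got {self.oviposition_mode!r}"
            )
        if self.n_species > len(_SPECIES_NAMES):
            raise ConfigError(f"at most {len(_SPECIES_NAMES)} species supported")
        if not any(p[0] == self.tuning_property for p in self.property_spec):
            raise ConfigError(
                f"tuning_property {self.tuning_property!r} not in property_spec"
            )


@dataclass
class SyntheticDatabase:
    """Generator output: records plus side tables and the planted truth."""

    records: pd.DataFrame          # flat-file schema
    properties: pd.DataFrame       # odorant x property, with planted missingness
    descriptors: pd.DataFrame      # odorant x descriptor, for the NN pipeline
    synonyms: pd.DataFrame         # synonym -> canonical mapping table
    identities: dict[str, OdorantIdentity]
    truth: dict                    # every planted parameter


def _round4(x):
    return np.round(np.asarray(x, float), 4)


def generate_database(cfg: SyntheticConfig) -> SyntheticDatabase:
    """Generate the full synthetic database (deterministic given cfg.seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- odorants, identities, synonyms -----------------------------------
    names = [f"odorant-{i:03d}" for i in range(cfg.n_odorants)]
    # two real names anchor the curation fixtures (EAG reference and the
    # classic many-synonyms alcohol); their property values are synthetic
    if cfg.n_odorants >= 2:
        names[0] = "1-octen-3-ol"
        names[1] = "3-methyl-1-butanol"
    prop_names = [p[0] for p in cfg.property_spec]
    prop_values = {
        name: rng.normal(mean, sd, cfg.n_odorants)
        for name, mean, sd in cfg.property_spec
    }
    if "molecular_weight" in prop_values:
        prop_values["molecular_weight"] = np.clip(
            prop_values["molecular_weight"], 30.0, None
        )
    properties_full = pd.DataFrame(
        prop_values, index=pd.Index(names, name="odorant_canonical")
    ).round(4)

    syn_rows = []
    identities = {}
    extra_synonyms = {
        "3-methyl-1-butanol": ["isoamyl alcohol", "isopentyl alcohol", "isopentanol"],
    }
    for i, name in enumerate(names):
        syns = [name] + extra_synonyms.get(name, [])
        n_extra = int(rng.integers(0, 3))
        syns += [f"alt{k}-{name}" for k in range(1, n_extra + 1)]
        mw = float(properties_full.loc[name, "molecular_weight"]) \
            if "molecular_weight" in prop_names else None
        cid = 10_000 + i
        identities[name] = OdorantIdentity(
            canonical_name=name, synonyms=frozenset(syns),
            compound_id=cid, molecular_weight=mw,
        )
        for s in syns:
            syn_rows.append(
                {"synonym": s, "canonical_name": name, "compound_id": cid,
                 "molecular_weight": mw if mw is not None else ""}
            )
    synonyms = pd.DataFrame(syn_rows)

    # planted missingness hits the analysis property table only, never the
    # identity table (molecular weights for unit conversion stay available)
    properties = properties_full.copy()
    if cfg.missing_property_rate > 0:
        mask = rng.random(properties.shape) < cfg.missing_property_rate
        properties = properties.mask(mask)

    # --- species, ORs, studies --------------------------------------------
    species = _SPECIES_NAMES[: cfg.n_species]
    or_names = [f"OR{i + 1:02d}" for i in range(cfg.n_ors)]
    or_species = [species[i % cfg.n_species] for i in range(cfg.n_ors)]
    studies = [f"study-{i + 1:02d}" for i in range(cfg.n_studies)]

    x = properties_full[cfg.tuning_property].to_numpy(float)
    clean = cfg.tuning_amplitude * np.exp(
        -((x - cfg.tuning_center) ** 2) / (2.0 * cfg.tuning_width**2)
    )
    inhibited = rng.random((cfg.n_ors, cfg.n_odorants)) < cfg.inhibitory_fraction
    inhibition = np.where(
        inhibited, rng.uniform(5.0, cfg.inhibitory_max, (cfg.n_ors, cfg.n_odorants)), 0.0
    )
    noise = rng.normal(0.0, cfg.response_noise_sd, (cfg.n_ors, cfg.n_odorants))
    en_responses = _round4(clean[None, :] - inhibition + noise)
    oo_responses = _round4(
        cfg.oocyte_gain * np.maximum(0.0, en_responses - cfg.oocyte_threshold)
    )

    rows = []
    or_study = {o: studies[i % max(1, cfg.n_studies // 3)] for i, o in enumerate(or_names)}
    oo_study = studies[-1]
    for i, or_name in enumerate(or_names):
        # alternate V/V and W/V reporting; both round to the same decade
        en_unit = "wv_g_per_ml" if i % 2 else "vv_fraction"
        for j, odor in enumerate(names):
            rows.append(
                _record_row(
                    "OR", or_species[i], identities[odor], 1e-2, en_unit,
                    en_responses[i, j], "spikes/s", "empty_neuron", or_study[or_name],
                    receptor=or_name, background_subtracted=True,
                )
            )
            if or_species[i] == species[0]:
                rows.append(
                    _record_row(
                        "OR", or_species[i], identities[odor], 1e-2, "vv_fraction",
                        oo_responses[i, j], "nA", "oocyte", oo_study,
                        receptor=or_name, background_subtracted=True,
                    )
                )

    # per-(species, odor) activation counts at the OR decade
    activation_count = {
        sp: (
            (en_responses[[k for k, s in enumerate(or_species) if s == sp], :]
             >= cfg.activation_threshold).sum(axis=0)
        )
        for sp in species
    }

    # --- behavior ----------------------------------------------------------
    n_beh = max(1, int(round(cfg.behavior_odor_fraction * cfg.n_odorants)))
    beh_study_pool = studies[max(1, cfg.n_studies // 3):] or studies
    base = {}
    for si, sp in enumerate(species):
        chosen = rng.choice(cfg.n_odorants, size=n_beh, replace=False)
        assays = _SPECIES_ASSAYS[si % len(_SPECIES_ASSAYS)]
        for j in chosen:
            odor = names[j]
            base[(sp, odor)] = float(rng.uniform(-0.5, 0.5))
            start = int(rng.integers(-4, -2))  # run of decades within 1e-4..1e-1
            decades = [start, start + 1]
            if rng.random() < 0.5 and start + 2 <= -1:
                decades.append(start + 2)
            odor_assays = (assays[0], assays[1 + int(rng.integers(0, 2))])
            for dec in decades:
                for assay in odor_assays:
                    for study in rng.choice(beh_study_pool, 2, replace=False):
                        pi = (
                            base[(sp, odor)]
                            - cfg.concentration_slope * (dec - cfg.reference_decade)
                            + cfg.assay_offsets.get(assay, 0.0)
                            - cfg.or_count_loading * activation_count[sp][j]
                            + rng.normal(0.0, cfg.pi_noise_sd)
                        )
                        pi = float(_round4(np.clip(pi, -1.0, 1.0)))
                        rows.append(
                            _record_row(
                                "BEHAVIOR", sp, identities[odor], 10.0**dec,
                                "vv_fraction", pi, "PI", "behavior", str(study),
                                assay_category=assay,
                                behavioral_context="host_seeking_foraging",
                            )
                        )
            # oviposition index for the same odor at the same decades
            if si == 0:
                if cfg.oviposition_mode == "independent":
                    obase = float(rng.uniform(-0.5, 0.5))
                else:
                    rho = cfg.oviposition_rho
                    obase = float(
                        rho * base[(sp, odor)]
                        + np.sqrt(1 - rho**2) * rng.uniform(-0.5, 0.5)
                    )
                # no concentration slope here: egg-laying preference is
                # modeled as dose-independent, so the independent mode
                # yields a truly null PI-oviposition correlation
                for dec in decades:
                    ovi = obase + rng.normal(0.0, cfg.pi_noise_sd)
                    ovi = float(_round4(np.clip(ovi, -1.0, 1.0)))
                    rows.append(
                        _record_row(
                            "BEHAVIOR", sp, identities[odor], 10.0**dec,
                            "vv_fraction", ovi, "PI", "behavior",
                            str(rng.choice(beh_study_pool)),
                            assay_category="dual_port",
                            behavioral_context="oviposition",
                        )
                    )

    # --- EAG and native SSR filler ----------------------------------------
    eag_panel = list(range(min(20, cfg.n_odorants)))
    for study in studies[:2]:
        for j in eag_panel:
            value = 1.0 if names[j] == "1-octen-3-ol" else float(
                _round4(rng.uniform(0.1, 2.0))
            )
            rows.append(
                _record_row(
                    "EAG", species[0], identities[names[j]], 1e-2, "vv_fraction",
                    value, "normalized", "eag", study,
                    eag_reference="1-octen-3-ol",
                )
            )
    for j in range(min(15, cfg.n_odorants)):
        rows.append(
            _record_row(
                "SSR", species[-1], identities[names[j]], 1e-2, "vv_fraction",
                float(_round4(rng.normal(40, 20))), "spikes/s", "ssr_native",
                studies[0], receptor="ab1A", background_subtracted=True,
            )
        )

    records = rec._coerce_dtypes(pd.DataFrame(rows))

    # --- descriptor matrix --------------------------------------------------
    desc = {f"prop_{p}": properties_full[p].to_numpy(float) for p in prop_names}
    for k in range(cfg.n_correlated_descriptors):
        noise_sd = 0.02 * np.std(x) * (k + 1) / cfg.n_correlated_descriptors
        desc[f"{cfg.tuning_property}_proxy_{k}"] = _round4(
            x + rng.normal(0, max(noise_sd, 1e-6), cfg.n_odorants)
        )
    for k in range(cfg.n_noise_descriptors):
        desc[f"noise_{k:02d}"] = _round4(rng.normal(0, 1, cfg.n_odorants))
    desc["constant"] = np.zeros(cfg.n_odorants)
    descriptors = pd.DataFrame(desc, index=properties_full.index.copy())
    for k in range(cfg.n_missing_descriptors):
        col = _round4(rng.normal(0, 1, cfg.n_odorants))
        holes = rng.random(cfg.n_odorants) < 0.1
        col = np.where(holes, np.nan, col)
        descriptors[f"patchy_{k}"] = col

    truth = {
        "config": _config_dict(cfg),
        "base_valence": {f"{sp}|{od}": v for (sp, od), v in base.items()},
        "activation_count": {
            sp: activation_count[sp].tolist() for sp in species
        },
        "species": species,
        "or_names": or_names,
        "or_species": or_species,
    }
    return SyntheticDatabase(
        records=records, properties=properties, descriptors=descriptors,
        synonyms=synonyms, identities=identities, truth=truth,
    )


def _config_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["property_spec"] = [list(p) for p in cfg.property_spec]
    return d


def _record_row(
    data_type, species, identity, conc_value, conc_unit, response, unit,
    technique, study, receptor=None, assay_category=None,
    behavioral_context=None, eag_reference=None, background_subtracted=False,
):
    return {
        "data_type": data_type,
        "species": species,
        "odorant_canonical": identity.canonical_name,
        "compound_id": identity.compound_id,
        "concentration_value": float(conc_value),
        "concentration_unit": conc_unit,
        "response_value": float(response),
        "response_unit": unit,
        "technique": technique,
        "receptor_or_sensillum": receptor or "",
        "assay_category": assay_category or "",
        "behavioral_context": behavioral_context or "",
        "age_days_min": 6.0,
        "age_days_max": 8.0,
        "sex": "female",
        "study_id": study,
        "eag_reference": eag_reference or "",
        "background_subtracted": bool(background_subtracted),
    }


# ---------------------------------------------------------------------------
# Messy raw variants
# ---------------------------------------------------------------------------

def generate_raw_variants(
    db: SyntheticDatabase, seed: int | None = None
) -> pd.DataFrame:
    """Re-export a standardized table in messy "as published" conventions.

    Each row is rewritten with a randomly chosen reporting convention —
    a synonym with scrambled case/whitespace for the odorant name; the
    concentration as molarity, ppm, or mass-per-area where a molecular
    weight permits; behavior as percent attraction/repellency or raw
    choice counts; EAG as unnormalized deflections scaled by a per-study
    factor; firing rates with the solvent background added back — such
    that :func:`odoratlas.standardize.standardize_table` recovers the
    input table field-identically.
    """
    records = db.records
    rng = np.random.default_rng(
        db.truth["config"]["seed"] + 1 if seed is None else seed
    )
    eag_scale = {
        s: float(rng.uniform(1.5, 4.0))
        for s in records.loc[records["data_type"] == "EAG", "study_id"].unique()
    }
    solvent_bg = {
        s: float(rng.integers(10, 40))
        for s in records["study_id"].unique()
    }
    raw_rows = []
    for _, row in records.iterrows():
        identity = db.identities[row["odorant_canonical"]]
        raw = {c: "" for c in _RAW_COLUMNS_ORDER}
        raw.update(
            data_type=row["data_type"], species=row["species"],
            technique=row["technique"],
            receptor_or_sensillum=row["receptor_or_sensillum"],
            assay_category=row["assay_category"],
            behavioral_context=row["behavioral_context"],
            age_days_min=row["age_days_min"], age_days_max=row["age_days_max"],
            sex=row["sex"], study_id=row["study_id"],
            background_subtracted="True" if row["background_subtracted"] else "",
        )
        # odorant name: random synonym, scrambled case / padding
        syn = str(rng.choice(sorted(identity.synonyms)))
        style = rng.integers(0, 3)
        if style == 1:
            syn = syn.upper()
        elif style == 2:
            syn = "  " + syn.title() + " "
        raw["odorant"] = syn

        cval, cunit = row["concentration_value"], row["concentration_unit"]
        raw["concentration_value"], raw["concentration_unit"] = cval, cunit
        if cunit == "wv_g_per_ml" and identity.molecular_weight:
            choice = rng.integers(0, 4)
            if choice == 1:
                raw["concentration_value"] = cval * 1000.0 / identity.molecular_weight
                raw["concentration_unit"] = "molar"
            elif choice == 2:
                raw["concentration_value"] = cval * 1e6
                raw["concentration_unit"] = "ppm"
            elif choice == 3:
                area = float(rng.choice([5.0, 6.6, 10.0]))
                volume = float(rng.choice([0.02, 0.025, 0.05]))
                raw["concentration_value"] = cval * volume / area
                raw["concentration_unit"] = "mass_per_area_with_volume"
                raw["area_cm2"], raw["volume_ml"] = area, volume

        value = float(row["response_value"])
        if row["data_type"] == "BEHAVIOR":
            counts_ok = float(value * 5000).is_integer()
            choice = rng.integers(0, 4 if counts_ok else 3)
            if choice == 0:
                raw["response_metric"], raw["response_value"] = "preference_index", value
            elif choice == 1:
                raw["response_metric"] = "percent_attraction"
                raw["response_value"] = (value + 1.0) * 50.0
            elif choice == 2:
                raw["response_metric"] = "percent_repellency"
                raw["response_value"] = (1.0 - value) * 50.0
            else:
                raw["response_metric"] = "choice_counts"
                raw["n_test"] = int(round((1.0 + value) * 5000))
                raw["n_control"] = int(round((1.0 - value) * 5000))
        elif row["data_type"] == "EAG":
            if row["response_unit"] == "normalized":
                raw["response_metric"] = "eag_raw"
                raw["response_value"] = value * eag_scale[row["study_id"]]
                raw["eag_reference"] = row["eag_reference"]
            else:
                raw["response_metric"] = "eag_normalized"
                raw["response_value"] = value
                raw["eag_reference"] = row["eag_reference"]
        elif row["response_unit"] == "nA":
            raw["response_metric"], raw["response_value"] = "current_nA", value
        else:  # spikes/s
            if rng.random() < 0.5:
                bg = solvent_bg[row["study_id"]]
                raw["response_metric"] = "spikes_per_s_raw"
                raw["response_value"] = value + bg
                raw["solvent_response"] = bg
            else:
                raw["response_metric"], raw["response_value"] = "spikes_per_s", value
        raw_rows.append(raw)
    return pd.DataFrame(raw_rows, columns=_RAW_COLUMNS_ORDER)


_RAW_COLUMNS_ORDER = [
    "data_type", "species", "odorant", "concentration_value",
    "concentration_unit", "area_cm2", "volume_ml", "response_metric",
    "response_value", "n_test", "n_control", "solvent_response", "technique",
    "receptor_or_sensillum", "assay_category", "behavioral_context",
    "age_days_min", "age_days_max", "sex", "study_id", "eag_reference",
    "background_subtracted",
]
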