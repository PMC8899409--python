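"""Generate the synthetic study database.

Emits, under results/data/: the standardized record table (four data
types over two species), the odorant property table with planted
missingness, the descriptor matrix for the response model, the synonym
table, a messy "as published" raw export, and the planted-truth JSON.
"""

import json
from pathlib import Path

from odoratlas import SyntheticConfig, generate_database, generate_raw_variants
from odoratlas.records import write_records

SEED = 2022
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    cfg = SyntheticConfig(seed=SEED)
    db = generate_database(cfg)
    (OUT / "raw").mkdir(parents=True, exist_ok=True)
    write_records(db.records, OUT / "records.csv")
    db.properties.to_csv(OUT / "props.csv")
    db.descriptors.to_csv(OUT / "descriptors.csv")
    db.synonyms.to_csv(OUT / "synonyms.tsv", sep="\t", index=False)
    generate_raw_variants(db).to_csv(OUT / "raw" / "records_raw.csv", index=False)
    with open(OUT / "truth.json", "w") as fh:
        json.dump(db.truth, fh, indent=2, default=str)
    counts = db.records["data_type"].value_counts().to_dict()
    print(f"wrote {len(db.records)} records to {OUT}")
    print("  by data type:", {k: int(v) for k, v in counts.items()})
    print(f"  {cfg.n_odorants} odorants, {cfg.n_ors} ORs, "
          f"{cfg.n_species} species, planted tuning "
          f"(b*={cfg.tuning_center}, sigma*={cfg.tuning_width}, "
          f"a*={cfg.tuning_amplitude})")


if __name__ == "__main__":
    main()
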