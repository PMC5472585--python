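#!/usr/bin/env python
"""Generate the synthetic study corpora used by all downstream analyses.

Writes to results/data/:
  * planted_clean.csv   — 4,000 reactions, deterministic label rule
  * planted_noisy.csv   — 4,000 reactions, 20% label noise, 5% duplicates,
                          5% missing condition fields
  * messy.csv           — 400 raw rows exercising every rejection path
  * *_truth.json        — hidden ground truth / manifests

The planted corpora emulate literature reaction sets: alkyl scaffolds
decorated with ten signal-carrying fragments, simple halogenation/
hydroxylation templates, yields back-generated so a 65% threshold
reproduces the hidden labels.
"""

import json
from pathlib import Path

from rxnaudit.synthetic_data import (
    PlantedReactionSpec,
    messy_records,
    planted_reactions,
)

SEED = 20260928
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def write_corpus(records, path):
    with open(path, "w") as fh:
        fh.write("reaction_id,rsmi,yield,time,solvent,temperature\n")
        for r in records:
            fh.write(
                f"{r.reaction_id},{r.rsmi},"
                f"{'' if r.yield_pct is None else r.yield_pct},"
                f"{'' if r.time_h is None else r.time_h},"
                f"{r.solvent or ''},"
                f"{'' if r.temperature_c is None else r.temperature_c}\n"
            )


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    specs = {
        "planted_clean": PlantedReactionSpec(n_reactions=4000, seed=SEED),
        "planted_noisy": PlantedReactionSpec(
            n_reactions=4000, label_noise=0.2, duplicate_rate=0.05,
            missing_rate=0.05, seed=SEED + 1,
        ),
    }
    for name, spec in specs.items():
        records, truth = planted_reactions(spec)
        write_corpus(records, OUT / f"{name}.csv")
        with open(OUT / f"{name}_truth.json", "w") as fh:
            json.dump(
                {
                    "bayes_error": truth.bayes_error,
                    "informative_features": truth.informative_features,
                    "observed_labels": truth.observed_labels,
                    "n_duplicates": truth.n_duplicates,
                },
                fh, indent=2, sort_keys=True,
            )
        print(
            f"{name}: {len(records)} records "
            f"({truth.n_duplicates} duplicate reports), "
            f"planted Bayes error {truth.bayes_error:.3f}"
        )

    csv_text, manifest = messy_records(400, seed=SEED + 2)
    (OUT / "messy.csv").write_text(csv_text)
    with open(OUT / "messy_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    print(
        f"messy: 400 rows, expect {manifest['n_parsed']} parsed, "
        f"{manifest['n_dedup_survivors']} after dedup"
    )


if __name__ == "__main__":
    main()
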