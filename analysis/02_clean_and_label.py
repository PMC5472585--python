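#!/usr/bin/env python
"""Clean and binary-label the generated corpora; verify against manifests.

Runs the full data-preparation protocol (parse -> reject -> deduplicate ->
strict-threshold label) on each corpus from step 01 and reports the
arithmetic: rejection reasons, dedup survivors, class balance. For the messy
corpus the counts are checked against the generator's manifest.
"""

import json
from collections import Counter
from pathlib import Path

from rxnaudit.reaction_io import (
    LabelSpec,
    Target,
    deduplicate,
    label,
    read_reactions_csv,
    write_labeled_csv,
    write_rejections,
)

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results" / "cleaned"


def clean_one(name, target=Target.YIELD):
    records, rejections = read_reactions_csv(DATA / f"{name}.csv")
    survivors = deduplicate(records, target)
    ds = label(survivors, LabelSpec(target))
    write_labeled_csv(ds, OUT / f"{name}_labeled.csv")
    write_rejections(rejections, OUT / f"{name}_rejections.jsonl")
    reasons = Counter(r["reason"] for r in rejections)
    print(
        f"{name}: {len(records)} parsed, {len(rejections)} rejected "
        f"{dict(reasons)}, {len(survivors)} after dedup, "
        f"{sum(ds.labels)}/{len(ds.labels)} high-yield, "
        f"{ds.n_excluded} missing-target"
    )
    return records, rejections, survivors, ds


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    clean_one("planted_clean")
    clean_one("planted_noisy")
    records, rejections, survivors, ds = clean_one("messy")
    manifest = json.load(open(DATA / "messy_manifest.json"))
    checks = {
        "parsed": len(records) == manifest["n_parsed"],
        "rejected": len(rejections) == manifest["n_rejected"],
        "dedup": len(survivors) == manifest["n_dedup_survivors"],
        "label_1": sum(ds.labels) == manifest["yield"]["n_label_1"],
    }
    assert all(checks.values()), checks
    print(f"messy corpus matches its manifest exactly: {checks}")


if __name__ == "__main__":
    main()
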