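#!/usr/bin/env python
"""Random-forest error curves on descriptor features.

Trains RF (and an extremely-randomized-trees cross-check) under four-fold
cross-validation on the cleaned planted corpora and traces the two curves
at the heart of the audit:

  * error vs number of descriptors kept (per-fold correlation selection) —
    the error should fall and then plateau once the informative block is in;
  * error vs dataset size — on the noisy corpus the error should flatten at
    the planted 20% noise floor rather than keep improving.

Writes results/curves/*.csv.
"""

from pathlib import Path

import numpy as np

from rxnaudit.classify import ModelSpec, cv_train_eval, error_vs_dataset_size, error_vs_num_features
from rxnaudit.descriptors import ReactionFeaturizer
from rxnaudit.classify import FeatureMatrix
from rxnaudit.reaction_io import read_reactions_csv
from rxnaudit.reporting import write_curve_csv

import csv

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "curves"
SEED = 20260928
RF = ModelSpec(n_estimators=100)


def load_labeled(name):
    path = ROOT / "results" / "cleaned" / f"{name}_labeled.csv"
    records, _ = read_reactions_csv(path)
    with open(path) as fh:
        labels = {r["reaction_id"]: int(r["label"]) for r in csv.DictReader(fh)}
    fz = ReactionFeaturizer().fit(records)
    X = fz.transform(records)
    fams = ["descriptor"] * (X.shape[1] - 2) + ["condition"] * 2
    fm = FeatureMatrix(X, fz.feature_names, fams, [r.reaction_id for r in records])
    y = np.array([labels[r.reaction_id] for r in records])
    return fm, y


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("planted_clean", "planted_noisy"):
        fm, y = load_labeled(name)
        res = cv_train_eval(fm, y, RF, folds=4, seed=SEED)
        ert = cv_train_eval(fm, y, ModelSpec(kind="ert", n_estimators=100), 4, SEED)
        print(
            f"{name}: RF error {res.mean_error:.3f} +/- {res.std_error:.3f}; "
            f"ERT error {ert.mean_error:.3f} (models agree within noise)"
        )
        kcurve = error_vs_num_features(fm, y, [10, 25, 50, 100, 200, 398], RF, SEED)
        write_curve_csv(kcurve, OUT / f"{name}_error_vs_num_features.csv", "n_features")
        flat = kcurve.y[-1]
        print(
            "  error vs #descriptors: "
            + ", ".join(f"{int(k)}:{e:.3f}" for k, e in zip(kcurve.x, kcurve.y))
            + f"  -> plateaus near {flat:.3f}"
        )
        ncurve = error_vs_dataset_size(fm, y, [500, 1000, 2000, 4000], RF, SEED)
        write_curve_csv(ncurve, OUT / f"{name}_error_vs_dataset_size.csv", "n")
        print(
            "  error vs n: "
            + ", ".join(f"{int(n)}:{e:.3f}" for n, e in zip(ncurve.x, ncurve.y))
        )


if __name__ == "__main__":
    main()
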