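#!/usr/bin/env python
"""Feature diagnostics: selection recovery, importance stability, linear
cross-check, PCA overlap, and the regression noise floor.

Confirms that the audit's negative verdicts are not artifacts of the
protocol: correlation ranking does recover planted signal, Gini importances
are stable across runs, an L1-logistic model agrees with the forests, PCA
shows the class overlap the error curves imply, and RF regression on pure
noise returns the theoretical RMSE floor 100/sqrt(12).
"""

import csv
from pathlib import Path

import numpy as np

from rxnaudit.classify import (
    FeatureMatrix,
    ModelSpec,
    correlation_rank,
    gini_importance_stability,
    lasso_logistic_check,
    pca_projection,
    rf_regression_rmse,
)
from rxnaudit.descriptors import ReactionFeaturizer
from rxnaudit.reaction_io import read_reactions_csv
from rxnaudit.synthetic_data import informative_columns, planted_reactions, PlantedReactionSpec

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "diagnostics"
SEED = 20260928


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    records, truth = planted_reactions(
        PlantedReactionSpec(n_reactions=4000, label_noise=0.2, seed=SEED + 9)
    )
    fz = ReactionFeaturizer().fit(records)
    X = fz.transform(records)
    fm = FeatureMatrix.from_array(
        X, fz.feature_names, "descriptor", [r.reaction_id for r in records]
    )
    y = np.array([truth.observed_labels[r.reaction_id] for r in records])

    informative = informative_columns(fm, truth)
    ranked = [n for n, _ in correlation_rank(fm, y)]
    top = set(ranked[: 2 * len(informative)])
    rec = len(top & set(informative)) / len(informative)
    print(
        f"correlation ranking: {100 * rec:.0f}% of the {len(informative)} "
        f"informative columns in the top {2 * len(informative)} slots"
    )
    with open(OUT / "correlation_ranking.csv", "w") as fh:
        fh.write("rank,feature,informative\n")
        for i, name in enumerate(ranked[:100]):
            fh.write(f"{i},{name},{int(name in informative)}\n")

    stab = gini_importance_stability(
        fm, y, ModelSpec(n_estimators=50), n_runs=4, seeds=[1, 2, 3, 4]
    )
    print(
        f"Gini importances: top feature '{stab.top_feature()}', mean pairwise "
        f"Spearman rank agreement across runs {stab.rank_agreement:.3f}"
    )

    acc = lasso_logistic_check(fm, y, subsample_n=2000, seed=SEED)
    print(f"L1-logistic cross-check accuracy (n=2000 subsample): {acc:.3f}")

    proj = pca_projection(fm, y)
    sep = proj.centroid_separation(0)
    np.savetxt(
        OUT / "pca_scores.csv",
        np.column_stack([proj.scores, y]),
        delimiter=",", header="pc1,pc2,label", comments="",
    )
    print(
        f"PCA: class-centroid separation {sep:.2f} pooled sd on PC1 — the "
        f"classes overlap heavily in the leading descriptor directions"
    )

    rng = np.random.default_rng(SEED)
    n = 8000
    noise_target = rng.uniform(0, 100, size=n)
    rmse = rf_regression_rmse(
        FeatureMatrix.from_array(rng.normal(size=(n, 10))), noise_target,
        seed=SEED, model_spec=ModelSpec(kind="rf_regressor", n_estimators=100),
    )
    print(
        f"RF regression on pure U(0,100) noise: RMSE {rmse:.1f} vs theoretical "
        f"floor 100/sqrt(12) = {100 / np.sqrt(12):.1f}"
    )


if __name__ == "__main__":
    main()
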