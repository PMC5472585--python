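# rxnaudit

A predictability audit for organic reaction outcomes. Given a corpus of
reactions (reaction SMILES plus reported yield %, time h, solvent,
temperature), `rxnaudit` answers two questions:

1. **How well can a binary outcome be predicted** — high vs low yield, slow
   vs rapid reaction — from standard machine-readable representations:
   whole-molecule descriptors, signed atom-pair difference fingerprints, and
   mined maximum-common-substructure ("chemical word") features?
2. **Is the residual error reducible?** Using the Cover–Hart
   nearest-neighbor bracket on the Bayes error R*,

       (1 − √(1 − 2·R_NN)) / 2 ≤ R* ≤ R_NN,

   where R_NN is the leave-one-out 1-NN error on the same features: if the
   cross-validated classifier error sits at the bracket, no classifier on
   those features can do substantially better — the error is intrinsic to
   the representation, not to the model.

The package is aimed at cheminformaticians and ML practitioners who want to
quantify, rather than assume, the ceiling that a molecular representation
places on reaction-outcome prediction. Because real literature corpora are
proprietary, the package ships generators for synthetic study conditions
with analytically known answers (planted label rules, controlled label
noise ε — which is exactly the Bayes error of the generated labels — messy
records with exact cleaning manifests), so every claim the audit makes is
testable against ground truth.

## Layout

* `src/rxnaudit/` — the library: `reaction_io` (parse/dedup/label),
  `descriptors`, `fingerprints`, `cld` (feature families), `classify`
  (four-fold CV curves), `bayes_bounds` (irreducible-error bracket),
  `synthetic_data` (generators), `reporting` + `cli` (pipeline, manifests,
  `audit` command).
* `analysis/01…07_*.py` — the audit as a sequence of narrative drivers
  (generate → clean → descriptor models → fingerprint models → Bayes
  bounds → chemical words → diagnostics), writing tables under `results/`.
* `docs/methods.md` — models, parameter choices, generator design, and
  limitations.

## Worked example

```python
import numpy as np
from rxnaudit.synthetic_data import PlantedReactionSpec, planted_reactions
from rxnaudit.descriptors import ReactionFeaturizer
from rxnaudit.classify import FeatureMatrix, ModelSpec, cv_train_eval
from rxnaudit.bayes_bounds import bound_estimate

# 4,000 literature-style reactions whose hidden label rule is corrupted
# with 20% label noise -> the Bayes error of the labels is exactly 0.20
records, truth = planted_reactions(
    PlantedReactionSpec(n_reactions=4000, label_noise=0.2, seed=7)
)
fz = ReactionFeaturizer().fit(records)
fm = FeatureMatrix.from_array(
    fz.transform(records), fz.feature_names,
    "descriptor", [r.reaction_id for r in records],
)
y = np.array([truth.observed_labels[r.reaction_id] for r in records])

res = cv_train_eval(fm, y, ModelSpec(n_estimators=100), folds=4, seed=0)
est = bound_estimate(fm.values, y)
print(f"planted Bayes error: {truth.bayes_error:.3f}")
print(f"RF 4-fold CV error:  {res.mean_error:.3f} ± {res.std_error:.3f}")
print(f"Bayes bracket:       [{est.lower:.3f}, {est.upper:.3f}]")
```

Output (seeds as above):

```
planted Bayes error: 0.200
RF 4-fold CV error:  0.285 ± 0.009
Bayes bracket:       [0.244, 0.368]
```

Reading: the forest's 28% error is NOT evidence of a weak model — the
bracket says at least ~24% error is unavoidable on this finite sample of
this representation, consistent with the 20% planted noise floor (the
nearest-neighbor estimate carries upward finite-sample bias at n = 4,000 in
~400 dimensions; at n = 20,000 the bracket tightens toward 0.20, as the
acceptance checks verify). Rerunning with `label_noise=0` drives the RF
error below 2% and the bracket toward [0, 0.05]: the pipeline tells
reducible from irreducible error.

The same audit from the shell:

```bash
audit simulate reactions --spec spec.yaml --out data/
audit clean --input data/reactions.csv --target yield --out-dir cleaned/
audit featurize --input cleaned/labeled.csv --features descriptors --out feat.csv
audit train --features feat.csv --n-estimators 100 --seed 0 --out-dir run/
audit bounds --features feat.csv --seed 0
```

or end-to-end with a YAML config and a digest-stamped run manifest:
`audit run --config config.yaml`.

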