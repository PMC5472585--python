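"""Pipeline orchestration, run manifests, and table/figure emission.

A run is driven by a single YAML-able config dict and a single top-level
seed; every stage draws its randomness from a named substream of that seed,
so e.g. changing the CLD-mining stage cannot perturb the classifier folds.
Every artifact written during a run is recorded in a :class:`RunManifest`
with a content digest, making reruns byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .bayes_bounds import BoundCurve, bound_curve, bound_estimate
from .classify import (
    Curve,
    FeatureMatrix,
    ModelSpec,
    cv_train_eval,
    error_vs_dataset_size,
    error_vs_num_features,
)
from .cld import cld_features, mine_clds
from .descriptors import ReactionFeaturizer
from .fingerprints import fold, reaction_fingerprint
from .reaction_io import (
    LabelSpec,
    Target,
    deduplicate,
    label,
    median_threshold,
    parse_rsmi,
    read_reactions_csv,
    write_labeled_csv,
    write_rejections,
)
from .synthetic_data import PlantedReactionSpec, planted_reactions

__all__ = [
    "ConfigError",
    "RunManifest",
    "stage_seed",
    "write_curve_csv",
    "write_bound_curve_csv",
    "plot_error_curve",
    "assemble_features",
    "run_pipeline",
]


class ConfigError(ValueError):
    """The run configuration failed schema validation."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (kept below 2^31)."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seeds: dict[str, int]
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def record(self, path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "input_digests": self.input_digests,
                    "outputs": self.outputs,
                    "version": self.version,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def write_curve_csv(curve: Curve, path, x_name: str = "x") -> None:
    with open(path, "w") as fh:
        fh.write(f"{x_name},mean_error,std_error\n")
        for x, y, e in zip(curve.x, curve.y, curve.yerr):
            fh.write(f"{x:g},{y:.6f},{e:.6f}\n")


def write_bound_curve_csv(bc: BoundCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("n,lower,upper,r_nn\n")
        for n, lo, up, est in zip(bc.sizes, bc.lower, bc.upper, bc.estimates):
            fh.write(f"{n},{lo:.6f},{up:.6f},{est.r_nn:.6f}\n")


def plot_error_curve(
    curve: Curve, path, *, x_label: str, bounds: BoundCurve | None = None,
    log_x: bool = False,
) -> None:
    """Classifier-error curve with an optional Bayes-bound band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(curve.x, curve.y, yerr=curve.yerr, fmt="o-", color="crimson",
                label="CV error")
    if bounds is not None:
        ax.fill_between(bounds.sizes, bounds.lower, bounds.upper, color="steelblue",
                        alpha=0.3, label="Bayes error bracket")
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel(x_label)
    ax.set_ylabel("misclassification rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# configuration schema


_DEFAULTS = {
    "target": "yield",
    "threshold": None,  # None -> LabelSpec default; "median" -> sample median
    "features": ["descriptors"],
    "fp_length": 256,
    "cld": {"n_pairs": 200, "k": 50, "vocab_molecules": 150},
    "model": {"kind": "rf", "n_estimators": 100},
    "folds": 4,
    "k_grid": None,
    "size_grid": None,
    "bounds_k": 1,
    "figures": False,
}


def validate_config(config: dict) -> dict:
    """Fill defaults and reject invalid configurations before any work."""
    cfg = {**_DEFAULTS, **config}
    if "seed" not in cfg or not isinstance(cfg["seed"], int):
        raise ConfigError("config requires an integer 'seed'")
    if "out_dir" not in cfg:
        raise ConfigError("config requires 'out_dir'")
    if "data" not in cfg or "kind" not in cfg["data"]:
        raise ConfigError("config requires data.kind")
    if cfg["data"]["kind"] not in ("planted", "csv"):
        raise ConfigError(f"unknown data.kind {cfg['data']['kind']!r}")
    if cfg["data"]["kind"] == "csv" and "path" not in cfg["data"]:
        raise ConfigError("data.kind=csv requires data.path")
    if not isinstance(cfg["folds"], int) or cfg["folds"] < 2:
        raise ConfigError("folds must be an integer >= 2")
    if cfg["target"] not in ("yield", "time"):
        raise ConfigError("target must be 'yield' or 'time'")
    unknown = set(cfg["features"]) - {"descriptors", "fingerprints", "cld"}
    if unknown:
        raise ConfigError(f"unknown feature families: {sorted(unknown)}")
    if not cfg["features"]:
        raise ConfigError("at least one feature family is required")
    return cfg


# ---------------------------------------------------------------------------
# feature assembly


def assemble_features(
    records: Sequence,
    *,
    families: Sequence[str] = ("descriptors",),
    fp_length: int = 256,
    cld_vocab=None,
    cld_k: int = 0,
    featurizer: ReactionFeaturizer | None = None,
) -> FeatureMatrix:
    """Build a FeatureMatrix for the requested feature families.

    Descriptor rows are substrate/product descriptor sums plus condition
    features; fingerprint columns are the folded signed reaction-difference
    fingerprint; CLD columns are binary top-k vocabulary matches.
    """
    blocks, names, fams = [], [], []
    parsed = [parse_rsmi(r.rsmi) for r in records]
    if "descriptors" in families:
        fz = featurizer or ReactionFeaturizer().fit(records)
        X = fz.transform(records)
        blocks.append(X)
        names += fz.feature_names
        fams += ["descriptor"] * (X.shape[1] - 2) + ["condition"] * 2
    if "fingerprints" in families:
        F = np.asarray([fold(reaction_fingerprint(p), fp_length) for p in parsed])
        blocks.append(F)
        names += [f"fp_{j}" for j in range(fp_length)]
        fams += ["fingerprint"] * fp_length
    if "cld" in families:
        if cld_vocab is None or cld_k < 1:
            raise ValueError("cld features need a vocabulary and cld_k >= 1")
        C = np.asarray([cld_features(p, cld_vocab, cld_k) for p in parsed])
        blocks.append(C)
        names += [f"cld_{j}" for j in range(cld_k)]
        fams += ["cld"] * cld_k
    return FeatureMatrix(
        np.hstack(blocks), names, fams, [r.reaction_id for r in records]
    )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: dict) -> RunManifest:
    """Execute clean -> featurize -> train/bounds -> report and return the manifest.

    Stage order and failure behavior: each stage raises with its name on the
    first error; nothing after a failed stage runs.
    """
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        s: stage_seed(cfg["seed"], s)
        for s in ("simulate", "clean", "featurize", "cld", "train", "bounds")
    }
    manifest = RunManifest(config=cfg, seeds=seeds)

    # --- data
    if cfg["data"]["kind"] == "planted":
        spec = PlantedReactionSpec(
            n_reactions=cfg["data"].get("n_reactions", 1000),
            label_noise=cfg["data"].get("label_noise", 0.0),
            duplicate_rate=cfg["data"].get("duplicate_rate", 0.0),
            missing_rate=cfg["data"].get("missing_rate", 0.0),
            seed=seeds["simulate"],
        )
        records, _truth = planted_reactions(spec)
        rejections: list[dict] = []
    else:
        path = cfg["data"]["path"]
        manifest.input_digests[str(path)] = sha256_file(path)
        records, rejections = read_reactions_csv(path)

    # --- clean
    target = Target(cfg["target"])
    records = deduplicate(records, target)
    threshold = cfg["threshold"]
    if threshold == "median":
        threshold = median_threshold(records, target)
    dataset = label(records, LabelSpec(target, threshold))
    labeled_path = out / "labeled.csv"
    write_labeled_csv(dataset, labeled_path)
    manifest.record(labeled_path)
    if rejections:
        rej_path = out / "rejections.jsonl"
        write_rejections(rejections, rej_path)
        manifest.record(rej_path)

    # --- featurize
    cld_vocab, cld_k = None, 0
    if "cld" in cfg["features"]:
        rng = np.random.default_rng(seeds["cld"])
        mols = []
        for rec in dataset.records:
            p = parse_rsmi(rec.rsmi)
            mols.extend(p.reactants)
            mols.extend(p.products)
        n_vocab = min(len(mols), cfg["cld"]["vocab_molecules"])
        pick = rng.choice(len(mols), size=n_vocab, replace=False)
        cld_vocab = mine_clds(
            [mols[i] for i in pick], cfg["cld"]["n_pairs"], seeds["cld"]
        )
        cld_k = min(cfg["cld"]["k"], len(cld_vocab))
        vocab_path = out / "cld_vocabulary.tsv"
        cld_vocab.save_tsv(vocab_path)
        manifest.record(vocab_path)
    family_map = {"descriptors": "descriptors", "fingerprints": "fingerprints", "cld": "cld"}
    fm = assemble_features(
        dataset.records,
        families=[family_map[f] for f in cfg["features"]],
        fp_length=cfg["fp_length"],
        cld_vocab=cld_vocab,
        cld_k=cld_k,
    )
    y = np.asarray(dataset.labels)

    # --- train + bounds
    model = ModelSpec(**cfg["model"])
    res = cv_train_eval(fm, y, model, cfg["folds"], seeds["train"])
    summary = {
        "cv_mean_error": res.mean_error,
        "cv_std_error": res.std_error,
        "fold_errors": res.fold_errors,
        "n": len(y),
        "n_features": fm.shape[1],
    }
    curves: dict[str, Curve] = {}
    if cfg["k_grid"]:
        curves["error_vs_num_features"] = error_vs_num_features(
            fm, y, cfg["k_grid"], model, seeds["train"], cfg["folds"]
        )
    if cfg["size_grid"]:
        curves["error_vs_dataset_size"] = error_vs_dataset_size(
            fm, y, cfg["size_grid"], model, seeds["train"], cfg["folds"]
        )
    est = bound_estimate(fm.values, y, k=cfg["bounds_k"], seed=seeds["bounds"])
    summary["bayes_bounds"] = est.to_dict()
    bcurve = None
    if cfg["size_grid"]:
        bcurve = bound_curve(fm.values, y, cfg["size_grid"], cfg["bounds_k"], seeds["bounds"])

    # --- report
    for name, curve in curves.items():
        path = out / f"{name}.csv"
        x_name = "n_features" if "features" in name else "n"
        write_curve_csv(curve, path, x_name)
        manifest.record(path)
    if bcurve is not None:
        path = out / "bounds_vs_dataset_size.csv"
        write_bound_curve_csv(bcurve, path)
        manifest.record(path)
        if cfg["figures"] and "error_vs_dataset_size" in curves:
            fig_path = out / "error_vs_dataset_size.png"
            plot_error_curve(
                curves["error_vs_dataset_size"], fig_path,
                x_label="reactions", bounds=bcurve,
            )
            manifest.record(fig_path)
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest.record(summary_path)
    manifest.save(out / "manifest.json")
    return manifest
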