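"""Synthetic inputs with known ground truth.

Real literature reaction corpora are proprietary, so every claim this package
makes is validated on generated data whose answers are known by construction:

* :func:`gaussian_dataset` — two Gaussian classes with a closed-form Bayes
  error, the oracle for the nearest-neighbor Bayes-bound estimator;
* :func:`planted_features` — a plain tabular problem (informative + noise
  columns) for feature-selection and learning-curve behavior;
* :func:`planted_reactions` — literature-style reaction records (RSMI +
  yield/time/conditions) whose labels follow a hidden rule over designated
  structural fragments, with controllable label noise, duplicate reports and
  missing fields, plus a truth log naming the informative descriptor columns;
* :func:`messy_records` — a raw CSV exercising every rejection and
  deduplication path, with a manifest stating the exact expected outcome.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .reaction_io import ReactionRecord

__all__ = [
    "GaussianSpec",
    "gaussian_dataset",
    "planted_features",
    "PlantedReactionSpec",
    "PlantedTruth",
    "planted_reactions",
    "messy_records",
    "INFORMATIVE_FRAGMENTS",
]


# ---------------------------------------------------------------------------
# Gaussian two-class data with analytic Bayes error


@dataclass(frozen=True)
class GaussianSpec:
    """Two spherical unit-variance Gaussian classes in d dimensions.

    Class means sit at -delta/2 and +delta/2 on the first axis and 0
    elsewhere, so only the first coordinate is informative. For equal priors
    the Bayes error is Phi(-delta/2).
    """

    d: int = 5
    delta: float = 2.0
    priors: tuple[float, float] = (0.5, 0.5)
    n: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not math.isclose(sum(self.priors), 1.0) or min(self.priors) <= 0:
            raise ValueError("priors must be positive and sum to 1")

    @property
    def analytic_bayes_error(self) -> float:
        pi0, pi1 = self.priors
        if self.delta == 0:
            return float(min(pi0, pi1))
        t = math.log(pi0 / pi1) / self.delta
        return float(
            pi1 * norm.cdf(-self.delta / 2 + t) + pi0 * norm.cdf(-self.delta / 2 - t)
        )


def gaussian_dataset(spec: GaussianSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample (X, y) from the spec and return the analytic Bayes error."""
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n) < spec.priors[1]).astype(int)
    X = rng.standard_normal((spec.n, spec.d))
    X[:, 0] += np.where(y == 1, spec.delta / 2, -spec.delta / 2)
    return X, y, spec.analytic_bayes_error


# ---------------------------------------------------------------------------
# Tabular planted-feature data


def planted_features(
    n: int,
    n_informative: int = 10,
    n_noise: int = 90,
    effect_size: float = 1.0,
    label_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Standard-normal features with a linear planted rule on the first block.

    The clean label is 1 iff ``effect_size * sum(informative) / sqrt(k) > 0``
    and is then flipped with probability ``label_noise`` (which therefore is
    the Bayes error of the observed labels). Returns (X, y, informative
    column names); columns are named ``inf_##`` and ``noise_##``.
    """
    if not 0 <= label_noise < 0.5:
        raise ValueError("label_noise must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_informative + n_noise))
    score = effect_size * X[:, :n_informative].sum(axis=1) / math.sqrt(n_informative)
    y = (score > 0).astype(int)
    flips = rng.random(n) < label_noise
    y[flips] = 1 - y[flips]
    names = [f"inf_{j:02d}" for j in range(n_informative)] + [
        f"noise_{j:02d}" for j in range(n_noise)
    ]
    return X, y, names[:n_informative]


# ---------------------------------------------------------------------------
# Planted reaction corpora

# (fragment SMILES, dedicated descriptor, weight sign). Each fragment is
# independently present with probability 1/2 and is detected one-to-one by a
# structural-motif descriptor. Signs are mixed, with chemically related
# fragments paired opposite (ketone/acid, benzene/pyridine, hydroxyl/ether,
# amine/nitro, nitrile/thiol), so that aggregate descriptors — molecular
# weight, total carbonyl or aromatic-ring or H-donor counts — stay
# uncorrelated with the label rule and the signal is carried by the
# fragment-specific columns.
INFORMATIVE_FRAGMENTS: tuple[tuple[str, str, int], ...] = (
    ("C#N", "fr_nitrile", +1),
    ("[N+](=O)[O-]", "fr_nitro", -1),
    ("C(=O)O", "fr_COO", -1),
    ("c1ccccc1", "fr_benzene", -1),
    ("c1ccncc1", "fr_pyridine", +1),
    ("S", "fr_SH", -1),
    ("O", "fr_Al_OH", +1),
    ("N", "fr_NH2", +1),
    ("C(=O)C", "fr_ketone", +1),
    ("OC", "fr_ether", -1),
)

# label-neutral distractor fragments
_DISTRACTOR_FRAGMENTS = ("F", "Cl", "Br", "C")

# transformation templates: (name, product suffix appended to the chain
# terminus, agent SMILES)
_TEMPLATES = (
    ("chlorination", "Cl", "ClCl"),
    ("bromination", "Br", "BrBr"),
    ("hydroxylation", "O", "OO"),
)

_SOLVENTS = ("water", "ethanol", "methanol", "DMF", "THF", "toluene", "DCM", "MeCN")
_TEMPERATURES = (-78.0, 0.0, 25.0, 25.0, 25.0, 60.0, 80.0, 110.0)

_CHAIN_LENGTHS = (2, 3, 4, 5, 6, 7, 8)


@dataclass(frozen=True)
class PlantedReactionSpec:
    """Study conditions for a planted reaction corpus.

    ``label_noise`` is the probability that the clean rule-derived label is
    flipped; with the default deterministic rule (``effect_size=inf``) it
    equals the Bayes error of the observed labels given the structure. A
    finite ``effect_size`` beta samples the clean label from a logistic
    P(y=1) = sigmoid(beta * score), making the rule itself stochastic.
    ``duplicate_rate`` is the per-record probability of an extra report of
    the same reaction with a perturbed outcome; ``missing_rate`` the
    per-field probability that solvent/temperature/time are absent.
    """

    n_reactions: int = 1000
    label_noise: float = 0.0
    effect_size: float = math.inf
    duplicate_rate: float = 0.0
    missing_rate: float = 0.0
    yield_threshold: float = 65.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not (0 <= self.duplicate_rate < 1 and 0 <= self.missing_rate < 1):
            raise ValueError("rates must lie in [0, 1)")


@dataclass
class PlantedTruth:
    """Hidden ground truth for a planted corpus.

    ``informative_features`` names the canonical descriptor columns carrying
    the planted signal (the dedicated substrate/product fragment counts);
    ``fragment_presence`` records, per base reaction, which informative
    fragments are present, so the full informative column set — including
    descriptor aliases that coincide with a fragment indicator — can be
    identified in any realized feature matrix (:func:`informative_columns`).
    """

    informative_features: list[str]  # canonical descriptor column names
    fragment_descriptors: list[str]
    fragment_presence: dict[str, tuple[int, ...]]
    bayes_error: float
    clean_labels: dict[str, int]
    observed_labels: dict[str, int]
    scores: dict[str, float]
    n_duplicates: int
    duplicate_ids: list[str]
    spec: PlantedReactionSpec

    def base_id(self, reaction_id: str) -> str:
        return reaction_id[:-4] if reaction_id.endswith("_dup") else reaction_id

    def label_for(self, reaction_id: str) -> int:
        return self.observed_labels[self.base_id(reaction_id)]

    def presence_for(self, reaction_id: str) -> tuple[int, ...]:
        return self.fragment_presence[self.base_id(reaction_id)]


def _build_substrate(chain_len: int, fragments: Sequence[str]) -> str:
    """Linear carbon chain with fragment branches distributed along it.

    Each chain atom takes at most two branches (valence-safe for the fragment
    set used); the chain terminus is kept bare so templates can append there.
    """
    # keep at most two branches per chain atom (valence-safe); extend the
    # chain if the fragment draw needs more slots
    chain_len = max(chain_len, math.ceil(len(fragments) / 2) + 1)
    slots = max(chain_len - 1, 1)
    branches: dict[int, list[str]] = {}
    for i, frag in enumerate(fragments):
        pos = i % slots
        branches.setdefault(pos, []).append(frag)
    parts = []
    for pos in range(chain_len):
        atom = "C"
        for frag in branches.get(pos, ()):
            atom += f"({frag})"
        parts.append(atom)
    return "".join(parts)


def _score_distribution() -> dict[int, float]:
    """Exact pmf of the signed fragment score (sum of +/-1 coin flips)."""
    pmf = {0: 1.0}
    for _, _, sign in INFORMATIVE_FRAGMENTS:
        nxt: dict[int, float] = {}
        for s, p in pmf.items():
            for present in (0, 1):
                nxt[s + sign * present] = nxt.get(s + sign * present, 0.0) + p / 2
        pmf = nxt
    return pmf


def _bayes_error(spec: PlantedReactionSpec) -> float:
    """Exact Bayes error of the observed labels given fragment presence."""
    eps = spec.label_noise
    if math.isinf(spec.effect_size):
        return eps
    pmf = _score_distribution()
    inner = sum(
        p * min(_sigmoid(spec.effect_size * s), 1 - _sigmoid(spec.effect_size * s))
        for s, p in pmf.items()
    )
    return eps + (1 - 2 * eps) * inner


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def planted_reactions(
    spec: PlantedReactionSpec,
) -> tuple[list[ReactionRecord], PlantedTruth]:
    """Generate a literature-style reaction corpus with planted structure.

    Substrates are built from a small scaffold grammar (alkyl chains with the
    fragment set above as branches); the product appends a template group
    (chlorination / bromination / hydroxylation) at the chain terminus, and
    the agent is the corresponding reagent. The clean label is a threshold on
    the signed count of informative fragments; observed labels flip with
    probability ``label_noise``. Yields are back-generated so that strict
    thresholding at ``yield_threshold`` reproduces the observed labels
    exactly (class 1 uniform on [threshold+5, 100], class 0 on
    [0, threshold-5]); times are log-uniform on [0.25 h, 96 h], mimicking the
    heavy "left overnight" tail, and carry no planted signal.

    Each base reaction has a unique (substrate, template) pair, so the only
    duplicate transformations are the deliberately injected ones.
    """
    rng = np.random.default_rng(spec.seed)
    n_frag = len(INFORMATIVE_FRAGMENTS)
    records: list[ReactionRecord] = []
    clean_labels: dict[str, int] = {}
    observed_labels: dict[str, int] = {}
    fragment_presence: dict[str, tuple[int, ...]] = {}
    scores: dict[str, float] = {}
    duplicate_ids: list[str] = []
    seen: set[tuple[str, int]] = set()

    def _draw_yield(label: int) -> float:
        t = spec.yield_threshold
        lo, hi = (t + 5, 100.0) if label == 1 else (0.0, t - 5)
        return float(np.round(rng.uniform(lo, hi), 1))

    for i in range(spec.n_reactions):
        for _attempt in range(200):
            present = rng.random(n_frag) < 0.5
            distract = rng.random(len(_DISTRACTOR_FRAGMENTS)) < 0.3
            chain_len = int(rng.choice(_CHAIN_LENGTHS))
            t_idx = int(rng.integers(len(_TEMPLATES)))
            frags = [f for (f, _, _), p in zip(INFORMATIVE_FRAGMENTS, present) if p]
            frags += [f for f, p in zip(_DISTRACTOR_FRAGMENTS, distract) if p]
            substrate = _build_substrate(chain_len, frags)
            key = (substrate, t_idx)
            if key not in seen:
                seen.add(key)
                break
        else:
            raise RuntimeError("could not draw a fresh substrate/template pair")

        score = float(
            sum(sign * int(p) for (_, _, sign), p in zip(INFORMATIVE_FRAGMENTS, present))
        )
        if math.isinf(spec.effect_size):
            clean = int(score > 0)
        else:
            clean = int(rng.random() < _sigmoid(spec.effect_size * score))
        observed = clean if rng.random() >= spec.label_noise else 1 - clean

        _, suffix, agent = _TEMPLATES[t_idx]
        rsmi = f"{substrate}>{agent}>{substrate}{suffix}"
        rid = f"rx{i:06d}"
        time_h = float(np.round(np.exp(rng.uniform(np.log(0.25), np.log(96.0))), 2))
        solvent: str | None = str(rng.choice(_SOLVENTS))
        temperature: float | None = float(rng.choice(_TEMPERATURES))
        if rng.random() < spec.missing_rate:
            solvent = None
        if rng.random() < spec.missing_rate:
            temperature = None
        if rng.random() < spec.missing_rate:
            time_h = None  # type: ignore[assignment]

        records.append(
            ReactionRecord(rid, rsmi, _draw_yield(observed), time_h, solvent, temperature)
        )
        clean_labels[rid] = clean
        observed_labels[rid] = observed
        fragment_presence[rid] = tuple(int(p) for p in present)
        scores[rid] = score

        if rng.random() < spec.duplicate_rate:
            # a second literature report of the same transformation with a
            # (slightly) different outcome in the same class range
            drid = f"{rid}_dup"
            records.append(
                ReactionRecord(
                    drid,
                    rsmi,
                    _draw_yield(observed),
                    float(np.round(np.exp(rng.uniform(np.log(0.25), np.log(96.0))), 2)),
                    solvent,
                    temperature,
                )
            )
            duplicate_ids.append(drid)

    fragment_descriptors = [d for _, d, _ in INFORMATIVE_FRAGMENTS]
    informative = [f"s_{d}" for d in fragment_descriptors] + [
        f"p_{d}" for d in fragment_descriptors
    ]
    truth = PlantedTruth(
        informative_features=informative,
        fragment_descriptors=fragment_descriptors,
        fragment_presence=fragment_presence,
        bayes_error=_bayes_error(spec),
        clean_labels=clean_labels,
        observed_labels=observed_labels,
        scores=scores,
        n_duplicates=len(duplicate_ids),
        duplicate_ids=duplicate_ids,
        spec=spec,
    )
    return records, truth


def informative_columns(
    feature_matrix, truth: PlantedTruth, min_corr: float = 0.9999
) -> list[str]:
    """All feature columns that are exact indicators of a planted fragment.

    Real descriptor sets are collinear: several descriptors count the same
    structural motif (e.g. a carboxylic-acid group is counted by more than
    one named descriptor). The informative set of a realized feature matrix
    is therefore not just the canonical columns in the truth log but every
    column whose values coincide (|Pearson r| >= ``min_corr``) with one of
    the planted fragment-presence indicators.
    """
    V = np.asarray(feature_matrix.values, dtype=float)
    ids = feature_matrix.row_ids
    F = np.asarray([truth.presence_for(r) for r in ids], dtype=float)  # (n, 10)
    sdF = F.std(axis=0)
    if np.any(sdF == 0):
        raise ValueError("a fragment is constant over these rows")
    Fz = (F - F.mean(axis=0)) / sdF
    sdV = V.std(axis=0)
    Vz = (V - V.mean(axis=0)) / np.where(sdV == 0, 1.0, sdV)
    corr = np.abs(Fz.T @ Vz) / len(ids)  # (10, p)
    corr[:, sdV == 0] = 0.0
    hit = corr.max(axis=0) >= min_corr
    return [c for c, h in zip(feature_matrix.columns, hit) if h]


# ---------------------------------------------------------------------------
# Messy literature-style CSV


def messy_records(n: int, seed: int = 0) -> tuple[str, dict]:
    """A raw reaction CSV exercising every rejection and dedup path.

    Returns (csv_text, manifest). Rows are a seeded mixture of valid records,
    malformed RSMI, unparseable SMILES, rows missing both outcomes, rows with
    out-of-range yields, rows missing only the yield, and duplicate reports
    with conflicting outcomes. The manifest states, by construction (not by
    running the cleaning pipeline), the exact expected counts after parsing,
    deduplication and labeling for both targets, using strict thresholds of
    65 (yield) and 12 h (time) and max-yield / min-time duplicate survival.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    categories = ("valid", "malformed", "unparseable", "missing_both", "bad_yield",
                  "missing_yield", "duplicate")
    probs = (0.55, 0.07, 0.07, 0.07, 0.06, 0.08, 0.10)

    header = "reaction_id,rsmi,yield,time,solvent,temperature"
    rows = [header]
    manifest_counts = {c: 0 for c in categories}
    # per dedup-key outcome bookkeeping: key -> list of (yield, time)
    outcomes: dict[str, list[tuple[float | None, float]]] = {}
    valid_rsmis: list[str] = []

    def _fresh_rsmi() -> str:
        i = len(valid_rsmis)
        chain = "C" * (i + 2)
        return f"{chain}O>>{chain}=O"

    for i in range(n):
        cat = "valid" if i == 0 else str(rng.choice(categories, p=probs))
        if cat == "duplicate" and not valid_rsmis:
            cat = "valid"
        rid = f"m{i:05d}"
        y = float(np.round(rng.uniform(0, 100), 1))
        t = float(np.round(rng.uniform(0.25, 96), 2))
        solvent = str(rng.choice(_SOLVENTS))
        temp = float(rng.choice(_TEMPERATURES))
        if cat == "valid":
            rsmi = _fresh_rsmi()
            valid_rsmis.append(rsmi)
            outcomes.setdefault(rsmi, []).append((y, t))
            rows.append(f"{rid},{rsmi},{y},{t},{solvent},{temp}")
        elif cat == "duplicate":
            rsmi = valid_rsmis[int(rng.integers(len(valid_rsmis)))]
            outcomes.setdefault(rsmi, []).append((y, t))
            rows.append(f"{rid},{rsmi},{y},{t},{solvent},{temp}")
        elif cat == "malformed":
            rows.append(f"{rid},CCO>CC=O,{y},{t},{solvent},{temp}")
        elif cat == "unparseable":
            rows.append(f"{rid},C(C>>CCO,{y},{t},{solvent},{temp}")
        elif cat == "missing_both":
            rsmi = _fresh_rsmi()
            valid_rsmis.append(rsmi)  # consume a chain length; row still rejected
            rows.append(f"{rid},{rsmi},,,{solvent},{temp}")
        elif cat == "bad_yield":
            rows.append(f"{rid},CCO>>CC=O,{float(np.round(rng.uniform(101, 250), 1))},{t},{solvent},{temp}")
        elif cat == "missing_yield":
            rsmi = _fresh_rsmi()
            valid_rsmis.append(rsmi)
            outcomes.setdefault(rsmi, []).append((None, t))
            rows.append(f"{rid},{rsmi},,{t},{solvent},{temp}")
        manifest_counts[cat] += 1

    n_parsed = (
        manifest_counts["valid"] + manifest_counts["duplicate"] + manifest_counts["missing_yield"]
    )
    n_keys = len(outcomes)
    yield_threshold, time_threshold = 65.0, 12.0
    # dedup survivors per target, by construction
    surv_yield = {
        k: max((y for y, _ in v if y is not None), default=None) for k, v in outcomes.items()
    }
    surv_time = {k: min(t for _, t in v) for k, v in outcomes.items()}
    yield_labelable = [v for v in surv_yield.values() if v is not None]
    manifest = {
        "n_rows": n,
        "category_counts": manifest_counts,
        "n_rejected": n - n_parsed,
        "rejected_by_reason": {
            "malformed_rsmi": manifest_counts["malformed"],
            "unparseable_smiles": manifest_counts["unparseable"],
            "missing_outcomes": manifest_counts["missing_both"],
            "yield_out_of_range": manifest_counts["bad_yield"],
        },
        "n_parsed": n_parsed,
        "n_dedup_survivors": n_keys,
        "yield": {
            "threshold": yield_threshold,
            "n_labelable": len(yield_labelable),
            "n_excluded_missing_target": n_keys - len(yield_labelable),
            "n_label_1": sum(v > yield_threshold for v in yield_labelable),
            "n_label_0": sum(v <= yield_threshold for v in yield_labelable),
            "survivor_values": {k: v for k, v in surv_yield.items() if v is not None},
        },
        "time": {
            "threshold": time_threshold,
            "n_labelable": n_keys,
            "n_excluded_missing_target": 0,
            "n_label_1": sum(v > time_threshold for v in surv_time.values()),
            "n_label_0": sum(v <= time_threshold for v in surv_time.values()),
            "survivor_values": surv_time,
        },
    }
    return "\n".join(rows) + "\n", manifest
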