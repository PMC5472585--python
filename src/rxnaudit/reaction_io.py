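"""Reading, validation, deduplication and binary labeling of reaction records.

Reaction datasets scraped from the literature arrive as reaction SMILES
(``reactants>agents>products``) with per-record yield (%), time (h), solvent
and temperature fields, any of which may be missing, and with the same
reaction frequently reported several times with conflicting outcomes. This
module turns such a table into a clean, deduplicated, binary-labeled dataset:

* records that cannot be parsed, or that report neither yield nor time, are
  rejected with a reason code;
* duplicate reports of the same transformation (same canonical reactant and
  product sets, agents ignored) are collapsed — the most favorable outcome
  survives (highest yield, shortest time);
* binary labels are assigned by a strict threshold on yield or time.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Target",
    "ReactionRecord",
    "ParsedReaction",
    "LabelSpec",
    "LabeledDataset",
    "RsmiParseError",
    "parse_rsmi",
    "dedup_key",
    "deduplicate",
    "label",
    "median_threshold",
    "read_reactions_csv",
    "read_rsmi_file",
    "write_labeled_csv",
    "write_rejections",
]


class Target(str, Enum):
    """Which reaction outcome is being classified."""

    YIELD = "yield"
    TIME = "time"


#: rejection reason codes used in the JSON-lines rejection log
REASON_MALFORMED_RSMI = "malformed_rsmi"
REASON_UNPARSEABLE_SMILES = "unparseable_smiles"
REASON_NO_REACTANTS_OR_PRODUCTS = "no_reactants_or_products"
REASON_MISSING_OUTCOMES = "missing_outcomes"
REASON_YIELD_OUT_OF_RANGE = "yield_out_of_range"
REASON_NONPOSITIVE_TIME = "nonpositive_time"
REASON_MISSING_TARGET = "missing_target"


class RsmiParseError(ValueError):
    """A reaction SMILES string could not be parsed.

    Attributes
    ----------
    reason : str
        One of the module-level ``REASON_*`` codes.
    """

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class ReactionRecord:
    """One literature-style reaction entry, possibly incomplete.

    ``yield_pct`` is a percentage in [0, 100]; ``time_h`` is in hours and
    strictly positive; either (but not both) may be ``None``.
    """

    reaction_id: str
    rsmi: str
    yield_pct: float | None = None
    time_h: float | None = None
    solvent: str | None = None
    temperature_c: float | None = None


@dataclass(frozen=True)
class ParsedReaction:
    """Parsed RSMI: rdkit molecules plus canonical SMILES for each side."""

    reactants: tuple
    agents: tuple
    products: tuple
    reactant_smiles: tuple[str, ...]
    agent_smiles: tuple[str, ...]
    product_smiles: tuple[str, ...]


@dataclass(frozen=True)
class LabelSpec:
    """Binary labeling rule: label 1 iff the target value is > ``threshold``.

    Defaults follow common practice for literature reaction sets: 65 (%) for
    yield, the median of typical yield distributions, and 12 (h) for time,
    the boundary between well-specified times and "left overnight" entries.
    For time, the positive class is therefore SLOW; "rapid" is the complement.
    """

    target: Target = Target.YIELD
    threshold: float | None = None
    positive_class_name: str = ""

    def resolved_threshold(self) -> float:
        if self.threshold is not None:
            return float(self.threshold)
        return 65.0 if self.target == Target.YIELD else 12.0

    def resolved_positive_name(self) -> str:
        if self.positive_class_name:
            return self.positive_class_name
        return "high_yield" if self.target == Target.YIELD else "slow"


@dataclass
class LabeledDataset:
    """Records plus an aligned binary label vector."""

    records: list[ReactionRecord]
    labels: list[int]
    label_spec: LabelSpec
    n_excluded: int = 0

    def __post_init__(self):
        if len(self.records) != len(self.labels):
            raise ValueError("labels must align with records")


def _parse_side(text: str) -> tuple[tuple, tuple[str, ...]]:
    """Parse a dot-separated SMILES list; '' means no molecules."""
    if text == "":
        return (), ()
    mols, smis = [], []
    for part in text.split("."):
        mol = Chem.MolFromSmiles(part)
        if mol is None:
            raise RsmiParseError(
                f"unparseable SMILES component {part!r}", REASON_UNPARSEABLE_SMILES
            )
        mols.append(mol)
        smis.append(Chem.MolToSmiles(mol))
    return tuple(mols), tuple(smis)


def parse_rsmi(text: str) -> ParsedReaction:
    """Parse a reaction SMILES ``reactants>agents>products``.

    Requires exactly two ``>`` separators, at least one reactant and one
    product; the agent field may be empty. Canonical SMILES are retained so
    that deduplication keys are spelling-invariant.

    Raises
    ------
    RsmiParseError
        If the separator structure is wrong, any component fails to parse,
        or a side that must be non-empty is empty.
    """
    parts = text.split(">")
    if len(parts) != 3:
        raise RsmiParseError(
            f"expected 2 '>' separators, got {len(parts) - 1} in {text!r}",
            REASON_MALFORMED_RSMI,
        )
    reactants, r_smis = _parse_side(parts[0])
    agents, a_smis = _parse_side(parts[1])
    products, p_smis = _parse_side(parts[2])
    if not reactants or not products:
        raise RsmiParseError(
            "reaction must have >=1 reactant and >=1 product",
            REASON_NO_REACTANTS_OR_PRODUCTS,
        )
    return ParsedReaction(reactants, agents, products, r_smis, a_smis, p_smis)


def dedup_key(record_or_parsed) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Canonical, agent-insensitive identity of a transformation.

    The key is (sorted canonical reactant SMILES, sorted canonical product
    SMILES); agents, solvent and temperature are deliberately ignored, since
    the same reaction is typically reported under many conditions.
    """
    parsed = (
        record_or_parsed
        if isinstance(record_or_parsed, ParsedReaction)
        else parse_rsmi(record_or_parsed.rsmi)
    )
    return (tuple(sorted(parsed.reactant_smiles)), tuple(sorted(parsed.product_smiles)))


def deduplicate(
    records: Sequence[ReactionRecord], target: Target | str = Target.YIELD
) -> list[ReactionRecord]:
    """Collapse duplicate reports of the same transformation.

    For ``target='yield'`` the surviving record carries the highest reported
    yield among its duplicates; for ``target='time'`` the shortest reported
    time. Records whose target value is missing never displace one that has
    it. Output order is deterministic (sorted by dedup key).
    """
    target = Target(target)
    groups: dict[tuple, list[ReactionRecord]] = {}
    for rec in records:
        groups.setdefault(dedup_key(rec), []).append(rec)

    def _value(rec: ReactionRecord) -> float:
        v = rec.yield_pct if target == Target.YIELD else rec.time_h
        if v is None:
            # missing target sorts worse than any present value
            return -math.inf if target == Target.YIELD else math.inf
        return v

    survivors = []
    for key in sorted(groups):
        group = groups[key]
        if target == Target.YIELD:
            best = max(group, key=lambda r: (_value(r), r.reaction_id))
        else:
            best = min(group, key=lambda r: (_value(r), r.reaction_id))
        survivors.append(best)
    return survivors


def label(records: Sequence[ReactionRecord], spec: LabelSpec) -> LabeledDataset:
    """Assign binary labels by a strict threshold on the target value.

    label = 1 iff value > threshold; a value exactly at the threshold gets
    label 0 (so a median threshold puts the median itself in the low class).
    Records with the target value missing are excluded and counted.
    """
    threshold = spec.resolved_threshold()
    kept: list[ReactionRecord] = []
    labels: list[int] = []
    n_excluded = 0
    for rec in records:
        value = rec.yield_pct if spec.target == Target.YIELD else rec.time_h
        if value is None:
            n_excluded += 1
            continue
        kept.append(rec)
        labels.append(1 if value > threshold else 0)
    if not kept:
        raise ValueError("no labelable records")
    return LabeledDataset(kept, labels, spec, n_excluded)


def median_threshold(
    records: Sequence[ReactionRecord], target: Target | str = Target.YIELD
) -> float:
    """Sample median of the target values (lower-middle convention for even n)."""
    target = Target(target)
    values = sorted(
        (rec.yield_pct if target == Target.YIELD else rec.time_h)
        for rec in records
        if (rec.yield_pct if target == Target.YIELD else rec.time_h) is not None
    )
    if not values:
        raise ValueError(f"no records with {target.value} present")
    return float(values[(len(values) - 1) // 2])


def _opt_float(text: str) -> float | None:
    text = (text or "").strip()
    if text == "" or text.lower() in ("na", "nan", "none"):
        return None
    return float(text)


def read_reactions_csv(
    path, *, delimiter: str | None = None
) -> tuple[list[ReactionRecord], list[dict]]:
    """Read a reaction table with columns ``rsmi,yield,time,solvent,temperature``.

    Returns (accepted records, rejection log). Each rejection entry is a dict
    with ``reaction_id``, ``reason`` and ``detail`` and is suitable for
    :func:`write_rejections`. Validation applied per row:

    * the RSMI must parse (two separators, all components valid SMILES);
    * at least one of yield/time must be present;
    * a present yield must lie in [0, 100]; a present time must be > 0.
    """
    records, rejections = [], []
    with open(path, newline="") as fh:
        if delimiter is None:
            delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or "rsmi" not in reader.fieldnames:
            raise ValueError("header with an 'rsmi' column is required")
        for i, row in enumerate(reader):
            rid = row.get("reaction_id") or f"row{i}"

            def _reject(reason, detail=""):
                rejections.append(
                    {"reaction_id": rid, "reason": reason, "detail": detail}
                )

            try:
                parse_rsmi(row["rsmi"])
            except RsmiParseError as exc:
                _reject(exc.reason, str(exc))
                continue
            try:
                y = _opt_float(row.get("yield", ""))
                t = _opt_float(row.get("time", ""))
                temp = _opt_float(row.get("temperature", ""))
            except ValueError as exc:
                _reject("bad_numeric_field", str(exc))
                continue
            if y is None and t is None:
                _reject(REASON_MISSING_OUTCOMES)
                continue
            if y is not None and not (0.0 <= y <= 100.0):
                _reject(REASON_YIELD_OUT_OF_RANGE, f"yield={y}")
                continue
            if t is not None and t <= 0:
                _reject(REASON_NONPOSITIVE_TIME, f"time={t}")
                continue
            solvent = (row.get("solvent") or "").strip() or None
            records.append(
                ReactionRecord(rid, row["rsmi"], y, t, solvent, temp)
            )
    return records, rejections


def read_rsmi_file(path) -> list[ReactionRecord]:
    """Read a plain ``.rsmi`` file, one reaction SMILES per line (no outcomes).

    An optional tab-separated identifier may follow the RSMI. Unparseable
    lines raise; this format is for pre-cleaned inputs.
    """
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rsmi, _, rid = line.partition("\t")
            parse_rsmi(rsmi)
            records.append(ReactionRecord(rid or f"line{i}", rsmi))
    return records


def write_labeled_csv(dataset: LabeledDataset, path) -> None:
    """Write the cleaned dataset as CSV with an added ``label`` column."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["reaction_id", "rsmi", "yield", "time", "solvent", "temperature", "label"]
        )
        for rec, lab in zip(dataset.records, dataset.labels):
            writer.writerow(
                [
                    rec.reaction_id,
                    rec.rsmi,
                    "" if rec.yield_pct is None else rec.yield_pct,
                    "" if rec.time_h is None else rec.time_h,
                    rec.solvent or "",
                    "" if rec.temperature_c is None else rec.temperature_c,
                    lab,
                ]
            )


def write_rejections(rejections: Iterable[dict], path) -> None:
    """Write the rejection log as JSON lines."""
    with open(path, "w") as fh:
        for entry in rejections:
            fh.write(json.dumps(entry) + "\n")
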