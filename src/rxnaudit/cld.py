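"""Chemical-linguistic descriptors: mined maximum-common-substructure features.

The frequency of maximum common substructures (MCS) over large collections of
molecule pairs follows a power law like word-fragment frequencies in natural
language — hence "chemical words". This module mines such a vocabulary by
sampling molecule pairs, computing their connected MCS (element, bond order
and aromaticity required to match), ranking the patterns by occurrence
frequency, and exposing the top-K patterns as binary structural features for
reactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdFMCS

from .reaction_io import ParsedReaction

__all__ = ["Substructure", "CLDVocabulary", "mcs", "mine_clds", "cld_features"]

DEFAULT_MIN_SIZE = 3  # heavy atoms; smaller motifs carry no "word" content


@dataclass(frozen=True)
class Substructure:
    """A connected substructure pattern (SMARTS-like query).

    The pattern preserves the aromatic vs single/double bond distinction.
    ``approximate`` marks a best-so-far result returned on MCS timeout.
    """

    pattern: str
    atom_count: int
    bond_count: int = 0
    approximate: bool = False

    def query_mol(self):
        q = Chem.MolFromSmarts(self.pattern)
        if q is None:
            raise ValueError(f"pattern does not parse: {self.pattern!r}")
        return q


def _canonical_pattern(smarts: str) -> str:
    """Canonical key for aggregating identical substructures across pairs."""
    q = Chem.MolFromSmarts(smarts)
    if q is None:
        return smarts
    try:
        return Chem.MolToSmiles(q)
    except Exception:
        return smarts


def mcs(
    mol_a,
    mol_b,
    timeout_s: int = 10,
    min_size: int = DEFAULT_MIN_SIZE,
) -> Substructure | None:
    """Maximum (by atom count) connected common substructure of two molecules.

    Atoms must match by element, bonds by order with aromatic bonds distinct
    from single/double; ring-bond-to-ring-bond matching is not enforced.
    Returns ``None`` when the best common substructure has fewer than
    ``min_size`` heavy atoms. On timeout the best result found so far is
    returned, flagged ``approximate``.
    """
    res = rdFMCS.FindMCS(
        [mol_a, mol_b],
        maximizeBonds=False,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        ringMatchesRingOnly=False,
        completeRingsOnly=False,
        matchValences=False,
        timeout=timeout_s,
    )
    if res.numAtoms < min_size or not res.smartsString:
        return None
    return Substructure(
        pattern=res.smartsString,
        atom_count=res.numAtoms,
        bond_count=res.numBonds,
        approximate=bool(res.canceled),
    )


@dataclass
class CLDVocabulary:
    """Ranked "chemical word" vocabulary: (substructure, frequency) pairs.

    Frequencies are occurrence counts over the sampled molecule pairs and are
    non-increasing down the ranking; sampling metadata makes the vocabulary
    reproducible from (molecule list, n_pairs, seed).
    """

    entries: list[tuple[Substructure, int]]
    n_pairs: int
    seed: int

    def __post_init__(self):
        freqs = [f for _, f in self.entries]
        if any(f < 1 for f in freqs):
            raise ValueError("frequencies must be >= 1")
        if any(a < b for a, b in zip(freqs, freqs[1:])):
            raise ValueError("frequencies must be non-increasing")

    def __len__(self):
        return len(self.entries)

    def top(self, k: int) -> list[Substructure]:
        if k > len(self.entries):
            raise ValueError(f"requested top {k} of a {len(self.entries)}-entry vocabulary")
        return [s for s, _ in self.entries[:k]]

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_pairs={self.n_pairs}\tseed={self.seed}\n")
            for sub, freq in self.entries:
                fh.write(f"{sub.pattern}\t{freq}\n")

    @classmethod
    def load_tsv(cls, path) -> "CLDVocabulary":
        entries = []
        n_pairs, seed = 0, 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    meta = dict(
                        kv.split("=") for kv in line[1:].strip().split("\t") if "=" in kv
                    )
                    n_pairs = int(meta.get("n_pairs", 0))
                    seed = int(meta.get("seed", 0))
                    continue
                if not line:
                    continue
                pattern, freq = line.split("\t")
                q = Chem.MolFromSmarts(pattern)
                entries.append(
                    (
                        Substructure(
                            pattern,
                            atom_count=q.GetNumAtoms() if q else 0,
                            bond_count=q.GetNumBonds() if q else 0,
                        ),
                        int(freq),
                    )
                )
        return cls(entries, n_pairs, seed)


def _sample_pairs(n_mols: int, n_pairs: int, rng: np.random.Generator):
    """Uniform sample of unordered index pairs without replacement."""
    total = n_mols * (n_mols - 1) // 2
    n_pairs = min(n_pairs, total)
    if total <= 200_000:
        all_pairs = [(i, j) for i in range(n_mols) for j in range(i + 1, n_mols)]
        idx = rng.choice(total, size=n_pairs, replace=False)
        return [all_pairs[k] for k in sorted(idx)]
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_pairs:
        i, j = rng.integers(0, n_mols, size=2)
        if i == j:
            continue
        chosen.add((min(i, j), max(i, j)))
    return sorted(chosen)


def mine_clds(
    molecules: Sequence,
    n_pairs: int,
    seed: int,
    *,
    timeout_s: int = 10,
    min_size: int = DEFAULT_MIN_SIZE,
) -> CLDVocabulary:
    """Mine a CLD vocabulary from seeded uniform pair sampling.

    Computes the MCS of each sampled pair, aggregates identical patterns by a
    canonical form, and returns them ranked by frequency (ties broken by the
    canonical pattern string, so the ranking is fully deterministic).
    """
    if len(molecules) < 2:
        raise ValueError("need at least two molecules")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = _sample_pairs(len(molecules), n_pairs, rng)

    counts: dict[str, tuple[Substructure, int]] = {}
    for i, j in pairs:
        sub = mcs(molecules[i], molecules[j], timeout_s=timeout_s, min_size=min_size)
        if sub is None:
            continue
        key = _canonical_pattern(sub.pattern)
        if key in counts:
            prev, c = counts[key]
            counts[key] = (prev, c + 1)
        else:
            counts[key] = (sub, 1)

    ranked = sorted(counts.items(), key=lambda kv: (-kv[1][1], kv[0]))
    return CLDVocabulary([v for _, v in ranked], n_pairs=len(pairs), seed=seed)


def cld_features(
    reaction: ParsedReaction, vocab: CLDVocabulary, k: int
) -> np.ndarray:
    """Binary CLD feature vector for a reaction.

    Bit ``i`` is 1 iff the i-th ranked vocabulary substructure occurs in ANY
    reactant or product molecule of the reaction.
    """
    queries = [s.query_mol() for s in vocab.top(k)]
    mols = list(reaction.reactants) + list(reaction.products)
    bits = np.zeros(k, dtype=np.int8)
    for i, q in enumerate(queries):
        if any(m.HasSubstructMatch(q) for m in mols):
            bits[i] = 1
    return bits
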