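"""Atom-pair reaction-difference fingerprints with hash folding.

An AP3 fingerprint indexes a molecule by (atom type, atom type, topological
distance) triples with the bond-path distance capped at 3. The atom type is
the classic atom-pair typing: element, aromaticity flag, and heavy-neighbor
count. A reaction fingerprint is the signed difference

    sum of reactant fingerprints  -  sum of product fingerprints,

which encodes what changes across the reaction (an identity reaction maps to
the zero vector). The native index space is high-dimensional and very sparse,
so fingerprints are folded to a fixed length L (default 256) by hashing
indices — by default ``index mod L`` — and summing colliding entries, which
conserves the total signed count.

Counts are kept signed through the subtraction; a binary clamp (sign only)
is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from rdkit import Chem

from .reaction_io import ParsedReaction

__all__ = [
    "SparseFingerprint",
    "atom_type_code",
    "pair_index",
    "NATIVE_DIM",
    "ap3_fingerprint",
    "reaction_fingerprint",
    "fold",
]

MAX_PATH_LENGTH = 3

# atom type = (element, aromatic flag, heavy-neighbor count capped at 7)
_N_TYPE_CODES = 119 * 2 * 8  # 1904
_TYPE_SPACE = 2048  # next power of two, fixes the pair encoding

#: native fingerprint dimensionality implied by the index scheme
NATIVE_DIM = (_TYPE_SPACE * (_TYPE_SPACE + 1) // 2) * MAX_PATH_LENGTH


def atom_type_code(atom) -> int:
    """Integer atom-type code: element, aromaticity, heavy-neighbor count."""
    degree = min(atom.GetDegree(), 7)
    return (atom.GetAtomicNum() * 2 + int(atom.GetIsAromatic())) * 8 + degree


def pair_index(type_a: int, type_b: int, distance: int) -> int:
    """Stable index for an (atom type, atom type, distance) triple.

    Types are order-insensitive (sorted); distance is 1..MAX_PATH_LENGTH.
    """
    if not 1 <= distance <= MAX_PATH_LENGTH:
        raise ValueError(f"distance must be in 1..{MAX_PATH_LENGTH}")
    lo, hi = sorted((type_a, type_b))
    return (hi * (hi + 1) // 2 + lo) * MAX_PATH_LENGTH + (distance - 1)


@dataclass
class SparseFingerprint:
    """Sparse signed count vector over the native atom-pair index space.

    Zero entries are never stored; arithmetic drops entries that cancel.
    """

    entries: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.entries = {
            int(i): int(v) for i, v in self.entries.items() if int(v) != 0
        }
        for i in self.entries:
            if not 0 <= i < NATIVE_DIM:
                raise ValueError(f"index {i} outside [0, {NATIVE_DIM})")

    def __add__(self, other: "SparseFingerprint") -> "SparseFingerprint":
        merged = dict(self.entries)
        for i, v in other.entries.items():
            merged[i] = merged.get(i, 0) + v
        return SparseFingerprint(merged)

    def __neg__(self) -> "SparseFingerprint":
        return SparseFingerprint({i: -v for i, v in self.entries.items()})

    def __sub__(self, other: "SparseFingerprint") -> "SparseFingerprint":
        return self + (-other)

    def __eq__(self, other) -> bool:
        return isinstance(other, SparseFingerprint) and self.entries == other.entries

    def total(self) -> int:
        return sum(self.entries.values())

    def nnz(self) -> int:
        return len(self.entries)

    def to_jsonl_obj(self) -> dict[str, int]:
        return {str(i): v for i, v in sorted(self.entries.items())}


def ap3_fingerprint(mol) -> SparseFingerprint:
    """Atom-pair fingerprint with topological distance capped at 3 bonds.

    One entry per (type_i, type_j, d) with 1 <= d <= 3; the count is the
    number of heavy-atom pairs realizing that triple. A single-atom molecule
    has no pairs and gives the empty fingerprint.
    """
    n = mol.GetNumAtoms()
    if n < 2:
        return SparseFingerprint()
    types = [atom_type_code(a) for a in mol.GetAtoms()]
    dmat = Chem.GetDistanceMatrix(mol)
    entries: dict[int, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dmat[i, j])
            if 1 <= d <= MAX_PATH_LENGTH:
                idx = pair_index(types[i], types[j], d)
                entries[idx] = entries.get(idx, 0) + 1
    return SparseFingerprint(entries)


def reaction_fingerprint(parsed: ParsedReaction) -> SparseFingerprint:
    """Signed difference fingerprint: sum over reactants minus sum over products.

    Agents are excluded from both sums (they appear on neither side of the
    transformation in the RSMI convention).
    """
    fp = SparseFingerprint()
    for mol in parsed.reactants:
        fp = fp + ap3_fingerprint(mol)
    for mol in parsed.products:
        fp = fp - ap3_fingerprint(mol)
    return fp


def fold(
    fp: SparseFingerprint,
    length: int = 256,
    *,
    hash_fn: Callable[[int], int] | None = None,
    binary: bool = False,
) -> np.ndarray:
    """Fold a sparse fingerprint to a fixed-length signed integer vector.

    Every entry (i, v) adds v at position ``hash_fn(i) % length`` (default
    hash is the identity, i.e. plain ``i mod length``), so the signed total is
    conserved and folding is linear in the fingerprint. ``binary=True`` clamps
    the folded vector to its sign.
    """
    if length < 1:
        raise ValueError("fold length must be >= 1")
    out = np.zeros(length, dtype=np.int64)
    for i, v in fp.entries.items():
        h = i if hash_fn is None else hash_fn(i)
        out[h % length] += v
    if binary:
        out = np.sign(out)
    return out


def fold_matrix(
    fps: Iterable[SparseFingerprint], length: int = 256, **kw
) -> np.ndarray:
    """Stack folded fingerprints into an (n, length) matrix."""
    return np.asarray([fold(fp, length, **kw) for fp in fps])
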