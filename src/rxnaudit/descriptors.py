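"""Whole-molecule descriptor features for reactions.

Each reaction row is the concatenation of a substrate block (elementwise sum
of per-molecule descriptor vectors over the reactants), a product block (same
over the products), and two experimental-condition features (an integer
solvent code over a vocabulary learned on the training split, and the
temperature in degrees Celsius, median-imputed when missing). Agents carry no
descriptor block. With the default list of 198 descriptors the row width is
2*198 + 2 = 398.

Descriptor values are computed with rdkit and cached per canonical SMILES;
non-finite or failed values are replaced by 0 and counted per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import Descriptors

from .reaction_io import ParsedReaction, ReactionRecord, parse_rsmi

__all__ = [
    "DEFAULT_DESCRIPTOR_NAMES",
    "DescriptorCalculator",
    "SolventVocabulary",
    "ReactionFeaturizer",
    "load_descriptor_config",
]

# Post-2017 or numerically fragile entries excluded from the default list;
# the remaining 198 are classic whole-molecule descriptors (weight, atom/ring
# counts, structural-motif counts, topological indices, ...).
_EXCLUDED = {"qed", "SPS", "Ipc", "AvgIpc"} | {
    n for n, _ in Descriptors.descList if n.startswith("BCUT2D_")
}

DEFAULT_DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    n for n, _ in Descriptors.descList if n not in _EXCLUDED
)

_DESCRIPTOR_FNS = dict(Descriptors.descList)


def load_descriptor_config(path) -> tuple[str, ...]:
    """Read a descriptor list from a plain-text config (one name per line)."""
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.append(line)
    unknown = [n for n in names if n not in _DESCRIPTOR_FNS]
    if unknown:
        raise ValueError(f"unknown descriptor names: {unknown}")
    return tuple(names)


class DescriptorCalculator:
    """Computes named descriptor vectors per molecule, cached by canonical SMILES.

    The cache makes repeated featurization of corpora with recurring molecules
    (the normal case for reaction datasets) cheap, and guarantees the
    canonicalization invariance contract: two SMILES spellings of the same
    molecule yield the identical vector.
    """

    def __init__(self, names: Sequence[str] = DEFAULT_DESCRIPTOR_NAMES):
        unknown = [n for n in names if n not in _DESCRIPTOR_FNS]
        if unknown:
            raise ValueError(f"unknown descriptor names: {unknown}")
        self.names = tuple(names)
        self._fns = [_DESCRIPTOR_FNS[n] for n in self.names]
        self._cache: dict[str, np.ndarray] = {}
        #: per-descriptor count of failed / non-finite evaluations (zeroed out)
        self.failure_counts: dict[str, int] = {n: 0 for n in self.names}

    def __call__(self, mol) -> np.ndarray:
        smiles = Chem.MolToSmiles(mol)
        cached = self._cache.get(smiles)
        if cached is not None:
            return cached
        values = np.zeros(len(self.names))
        for j, fn in enumerate(self._fns):
            try:
                v = float(fn(mol))
            except Exception:
                self.failure_counts[self.names[j]] += 1
                continue
            if not np.isfinite(v):
                self.failure_counts[self.names[j]] += 1
                continue
            values[j] = v
        values.flags.writeable = False
        self._cache[smiles] = values
        return values

    def from_smiles(self, smiles: str) -> np.ndarray:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES {smiles!r}")
        return self(mol)


class SolventVocabulary:
    """Integer encoding of solvent strings with a reserved ``unknown`` code 0.

    Fit on the training split only, so a solvent first seen at test time maps
    to ``unknown`` rather than leaking test information into the encoding.
    """

    UNKNOWN = 0

    def __init__(self):
        self._index: dict[str, int] = {}

    def fit(self, solvents: Sequence[str | None]) -> "SolventVocabulary":
        seen = sorted({s.strip().lower() for s in solvents if s and s.strip()})
        self._index = {s: i + 1 for i, s in enumerate(seen)}
        return self

    def encode(self, solvent: str | None) -> int:
        if not solvent or not solvent.strip():
            return self.UNKNOWN
        return self._index.get(solvent.strip().lower(), self.UNKNOWN)

    def __len__(self):
        return len(self._index) + 1


@dataclass
class ReactionFeaturizer:
    """Assembles fixed-width descriptor feature rows for reactions.

    ``fit`` learns the solvent vocabulary and the temperature median from a
    training set; ``transform`` then produces rows for any records. Feature
    names are ``s_<descriptor>`` (substrate block), ``p_<descriptor>``
    (product block), ``solvent``, ``temperature``.
    """

    calculator: DescriptorCalculator = field(default_factory=DescriptorCalculator)
    solvent_vocab: SolventVocabulary = field(default_factory=SolventVocabulary)
    temperature_fill: float = 25.0

    @property
    def feature_names(self) -> list[str]:
        return (
            [f"s_{n}" for n in self.calculator.names]
            + [f"p_{n}" for n in self.calculator.names]
            + ["solvent", "temperature"]
        )

    def fit(self, records: Sequence[ReactionRecord]) -> "ReactionFeaturizer":
        self.solvent_vocab.fit([r.solvent for r in records])
        temps = [r.temperature_c for r in records if r.temperature_c is not None]
        if temps:
            self.temperature_fill = float(np.median(temps))
        return self

    def reaction_row(
        self,
        parsed: ParsedReaction,
        solvent: str | None = None,
        temperature_c: float | None = None,
    ) -> np.ndarray:
        if not parsed.reactants or not parsed.products:
            raise ValueError("reaction must have reactants and products")
        substrate = sum(self(m) for m in parsed.reactants)
        product = sum(self(m) for m in parsed.products)
        conditions = np.array(
            [
                float(self.solvent_vocab.encode(solvent)),
                self.temperature_fill if temperature_c is None else temperature_c,
            ]
        )
        return np.concatenate([substrate, product, conditions])

    # molecule-level passthrough so one cache serves both levels
    def __call__(self, mol) -> np.ndarray:
        return self.calculator(mol)

    def transform(self, records: Sequence[ReactionRecord]) -> np.ndarray:
        rows = [
            self.reaction_row(parse_rsmi(r.rsmi), r.solvent, r.temperature_c)
            for r in records
        ]
        return np.asarray(rows)
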