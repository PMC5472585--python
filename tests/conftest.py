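import numpy as np
import pytest
from rdkit import Chem

from rxnaudit.classify import FeatureMatrix
from rxnaudit.descriptors import DescriptorCalculator, ReactionFeaturizer
from rxnaudit import synthetic_data as sd


@pytest.fixture(scope="session")
def shared_calculator():
    """One descriptor calculator (and SMILES-keyed cache) for the whole run."""
    return DescriptorCalculator()


def featurize_corpus(records, calculator) -> FeatureMatrix:
    """Descriptor-family feature matrix for a record list, shared-cache."""
    fz = ReactionFeaturizer(calculator=calculator).fit(records)
    X = fz.transform(records)
    fams = ["descriptor"] * (X.shape[1] - 2) + ["condition"] * 2
    return FeatureMatrix(X, fz.feature_names, fams, [r.reaction_id for r in records])


@pytest.fixture(scope="session")
def small_planted(shared_calculator):
    """A small clean planted corpus with its feature matrix and labels."""
    records, truth = sd.planted_reactions(
        sd.PlantedReactionSpec(n_reactions=400, seed=42)
    )
    fm = featurize_corpus(records, shared_calculator)
    y = np.array([truth.observed_labels[r.reaction_id] for r in records])
    return records, truth, fm, y


@pytest.fixture(scope="session")
def fixture_molecules():
    """Small named molecules (<= 8 heavy atoms) for oracle comparisons."""
    smiles = {
        "ethanol": "CCO",
        "acetic_acid": "CC(=O)O",
        "acetone": "CC(=O)C",
        "benzene": "c1ccccc1",
        "toluene": "Cc1ccccc1",
        "phenol": "Oc1ccccc1",
        "pyridine": "c1ccncc1",
        "furan": "c1ccoc1",
        "butylamine": "CCCCN",
        "acrylonitrile": "C=CC#N",
        "isobutane": "CC(C)C",
        "chloropropane": "CCCCl",
    }
    return {name: Chem.MolFromSmiles(s) for name, s in smiles.items()}
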