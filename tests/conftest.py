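"""Shared fixtures: reference compounds and small synthetic libraries."""

import pytest

from vsfunnel.chem_io import MoleculeRecord
from vsfunnel.synthetic_data import gen_molecule_library, plant_activity_labels

# N-(4-(2-ethyl-4-(m-tolyl)thiazol-5-yl)pyridin-2-yl)benzamide — a published
# nanomolar JNK3 inhibitor hit; its descriptor row is known to one decimal
# (MW 399.5, 29 heavy atoms, TPSA 83.1 A^2 with sulfur terms, 5 rotatable
# bonds, 1 donor, 4 acceptors).
HIT_SMILES = "CCc1nc(-c2cccc(C)c2)c(-c2ccnc(NC(=O)c3ccccc3)c2)s1"

# Published per-stage scores for the same hit: staged docking tiers
# (HTVS/SP/XP, kcal/mol), MM/GBSA dG, external surface score, predicted pIC50.
HIT_SCORES = {
    "score_htvs": -8.401,
    "score_sp": -11.535,
    "score_xp": -13.065,
    "mmgbsa_dg": -82.05,
    "external_score": -173.73,
    "pic50_pred": 5.82,
}


@pytest.fixture(scope="session")
def hit_record() -> MoleculeRecord:
    return MoleculeRecord(id="hit", structure=HIT_SMILES)


@pytest.fixture(scope="session")
def small_library():
    return gen_molecule_library(40, seed=11)


@pytest.fixture(scope="session")
def labelled_library():
    lib = gen_molecule_library(60, seed=12)
    activity, truth = plant_activity_labels(lib, noise_sd=0.0, seed=13)
    return lib, activity, truth
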