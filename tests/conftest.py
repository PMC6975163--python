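import numpy as np
import pytest

from gemcurate import (
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    ensemble_essentiality,
    generate_ensemble,
)
from gemcurate.fixtures import FixtureSpec, make_split_ensemble, make_toy_universe


def build_chain_model() -> MetabolicModel:
    """Linear chain EX_A → T_A → R1 → BIOMASS with unit coefficients.

    Biomass flux is bottlenecked by the A uptake limit.
    """
    return MetabolicModel(
        id="chain",
        metabolites=[
            Metabolite("A_e", "A", "e"),
            Metabolite("A_c", "A", "c"),
            Metabolite("P_c", "precursor", "c"),
            Metabolite("biomass_e", "biomass", "e"),
        ],
        reactions=[
            Reaction("EX_A", {"A_e": -1.0}, 0.0, 1000.0),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0, gene_rule="g1"),
            Reaction("R1", {"A_c": -1.0, "P_c": 1.0}, 0.0, 1000.0,
                     gene_rule="g2 or g3"),
            Reaction("BIOMASS", {"P_c": -1.0, "biomass_e": 1.0}, 0.0, 1000.0),
            Reaction("EX_biomass", {"biomass_e": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction_id="BIOMASS",
    )


@pytest.fixture
def chain_model():
    return build_chain_model()


@pytest.fixture
def chain_medium():
    return Medium("minimal_A", {"EX_A": 10.0})


@pytest.fixture(scope="session")
def toy3():
    """3-pathway / 3-media gapped universe with enumerated ground truth."""
    spec = FixtureSpec(n_pathways=3, n_decoy_reactions=2, n_media=3, seed=0)
    return make_toy_universe(spec)


@pytest.fixture(scope="session")
def toy3_ensemble(toy3):
    draft, universal, media, _ = toy3
    return generate_ensemble(draft, universal, media, n=30, seed=1)


@pytest.fixture(scope="session")
def split_ensemble():
    """200-member ensemble with one engineered phenotype splitter."""
    return make_split_ensemble(n_members=200, n_decoys=20, seed=3)


@pytest.fixture(scope="session")
def split_essentiality(split_ensemble):
    ensemble, _ = split_ensemble
    return ensemble_essentiality(ensemble)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
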