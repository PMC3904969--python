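import numpy as np
import pytest

from metacna.model_io import MetabolicModel, Metabolite, Reaction
from metacna.simulate import SimulationConfig, generate_dataset


def make_model(reactions, metabolites=None, reversible=(), model_id="toy"):
    """Build a model from {rid: (reactants, products, genes)} shorthand."""
    mets = set()
    for r, p, _ in reactions.values():
        mets |= set(r) | set(p)
    if metabolites is None:
        metabolites = {m: "c" for m in mets}
    return MetabolicModel(
        id=model_id,
        metabolites=[
            Metabolite(id=m, name=m.rsplit("_", 1)[0], compartment=c)
            for m, c in metabolites.items()
        ],
        reactions=[
            Reaction(
                id=rid,
                reversible=rid in reversible,
                reactants=set(r),
                products=set(p),
                genes=set(g),
            )
            for rid, (r, p, g) in reactions.items()
        ],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by read-only tests."""
    cfg = SimulationConfig(
        seed=42,
        n_metabolites=60,
        n_reactions=80,
        n_genes=80,
        n_groups=40,
        n_taxa=12,
        gain_rate=0.01,
        loss_rate=0.01,
        n_traits=3,
        planted={"trait00": [("IG0000", 4.0)]},
        trait_noise_var_per_my=0.01,
        missing_trait_fraction=0.1,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
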