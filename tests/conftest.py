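import numpy as np
import pytest

from ert.reaction_io import EnzymaticReaction, ReactionCorpus
from ert.synthetic_data import GeneratorConfig, generate_enzymatic_corpus


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_reactions=400, n_scaffolds=16, general_multiplier=5, seed=123)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    corpus, manifest = generate_enzymatic_corpus(small_config)
    return corpus, manifest


@pytest.fixture()
def tiny_corpus() -> ReactionCorpus:
    return ReactionCorpus(
        [
            EnzymaticReaction("CC(=O)c1ccccc1", "C[C@H](O)c1ccccc1",
                              "ketoreductase from Lactobacillus kefir", "r0"),
            EnzymaticReaction("CC(=O)c1ccccc1", "C[C@@H](O)c1ccccc1",
                              "ketoreductase from Candida magnoliae", "r1"),
            EnzymaticReaction("CCO", "CC=O", "alcohol dehydrogenase", "r2"),
            EnzymaticReaction("CCOC(C)=O", "CC(=O)O.CCO", "pig liver esterase", "r3"),
            EnzymaticReaction("CO.OC(=O)Cc1ccccc1", "COC(=O)Cc1ccccc1", "", "g0"),
        ],
        name="tiny",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
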