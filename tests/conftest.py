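import numpy as np
import pytest

from glyqgram import GeneratorConfig, Glycan, MotifSpec


@pytest.fixture
def single() -> Glycan:
    return Glycan("SINGLE", {1: "Man"}, {})


@pytest.fixture
def chain3() -> Glycan:
    """Neu5Ac-(a2-3)-Gal-(b1-4)-GlcNAc, root at the reducing end."""
    return Glycan(
        "CHAIN3",
        {1: "GlcNAc", 2: "Gal", 3: "Neu5Ac"},
        {2: (1, "b1-4"), 3: (2, "a2-3")},
    )


@pytest.fixture
def branched3() -> Glycan:
    """A root mannose with two leaf children (a bent 3-gram)."""
    return Glycan(
        "BRANCH3",
        {1: "Man", 2: "Gal", 3: "Glc"},
        {2: (1, "a1-3"), 3: (1, "a1-6")},
    )


@pytest.fixture
def small_cfg() -> GeneratorConfig:
    return GeneratorConfig(min_nodes=3, max_nodes=10, max_depth=5, seed=0)


@pytest.fixture
def sialyl_motif() -> MotifSpec:
    frag = Glycan(
        "MOTIF",
        {1: "GlcNAc", 2: "Gal", 3: "Neu5Ac"},
        {2: (1, "b1-4"), 3: (2, "a2-3")},
    )
    return MotifSpec(frag, graft_layer_range=(1, 3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
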