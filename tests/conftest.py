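import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from otseq import design, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_library():
    """A designed library over a simulated genome: (genome, guides, constructs,
    manifest)."""
    cfg = simulate.SimConfig(
        seed=11, genome_length=8000, n_guides=1,
        planted_per_guide={0: 1, 2: 2, 3: 2, 4: 2},
    )
    genome, guides, _ = simulate.simulate_genome_and_guides(cfg)
    constructs, _ = design.design_library(genome, guides, 4, seed=5)
    manifest = design.constructs_to_manifest(constructs)
    return genome, guides, constructs, manifest


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
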