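import numpy as np
import pytest

from mitokit.synthetic import SyntheticConfig, make_genomes, make_reads


@pytest.fixture(scope="session")
def world():
    """Default synthetic genomes + manifest (seed 1), shared across tests."""
    cfg = SyntheticConfig(seed=1)
    mito, plastid, nuclear, manifest = make_genomes(cfg)
    return {"cfg": cfg, "mito": mito, "plastid": plastid,
            "nuclear": nuclear, "manifest": manifest}


@pytest.fixture(scope="session")
def read_pool(world):
    """Default labelled long-read mixture for the seed-1 world."""
    reads = make_reads((world["mito"], world["plastid"], world["nuclear"]),
                       world["manifest"], world["cfg"])
    return reads


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n, gc=0.5):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bases[rng.choice(4, size=n, p=p)].tobytes().decode()
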