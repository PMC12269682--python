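import numpy as np
import pytest

from fwdyn import structio, synthdata


@pytest.fixture(scope="session")
def toy_complex():
    """Static toy complex (no drift, no jitter) with motifs placed exactly."""
    spec = synthdata.ToyComplexSpec(
        F=20,
        drift=0.0,
        jitter=0.0,
        placed_motifs=[
            {"kind": "ring_pair", "distance": 4.0, "angle": 0.0},
            {"kind": "hbond", "distance": 2.0, "angle": 180.0},
        ],
        seed=42,
    )
    return synthdata.gen_toy_complex(spec)


@pytest.fixture()
def vh_region_map():
    """A seven-region heavy-chain annotation covering residues 1..120."""
    bounds = [
        ("FW1", 1, 25), ("CDR1", 26, 33), ("FW2", 34, 50), ("CDR2", 51, 58),
        ("FW3", 59, 96), ("CDR3", 97, 110), ("FW4", 111, 120),
    ]
    return structio.RegionMap(
        [structio.RegionEntry("H", r, s, e) for r, s, e in bounds]
    )


@pytest.fixture()
def short_sequence():
    return structio.ChainSequence(
        "H", [(i, aa) for i, aa in enumerate("MKTAYIAKQR", start=1)]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
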