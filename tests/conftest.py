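import numpy as np
import pytest

from phagerflp.digest import GenomeSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_genome(rng, length, gc=0.5, id="g", topology="linear"):
    bases = np.array(list("ACGT"))
    at = (1 - gc) / 2
    seq = "".join(rng.choice(bases, size=length, p=[at, gc / 2, gc / 2, at]))
    return GenomeSequence(id=id, seq=seq, topology=topology)


def plant_sites(seq: str, site: str, positions) -> str:
    """Overwrite seq with `site` at each start position (no length change)."""
    chars = list(seq)
    for p in positions:
        chars[p : p + len(site)] = list(site)
    return "".join(chars)
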