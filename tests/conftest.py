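import numpy as np
import pytest

from tcrshare import Clonotype, RepertoireSample, translate_cdr3


def make_sample(counts: dict[str, int], sample_id: str = "s", **meta) -> RepertoireSample:
    """Build a repertoire sample from a {cdr3_nt: count} mapping.

    Amino-acid sequences are derived by translation so aa-level operations
    work on the same fixture.
    """
    clones = {
        Clonotype(nt, translate_cdr3(nt), v_call="Va2", j_call="Ja2"): n
        for nt, n in counts.items()
    }
    return RepertoireSample(sample_id=sample_id, counts=clones, **meta)


@pytest.fixture
def build_sample():
    return make_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
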