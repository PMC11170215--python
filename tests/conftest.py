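import numpy as np
import pytest

from linkread.platform_io import BarcodedAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_genome():
    def _make(length, seed=0):
        bases = np.array(list("ACGT"))
        g = np.random.default_rng(seed)
        return "".join(bases[g.integers(0, 4, length)])

    return _make


def make_alignment(
    read_id="r1",
    barcode="ACGT",
    reference_name="g1",
    position=100,
    aligned_bases=150,
    mate=1,
    is_unique=True,
    is_primary=True,
    is_proper_pair=True,
    insert_size=350,
    mate_reference_name=None,
    hit_references=(),
    mapq=60,
):
    return BarcodedAlignment(
        read_id=read_id,
        barcode=barcode,
        reference_name=reference_name,
        position=position,
        mapq=mapq,
        is_unique=is_unique,
        aligned_bases=aligned_bases,
        mate=mate,
        is_primary=is_primary,
        mate_reference_name=mate_reference_name or reference_name,
        is_proper_pair=is_proper_pair,
        insert_size=insert_size,
        hit_references=hit_references or (reference_name,),
    )
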