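import numpy as np
import pytest

from peccseq import (
    FragmentFamily,
    generate_reference,
    sequence_fragments,
)
from peccseq.alignment import FragmentObservation


@pytest.fixture(scope="session")
def ref_small():
    """Two 2 kb contigs at 50% GC; shared across read-level tests."""
    return generate_reference(2, 2000, 0.5, seed=11)


def make_family(
    contig="chr1",
    start=100,
    length=150,
    molecule_id=0,
    strands="both",
    variants=(),
    lesions=(),
):
    return FragmentFamily(
        molecule_id=molecule_id,
        contig=contig,
        start=start,
        end=start + length,
        sequenced_strands=strands,
        variants=tuple(variants),
        lesions=tuple(lesions),
    )


def reads_for(ref, families, error_rate=0.0, seed=0, read_length=150):
    reads, _truth = sequence_fragments(
        families, ref, read_length=read_length, error_rate=error_rate, seed=seed
    )
    return reads


def make_frag(contig="chr1", start=0, end=150, strand="+", qname="f0", calls=None):
    """Minimal FragmentObservation for grouping tests (calls optional)."""
    if calls is None:
        calls = np.zeros((2, end - start), dtype=np.uint8)
    return FragmentObservation(
        qname=qname, contig=contig, start=start, end=end, strand=strand, calls=calls
    )
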