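import numpy as np
import pytest

from clonediv.clones import CloneDefinition, CloneProfile, Subclone
from clonediv.io import GermlineReference
from clonediv.simulate import default_germline


@pytest.fixture(scope="session")
def germline():
    return default_germline()


@pytest.fixture
def tiny_germline():
    # 30 nt, frame 0, with hand-placed WRC (TAC at 3-5) and GYW (GCT at 12-14)
    seq = "GGGTACGGGGGGGCTGGGGGGGGGGGGGGG"
    return GermlineReference(
        gene_name="IGHVTEST",
        sequence=seq,
        regions={"FR1": (0, 9), "CDR1": (9, 15), "FR2": (15, 24), "CDR2": (24, 27),
                 "FR3": (27, 30)},
        reading_frame_offset=0,
    )


def make_profile(seq_counts, sample_id="S", total=None, qualities=None,
                 min_clone_reads=0):
    """Build a CloneProfile directly from {sequence: count} for unit tests."""
    clone_reads = sum(seq_counts.values())
    major_seq = min(seq_counts, key=lambda s: (-seq_counts[s], s))
    subclones = []
    for seq, count in sorted(seq_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        qual = None
        if qualities is not None and seq in qualities:
            qual = np.asarray(qualities[seq], dtype=float)
        subclones.append(Subclone(
            sequence=seq, read_count=count, frequency=count / clone_reads,
            is_major=(seq == major_seq), mean_quality=qual))
    return CloneProfile(
        definition=CloneDefinition(v_call="IGHVTEST", d_call="IGHD1",
                                   j_call="IGHJ4", cdr3_nt="TGTGCG"),
        subclones=subclones,
        total_sample_reads=total or clone_reads,
        clone_reads=clone_reads,
        retained_reads=clone_reads,
        evaluable=clone_reads >= min_clone_reads,
        sample_id=sample_id,
    )


@pytest.fixture
def profile_factory():
    return make_profile
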