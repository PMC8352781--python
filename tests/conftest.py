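import numpy as np
import pytest

from beditscan.pipeline import default_amplicon_design
from beditscan.somatic import SampleEvidence, VariantRecord
from beditscan.synthetic import generate_reference, generate_tada_like_signature


@pytest.fixture(scope="session")
def toy_genome():
    return generate_reference(n_contigs=2, contig_length=60_000, gc_fraction=0.42, seed=101)


@pytest.fixture(scope="session")
def tada_sig():
    return generate_tada_like_signature(concentration=10.0, seed=3)


@pytest.fixture
def design():
    return default_amplicon_design()


def make_passing_snv(contig="chr1", position=5000, ref="C", alt="T",
                     qual=150.0, clone_depth=25, clone_alt=12, clone_gq=99,
                     control_depth=25, control_alt=0, control_gq=30,
                     **annotation_overrides):
    """A clone/control record pair built to pass every SNV cascade rule."""
    annotations = {"QD": 20.0, "MQ": 60.0, "FS": 1.0, "HaplotypeScore": 2.0,
                   "MQRankSum": 0.0, "ReadPosRankSum": 0.0}
    annotations.update(annotation_overrides)
    clone = VariantRecord(contig, position, ref, alt, qual, dict(annotations),
                          SampleEvidence(clone_depth, clone_alt, clone_gq))
    control = VariantRecord(contig, position, ref, alt, qual, dict(annotations),
                            SampleEvidence(control_depth, control_alt, control_gq))
    return clone, control
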