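import numpy as np
import pytest

from pairtax.io_formats import SeqRecord
from pairtax.reference_prep import Amplicon, rearrange_reference
from pairtax.simulate import generate_reference_db, worked_amplicon_example


@pytest.fixture(scope="session")
def small_db():
    """Six genera, three members each, 400 bp — enough taxonomic structure
    for classification and partitioning without long alignments."""
    return generate_reference_db(
        n_genera=6, seqs_per_genus=3, seq_len=400, seed=3
    )


@pytest.fixture(scope="session")
def worked_example():
    """Main reference, partial reference, primers and coordinate map for the
    padded-extraction scenario."""
    return worked_amplicon_example(seed=0)


def record_amplicon(record: SeqRecord) -> Amplicon:
    """Wrap a plain record as a pad-free amplicon."""
    return Amplicon(
        ref_id=record.id, seq=record.seq, ref_start=1, ref_end=len(record.seq),
        pad_left=0, pad_right=0, lineage=record.lineage,
    )


def rearranged_records(records, len1, len2, mode):
    return [
        rearrange_reference(record_amplicon(r), len1, len2, mode).to_record()
        for r in records
    ]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
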