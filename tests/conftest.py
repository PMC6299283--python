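import pytest

from phyloprof.seqio_trees import Alignment, SequenceRecord


@pytest.fixture
def small_alignment() -> Alignment:
    return Alignment(
        [
            SequenceRecord("taxA", "MKVL"),
            SequenceRecord("taxB", "MK-L"),
            SequenceRecord("taxC", "MRVL"),
        ]
    )


@pytest.fixture
def fasta_path(tmp_path, small_alignment):
    from phyloprof.seqio_trees import write_alignment

    path = tmp_path / "aln.fasta"
    write_alignment(small_alignment, path, "fasta")
    return path
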