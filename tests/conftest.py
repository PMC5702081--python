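import pytest

from guidescreen.fastq_filter import SequenceRead, write_fastq
from guidescreen.guide_report import GuideCounts, parse_reference


@pytest.fixture
def fastq_file(tmp_path):
    """Factory writing a list of (id, seq, qual) records to a FASTQ file."""

    def _write(records, name="reads.fastq"):
        path = tmp_path / name
        write_fastq((SequenceRead(*r) for r in records), path)
        return path

    return _write


@pytest.fixture
def small_reference(tmp_path):
    """A 3-gene x 2-guide reference CSV plus its parsed GuideReference."""
    path = tmp_path / "reference.csv"
    rows = [
        ("geneA", "geneA_g1", "AAAACCCCGGGGTTTTAAA"),
        ("geneA", "geneA_g2", "CCCCGGGGTTTTAAAACCC"),
        ("geneB", "geneB_g1", "GGGGTTTTAAAACCCCGGG"),
        ("geneB", "geneB_g2", "TTTTAAAACCCCGGGGTTT"),
        ("geneC", "geneC_g1", "ACGTACGTACGTACGTACG"),
        ("geneC", "geneC_g2", "TGCATGCATGCATGCATGC"),
    ]
    path.write_text(
        "gene,guide_id,sequence\n"
        + "".join(f"{g},{gid},{seq}\n" for g, gid, seq in rows)
    )
    return parse_reference(path, "sequence", ["gene", "guide_id"])


def counts_from_dict(counts, unmapped=0, label="lib"):
    return GuideCounts(dict(counts), unmapped=unmapped, library_label=label)
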