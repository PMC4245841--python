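import pytest

from indelred.io_model import IndelRecord, IndelType, ReferenceGenome


@pytest.fixture
def ref8():
    """Small two-chromosome reference with a CA repeat and an A run."""
    return ReferenceGenome({"chr1": "GCACACAG", "chr2": "TTAAAATT"})


def rec(rid, pos, type_, allele, chrom="chr1"):
    return IndelRecord(
        id=rid, chrom=chrom, pos=pos, type=IndelType(type_), allele=allele
    )
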