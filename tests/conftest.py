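import numpy as np
import pytest

from xenocomp.genome_io import CdsFeature, GenomeRecord, OperonLocus


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_genome():
    """60-nt genome with three adjacent same-strand genes in CAB order."""
    seq = "ATGAAATAAGGGATGCCCTAATTTATGGGGTAGCCCACGTACGTAGCTAGCTAGCTAGCT"
    genes = [
        ("xmoC", CdsFeature("op1_xmoC", 0, 9, "+")),
        ("xmoA", CdsFeature("op1_xmoA", 12, 21, "+")),
        ("xmoB", CdsFeature("op1_xmoB", 24, 33, "+")),
    ]
    genome = GenomeRecord(id="g1", sequence=seq, features=[f for _, f in genes])
    locus = OperonLocus(genome_id="g1", operon_id="op1", genes=genes)
    return genome, locus


@pytest.fixture
def genbank_file(tmp_path):
    """Minimal GenBank flat file: 30-nt genome, plain / complement / join CDS."""
    text = """LOCUS       testrec                   30 bp    DNA     linear   BCT 01-JAN-2020
DEFINITION  synthetic test record.
ACCESSION   testrec
FEATURES             Location/Qualifiers
     CDS             1..9
                     /locus_tag="geneA"
     CDS             complement(10..18)
                     /locus_tag="geneB"
     CDS             join(19..21,25..27)
                     /locus_tag="geneC"
ORIGIN
        1 atgaaatagg ggatgccctt aatttatggg
//
"""
    path = tmp_path / "toy.gbk"
    path.write_text(text)
    return path
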