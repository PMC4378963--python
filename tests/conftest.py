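import pytest

from avinc.model import FamilyMeta, Hit


def make_hit(
    scaffold="s1",
    family="RF00001",
    start=100,
    end=200,
    strand="+",
    bit=50.0,
    evalue=1e-6,
    genome="g00",
    pseudogene=False,
):
    return Hit(
        genome_id=genome,
        scaffold_id=scaffold,
        family_id=family,
        start=start,
        end=end,
        strand=strand,
        bit_score=bit,
        evalue=evalue,
        pseudogene=pseudogene,
    )


@pytest.fixture
def family_meta():
    fams = [
        FamilyMeta("RF00001", "CL00113", "rRNA", 38.0),
        FamilyMeta("RF00002", "CL00113", "rRNA", 40.0),
        FamilyMeta("RF00003", None, "Major spliceosomal RNA", 60.0),
        FamilyMeta("RF00005", "CL00001", "Transfer RNA", 29.0),
        FamilyMeta("tRNA", "CL00001", "Transfer RNA", 20.0),
        FamilyMeta("RF00103", None, "microRNA", 45.0),
    ]
    return {f.family_id: f for f in fams}


TBLOUT_TEXT = """\
# cmsearch tabular output
#target name\taccession\tquery name\taccession\tmdl\tmdl from\tmdl to\tseq from\tseq to\tstrand\ttrunc\tpass\tgc\tbias\tscore\tE-value\tinc\tdescription of target
scaf1 - 5S_rRNA RF00001 cm 1 119 101 200 + no 1 0.49 0.0 38.2 5e-06 ! -
scaf1 - mir-x RF00103 cm 1 60 200 101 - no 1 0.40 0.0 55.0 5e-04 ! some description here
scaf2 - U1 RF00003 cm 1 160 301 460 + no 1 0.52 0.1 82.5 1.3e-12 ! -
"""

TRNASCAN_TEXT = """\
Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tCove
Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore
--------\t------\t----\t------\t----\t-----\t-----\t----\t------
scaf1\t1\t1000\t928\tPseudo\tAGC\t0\t0\t35.20
scaf1\t2\t2000\t2072\tAla\tAGC\t0\t0\t66.10
"""


@pytest.fixture
def tblout_text():
    return TBLOUT_TEXT


@pytest.fixture
def trnascan_text():
    return TRNASCAN_TEXT
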