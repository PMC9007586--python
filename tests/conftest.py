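import pandas as pd
import pytest

from prodemand import ExpressionTable, ProteinRecord, Proteome

ENSEMBL_FIXTURE = """\
>ENSMUSP000A.1 pep gene:ENSMUSG000G.2 transcript:ENSMUST000T.3 gene_symbol:GeneA
MKVPPA
>ENSMUSP000B.1 pep gene:ENSMUSG000H.1 transcript:ENSMUST000U.1 gene_symbol:GeneB
MAACD*
"""


@pytest.fixture
def ensembl_fasta(tmp_path):
    path = tmp_path / "pep.fa"
    path.write_text(ENSEMBL_FIXTURE)
    return path


def make_proteome(spec):
    """spec: list of (protein_id, gene_id, transcript_id, sequence)."""
    return Proteome(
        [
            ProteinRecord(
                protein_id=pid, gene_id=gid, transcript_id=tid, sequence=seq
            )
            for pid, gid, tid, seq in spec
        ]
    )


@pytest.fixture
def toy_proteome():
    return make_proteome(
        [
            ("P1", "g1", "t1", "PP"),
            ("P2", "g2", "t2", "AAAA"),
            ("P3", "g3", "t3", "PAPA"),
            ("P4", "g4", "t4", "ACDEFGHIKL"),
            ("P5", "g5", "t5", "MNPQRSTVWY"),
        ]
    )


def make_expression(rows, labels=("undifferentiated", "differentiated")):
    """rows: mapping gene_id -> (abundance_from, abundance_to)."""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(labels))
    return ExpressionTable(frame.astype(float))
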