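import numpy as np
import pandas as pd
import pytest

from proteopin import PeptideMatrix, SimulationConfig, simulate_peptide_matrix

WIDE_TSV = """\
peptide\tprotein\tprev_aa\tnext_aa\tcleavage\tproteotypic\ts1\ts2
AGLVNTK_2\tP1\tK\tS\tfull\t1\t16\t100
GLVNTK_2\tP1\tA\tS\tsemi_n\t1\t4\tNA
LLDEGR_2\tP2\tR\tV\tfull\t1\t9\t25
"""

LONG_TSV = """\
ProteinName\tFullPeptideName\tIntensity\tfilename\tm_score\tdecoy
P1\tAGLVNTK_2\t3\trun1\t0.0001\t0
P1\tAGLVNTK_2\t5\trun1\t0.0001\t0
P1\tAGLVNTK_2\t7\trun2\t0.0001\t0
P2\tLLDEGR_2\t9\trun1\t0.0001\t0
P2\tLLDEGR_2\t11\trun2\t0.0001\t0
DECOY_P2\tLLDEGR_3\t99\trun1\t0.0001\t1
2/P1/P2\tSHAREDK_2\t50\trun1\t0.0001\t0
"""

FASTA = """\
>sp|P00001|TEST1 demo protein one
MKAGLKSR
>P2 demo protein two
MKLLDEGRVAK
"""


@pytest.fixture
def wide_tsv(tmp_path):
    p = tmp_path / "wide.tsv"
    p.write_text(WIDE_TSV)
    return p


@pytest.fixture
def long_tsv(tmp_path):
    p = tmp_path / "long.tsv"
    p.write_text(LONG_TSV)
    return p


@pytest.fixture
def fasta_file(tmp_path):
    p = tmp_path / "prot.fasta"
    p.write_text(FASTA)
    return p


def make_matrix(rows, samples):
    """Build a PeptideMatrix from (pid, protein, cleavage, *intensities) rows."""
    ids = [r[0] for r in rows]
    meta = pd.DataFrame(
        {
            "sequence": [r[0].split("_")[0] for r in rows],
            "protein": [r[1] for r in rows],
            "prev_aa": "K",
            "next_aa": "A",
            "cleavage": [r[2] for r in rows],
            "proteotypic": True,
        },
        index=ids,
    )
    inten = pd.DataFrame(
        [[np.nan if v is None else float(v) for v in r[3:]] for r in rows],
        index=ids,
        columns=samples,
        dtype=float,
    )
    return PeptideMatrix(inten, meta)


@pytest.fixture
def bench_matrix():
    """Simulated protease dose-response benchmark (default fraction grid)."""
    cfg = SimulationConfig(n_proteins=60, seed=11)
    return simulate_peptide_matrix(cfg)
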