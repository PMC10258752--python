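import numpy as np
import pytest

from airepi.io import Clonotype, Repertoire
from airepi.pgen import GenerativeModel


def make_repertoire(counts, locus="TRB", subject_id="S1", **clone_kwargs):
    """Repertoire with the given read counts and synthetic CDR3 sequences."""
    clonotypes = {}
    for i, count in enumerate(counts):
        nt = "TGT" + format(i, "06b").replace("0", "A").replace("1", "C") + "GGG"
        clonotypes[nt] = Clonotype(
            cdr3_nt=nt,
            cdr3_aa="CASSF",
            v_gene=f"V{i % 3 + 1}",
            j_gene=f"J{i % 2 + 1}",
            read_count=int(count),
            **clone_kwargs,
        )
    return Repertoire(subject_id=subject_id, locus=locus, clonotypes=clonotypes)


@pytest.fixture
def toy_model():
    """The 2V x 2J no-trim no-insertion model from the interface contract."""
    return GenerativeModel(
        v_segments=[("V1", "AC", 0.5), ("V2", "GG", 0.5)],
        j_segments=[("J1", "GT", 0.5), ("J2", "TT", 0.5)],
        insertion_length_probs=np.array([1.0]),
        insertion_base_probs=np.array([0.25, 0.25, 0.25, 0.25]),
        v_trim_probs=np.array([1.0]),
        j_trim_probs=np.array([1.0]),
    )


def write_airr_tsv(path, rows, columns=None):
    """Write a minimal AIRR-style TSV from a list of dicts."""
    columns = columns or [
        "junction",
        "junction_aa",
        "v_call",
        "j_call",
        "duplicate_count",
        "productive",
        "v_identity",
    ]
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in columns))
    path.write_text("\n".join(lines) + "\n")
    return path
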