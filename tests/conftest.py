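import numpy as np
import pytest

from tcrtrace.core import Clone, Repertoire

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_repertoire(clone_rows, sample_id="S1", patient_id="P1",
                    treatment="AHSCT", subpopulation="CD4_naive",
                    timepoint="t0", **kwargs):
    """Repertoire from (v, j, cdr3, count) rows, normalized."""
    clones = [
        Clone(v_gene=v, j_gene=j, cdr3_aa=cdr3, count=n, frequency=1.0)
        for v, j, cdr3, n in clone_rows
    ]
    return Repertoire.from_clones(
        clones, sample_id=sample_id, patient_id=patient_id,
        treatment=treatment, subpopulation=subpopulation,
        timepoint=timepoint, **kwargs,
    )


def random_cdr3s(rng, n, alphabet=AA, lengths=(8, 20)):
    """n distinct random CDR3-like strings (C…F anchored)."""
    out = set()
    letters = np.array(list(alphabet))
    while len(out) < n:
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        s = "C" + "".join(letters[rng.integers(0, len(letters), length - 2)]) + "F"
        out.add(s)
    return sorted(out)


@pytest.fixture
def skewed_repertoire():
    """Four clones with frequencies (0.7, 0.1, 0.1, 0.1)."""
    return make_repertoire(
        [
            ("TRBV5-1", "TRBJ2-7", "CASSLF", 7),
            ("TRBV5-1", "TRBJ2-7", "CASSLY", 1),
            ("TRBV9", "TRBJ1-1", "CASSLG", 1),
            ("TRBV9", "TRBJ1-2", "CASSLW", 1),
        ]
    )


@pytest.fixture
def uniform_repertoire():
    return make_repertoire(
        [("TRBV2", "TRBJ1-1", cdr3, 5)
         for cdr3 in ("CASAF", "CASCF", "CASDF", "CASEF", "CASGF",
                      "CASHF", "CASIF", "CASKF", "CASLF", "CASMF")]
    )
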