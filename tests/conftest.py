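import numpy as np
import pytest

from immunopair.repertoire import ClonotypeRecord, Repertoire

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_cdr3(i: int, length: int = 10) -> str:
    """Deterministic distinct CDR3 strings."""
    body = "".join(AA[(i // (len(AA) ** k)) % len(AA)] for k in range(length - 2))
    return "C" + body + "F"


def make_repertoire(counts, sample_id="S1", patient_id="P1", tissue="EAT",
                    v_call="TRBV1", j_call="TRBJ1"):
    """Repertoire with the given clonotype read counts (dict or list)."""
    if isinstance(counts, dict):
        items = list(counts.items())
    else:
        items = [(make_cdr3(i), c) for i, c in enumerate(counts)]
    records = [
        ClonotypeRecord(cdr3, v_call, "", j_call, int(c)) for cdr3, c in items
    ]
    return Repertoire(sample_id, records, patient_id=patient_id, tissue=tissue)


def random_repertoire(rng: np.random.Generator, n_clonotypes=None, sample_id="R"):
    """Random small repertoire with random V/J calls and counts."""
    n = n_clonotypes or int(rng.integers(3, 51))
    records = []
    for i in range(n):
        records.append(
            ClonotypeRecord(
                make_cdr3(int(rng.integers(0, 10_000))),
                f"TRBV{int(rng.integers(1, 6))}",
                "",
                f"TRBJ{int(rng.integers(1, 4))}",
                int(rng.integers(1, 100)),
            )
        )
    return Repertoire(sample_id, records)


@pytest.fixture
def worked_repertoire():
    """Counts 200/80/9/6 plus 705 singletons at depth 1000."""
    return make_repertoire([200, 80, 9, 6] + [1] * 705)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
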