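import numpy as np
import pytest

from tdrprof.tref import ReferenceSet, RRNARecord, build_mature_trna


def _body(rng: np.random.Generator, length: int, anticodon: str, start: int = 34) -> str:
    b = "".join(rng.choice(list("ACGT"), size=length))
    return b[: start - 1] + anticodon + b[start + 2 :]


@pytest.fixture(scope="session")
def toy_ref() -> ReferenceSet:
    """Small fixed reference: His-GUG (with -1 G), Lys-CUU, one rRNA.

    The His body starts with G and its anticodon sits at 34-36, so the
    canonical 5'-half is G1-G34 and the G-1 isoform exists.
    """
    rng = np.random.default_rng(20240101)
    his_body = "G" + _body(rng, 72, "GTG")[1:]
    lys_body = _body(rng, 73, "CTT")
    his = build_mature_trna(his_body, "His-GUG", (34, 36), check_anticodon=True)
    lys = build_mature_trna(lys_body, "Lys-CUU", (34, 36), check_anticodon=True)
    rrna = RRNARecord("rRNA_toy", "".join(rng.choice(list("ACGT"), size=120)))
    return ReferenceSet(trnas=[his, lys], rrnas=[rrna])


@pytest.fixture(scope="session")
def his_record(toy_ref):
    return toy_ref.trna("His-GUG")


@pytest.fixture(scope="session")
def lys_record(toy_ref):
    return toy_ref.trna("Lys-CUU")


ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG"


@pytest.fixture(scope="session")
def adapter() -> str:
    assert len(ADAPTER) == 63
    return ADAPTER


def write_fastq(path, reads, quals=None):
    """Plain-text FASTQ writer used to build fixtures at test time."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            q = quals[i] if quals else "I" * len(seq)
            fh.write(f"@read{i}\n{seq}\n+\n{q}\n")
    return path
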