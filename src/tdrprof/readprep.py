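"""Raw FASTQ -> collapsed, length-filtered insert sequences with counts.

The library geometry is the standard adapter-ligated small-RNA design:
the single-end read starts at the insert (the 5' adapter lies upstream
of the sequencing primer and is never read), so only the 3' adapter is
trimmed.  Trimming is exact-match: either the full adapter occurs inside
the read, or a sufficiently long adapter prefix terminates it.  No
quality trimming and no mismatch tolerance — the pipeline is exact-match
end to end.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

_READ_ALPHABET = re.compile(r"^[ACGTN]*$")


def expected_cdna_bounds(
    adapter5_bp: int = 55,
    adapter3_bp: int = 63,
    min_insert: int = 20,
    max_insert: int = 50,
) -> tuple[int, int]:
    """cDNA product length bounds for the adapter-ligated library.

    With a 55-bp 5' adapter and a 63-bp 3' adapter, 20-50-nt inserts
    amplify as 138-168-bp products — the gel window excised for
    sequencing.
    """
    base = adapter5_bp + adapter3_bp
    return (base + min_insert, base + max_insert)


@dataclass(frozen=True)
class ReadFilterConfig:
    """Adapter and length-window settings for read preparation.

    The 20-50 nt window is the small-RNA size range selected on the gel;
    ``min_overlap`` is the shortest adapter prefix accepted as evidence
    of read-through at the 3' end.
    """

    adapter_3p: str
    min_overlap: int = 7
    min_len: int = 20
    max_len: int = 50
    discard_no_adapter: bool = True

    def __post_init__(self):
        ad = self.adapter_3p.upper().replace("U", "T")
        object.__setattr__(self, "adapter_3p", ad)
        if len(ad) < 10:
            raise ValueError("3' adapter must be at least 10 nt")
        if not re.fullmatch(r"[ACGT]+", ad):
            raise ValueError("3' adapter must contain only A/C/G/T (no N)")
        if self.min_overlap < 5:
            raise ValueError("min_overlap must be >= 5")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def trim_3p_adapter(read_seq: str, cfg: ReadFilterConfig) -> str | None:
    """Return the insert 5' of the 3' adapter, or None when absent.

    The leftmost exact occurrence of the full adapter wins; failing
    that, the longest adapter prefix (>= min_overlap) that is an exact
    suffix of the read.  With ``discard_no_adapter`` unset, reads with
    no adapter evidence pass through untrimmed.
    """
    read = read_seq.upper()
    if not _READ_ALPHABET.fullmatch(read):
        raise ValueError(f"read contains characters outside A/C/G/T/N: {read_seq!r}")
    ad = cfg.adapter_3p
    idx = read.find(ad)
    if idx >= 0:
        return read[:idx]
    for k in range(min(len(ad) - 1, len(read)), cfg.min_overlap - 1, -1):
        if read.endswith(ad[:k]):
            return read[: len(read) - k]
    return None if cfg.discard_no_adapter else read


def length_pass(insert: str, cfg: ReadFilterConfig) -> bool:
    """True iff the insert lies in the selected size window."""
    return cfg.min_len <= len(insert) <= cfg.max_len


@dataclass
class CollapsedReads:
    """Unique insert sequences with counts for one sample."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_no_adapter: int = 0
    n_with_n: int = 0
    n_length_fail: int = 0

    @property
    def n_adapter_trimmed(self) -> int:
        return self.n_input - self.n_no_adapter

    @property
    def n_length_pass(self) -> int:
        return self.n_adapter_trimmed - self.n_with_n - self.n_length_fail

    def counters(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_adapter_trimmed": self.n_adapter_trimmed,
            "n_no_adapter": self.n_no_adapter,
            "n_with_n": self.n_with_n,
            "n_length_fail": self.n_length_fail,
            "n_length_pass": self.n_length_pass,
        }


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def collapse_fastq(fastq: str | Path, sample_id: str, cfg: ReadFilterConfig) -> CollapsedReads:
    """Stream a FASTQ (plain or gzip), trim, filter and collapse.

    Inserts containing N are discarded (exact-match mapping downstream
    cannot use them) and counted separately.  Read-count conservation:
    n_input = n_length_pass + n_no_adapter + n_with_n + n_length_fail.
    """
    cr = CollapsedReads(sample_id=sample_id)
    path = Path(fastq)
    with _open_maybe_gz(path) as fh:
        try:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                cr.n_input += 1
                insert = trim_3p_adapter(seq, cfg)
                if insert is None:
                    cr.n_no_adapter += 1
                    continue
                if "N" in insert:
                    cr.n_with_n += 1
                    continue
                if not length_pass(insert, cfg):
                    cr.n_length_fail += 1
                    continue
                cr.counts[insert] = cr.counts.get(insert, 0) + 1
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record at index {cr.n_input} in {path}: {exc}"
            ) from exc
    return cr


def write_collapsed(cr: CollapsedReads, outdir: str | Path) -> Path:
    """Write ``collapsed/{sample}.tsv`` plus a JSON counter sidecar.

    Rows are sorted by descending count, then lexicographic sequence.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{cr.sample_id}.tsv"
    with path.open("w") as fh:
        fh.write("sequence\tcount\n")
        for seq, n in sorted(cr.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{seq}\t{n}\n")
    (outdir / f"{cr.sample_id}.counters.json").write_text(
        json.dumps(cr.counters(), indent=2) + "\n"
    )
    return path


def read_collapsed(path: str | Path, sample_id: str | None = None) -> CollapsedReads:
    """Reload a collapsed TSV written by :func:`write_collapsed`."""
    path = Path(path)
    sample = sample_id or path.stem
    counts: dict[str, int] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("sequence\t"):
            raise ValueError(f"{path} is not a collapsed-reads TSV")
        for line in fh:
            seq, n = line.rstrip("\n").split("\t")
            counts[seq] = int(n)
    sidecar = path.with_suffix(".counters.json")
    cr = CollapsedReads(sample_id=sample, counts=counts)
    if sidecar.exists():
        c = json.loads(sidecar.read_text())
        cr.n_input = c["n_input"]
        cr.n_no_adapter = c["n_no_adapter"]
        cr.n_with_n = c["n_with_n"]
        cr.n_length_fail = c["n_length_fail"]
    else:
        cr.n_input = sum(counts.values())
    return cr
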