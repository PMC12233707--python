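"""Mature tRNA / rRNA reference model and its coordinate conventions.

Coordinate convention
---------------------
Body position 1 is the first nucleotide of the mature tRNA body; the
post-transcriptionally added guanosine of tRNA-His sits one position
upstream and is labelled ``-1`` (there is no position 0 internally; some
displays alias -1 as "0").  The 3'-CCA occupies positions
``body_len + 1 .. body_len + 3``.  All fragment coordinates produced by
the mapping and annotation stages are expressed in these labels.

Sequences are normalised to the DNA alphabet (U -> T) at load time, since
sequencer reads are DNA-alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq1

COORDINATE_NOTE = (
    "body position 1 = first nucleotide of the mature body; "
    "-1 = His extra G; CCA occupies body_len+1..body_len+3"
)

_VALID_BODY = re.compile(r"^[ACGT]+$")

#: bodies longer than this are rejected: inputs must be intron-free
#: mature bodies, and no human cytoplasmic tRNA body exceeds ~100 nt
MAX_BODY_LEN = 120

#: half-window extent around the anticodon: [anticodon_start - 2,
#: anticodon_start + 5] covers the canonical 8-nt anticodon loop where
#: angiogenin cleaves to produce tRNA halves
LOOP_UPSTREAM = 2
LOOP_DOWNSTREAM = 5


def normalize_seq(seq: str, *, what: str = "sequence") -> str:
    """Uppercase, RNA->DNA (U->T); reject characters outside {A,C,G,T}."""
    s = str(seq).upper().replace("U", "T")
    m = re.search(r"[^ACGT]", s)
    if m:
        raise ValueError(
            f"invalid character {s[m.start()]!r} at position {m.start()} in {what}"
        )
    return s


@dataclass(frozen=True)
class TRNARecord:
    """One deduplicated mature tRNA sequence.

    ``family_id`` is "AminoAcid-Anticodon" (e.g. ``His-GUG``);
    ``body_seq`` is the intron-free body without CCA and without the
    His -1 G; ``mature_seq`` carries both when applicable.
    """

    family_id: str
    body_seq: str
    anticodon_start: int  # 1-based on body coordinates
    has_minus1_g: bool
    isodecoder_ids: tuple[str, ...] = ()

    @property
    def body_len(self) -> int:
        return len(self.body_seq)

    @property
    def mature_seq(self) -> str:
        prefix = "G" if self.has_minus1_g else ""
        return prefix + self.body_seq + "CCA"

    @property
    def anticodon_span(self) -> tuple[int, int]:
        return (self.anticodon_start, self.anticodon_start + 2)

    @property
    def loop_window(self) -> tuple[int, int]:
        """Anticodon-loop label window used for half classification."""
        return (self.anticodon_start - LOOP_UPSTREAM, self.anticodon_start + LOOP_DOWNSTREAM)

    @property
    def labels(self) -> tuple[int, ...]:
        """Signed position label of every mature_seq offset, in order."""
        body_and_cca = range(1, self.body_len + 4)
        if self.has_minus1_g:
            return (-1, *body_and_cca)
        return tuple(body_and_cca)

    def offset_of(self, label: int) -> int:
        """Inverse of :func:`position_label` (0-based string offset)."""
        if self.has_minus1_g:
            if label == -1:
                return 0
            if 1 <= label <= self.body_len + 3:
                return label
        elif 1 <= label <= self.body_len + 3:
            return label - 1
        raise ValueError(f"label {label} not valid for {self.family_id}")

    def fragment_seq(self, start_label: int, end_label: int) -> str:
        i, j = self.offset_of(start_label), self.offset_of(end_label)
        if j < i:
            raise ValueError(f"end label {end_label} precedes start label {start_label}")
        return self.mature_seq[i : j + 1]

    def base_at(self, label: int) -> str:
        return self.mature_seq[self.offset_of(label)]


def position_label(record: TRNARecord, string_offset: int) -> int:
    """Signed label of a 0-based offset into ``record.mature_seq``.

    Returns -1 for the His extra G, 1..body_len for the body, and
    body_len+1..body_len+3 for the CCA.  Label 0 is never produced.
    """
    if not 0 <= string_offset < len(record.mature_seq):
        raise ValueError(
            f"offset {string_offset} out of range for {record.family_id} "
            f"(mature length {len(record.mature_seq)})"
        )
    return record.labels[string_offset]


def _amino_acid(family_id: str) -> str:
    try:
        aa, _anticodon = family_id.split("-", 1)
    except ValueError:
        raise ValueError(f"family_id {family_id!r} is not 'AminoAcid-Anticodon'") from None
    return aa


def build_mature_trna(
    body_seq: str,
    family_id: str,
    anticodon_span: tuple[int, int],
    force_minus1_g: bool | None = None,
    isodecoder_ids: tuple[str, ...] = (),
    check_anticodon: bool = False,
) -> TRNARecord:
    """Construct a :class:`TRNARecord` from an intron-free body.

    CCA is appended; a -1 G is prepended for His families (the
    post-transcriptional G-1 addition) unless ``force_minus1_g``
    overrides.  Body coordinates are unchanged by the prefix.

    With ``check_anticodon=True`` the anticodon substring is verified to
    reverse-complement to a codon of the family's amino acid under the
    standard genetic code.
    """
    body = normalize_seq(body_seq, what=f"body of {family_id}")
    if len(body) > MAX_BODY_LEN:
        raise ValueError(
            f"body of {family_id} is {len(body)} nt (> {MAX_BODY_LEN}): inputs "
            "must be intron-free mature tRNA bodies"
        )
    start, end = anticodon_span
    if end - start != 2:
        raise ValueError(f"anticodon span {anticodon_span} is not 3 nt wide")
    if not (1 <= start and end <= len(body)):
        raise ValueError(f"anticodon span {anticodon_span} outside body 1..{len(body)}")
    aa = _amino_acid(family_id)
    has_g = (aa == "His") if force_minus1_g is None else bool(force_minus1_g)
    if check_anticodon:
        anticodon = body[start - 1 : end]
        codon_aa = seq1(aa)
        translated = str(Seq(anticodon).reverse_complement().translate())
        if translated != codon_aa:
            raise ValueError(
                f"anticodon {anticodon} of {family_id} decodes {translated}, "
                f"expected {codon_aa}"
            )
    return TRNARecord(
        family_id=family_id,
        body_seq=body,
        anticodon_start=start,
        has_minus1_g=has_g,
        isodecoder_ids=tuple(isodecoder_ids),
    )


@dataclass(frozen=True)
class RRNARecord:
    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"rRNA {self.id} has an empty sequence")


@dataclass
class ReferenceSet:
    """Deduplicated mature tRNAs plus the rRNA mapping sink."""

    trnas: list[TRNARecord]
    rrnas: list[RRNARecord] = field(default_factory=list)
    coordinate_note: str = COORDINATE_NOTE

    def __post_init__(self):
        seqs = [t.mature_seq for t in self.trnas]
        if len(set(seqs)) != len(seqs):
            raise ValueError("two TRNARecords share an identical mature_seq")
        fams = [t.family_id for t in self.trnas]
        if len(set(fams)) != len(fams):
            raise ValueError(
                "family_id values are not unique after dedup-merge; "
                "disambiguate family ids for isodecoders with distinct mature sequences"
            )

    def trna(self, family_id: str) -> TRNARecord:
        for t in self.trnas:
            if t.family_id == family_id:
                return t
        raise KeyError(family_id)

    @property
    def family_ids(self) -> list[str]:
        return [t.family_id for t in self.trnas]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit reference.fa (mature seqs), reference_meta.tsv, rrna.fa."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fa = outdir / "reference.fa"
        with fa.open("w") as fh:
            for t in self.trnas:
                fh.write(f">{t.family_id}|{len(t.isodecoder_ids) or 1}\n{t.mature_seq}\n")
        meta = outdir / "reference_meta.tsv"
        rows = []
        for t in self.trnas:
            lo, hi = t.loop_window
            rows.append(
                dict(
                    family_id=t.family_id,
                    body_len=t.body_len,
                    has_minus1_g=t.has_minus1_g,
                    anticodon_start=t.anticodon_start,
                    anticodon_loop_start=lo,
                    anticodon_loop_end=hi,
                    isodecoder_ids=",".join(t.isodecoder_ids) or t.family_id,
                )
            )
        pd.DataFrame(rows).to_csv(meta, sep="\t", index=False)
        rfa = outdir / "rrna.fa"
        with rfa.open("w") as fh:
            for r in self.rrnas:
                fh.write(f">{r.id}\n{r.seq}\n")
        return {"reference.fa": fa, "reference_meta.tsv": meta, "rrna.fa": rfa}

    @classmethod
    def read(cls, refdir: str | Path) -> "ReferenceSet":
        """Reload a reference written by :meth:`write` (round-trip safe)."""
        refdir = Path(refdir)
        meta = pd.read_csv(refdir / "reference_meta.tsv", sep="\t")
        seqs = {
            rec.id.split("|")[0]: normalize_seq(str(rec.seq), what=rec.id)
            for rec in SeqIO.parse(str(refdir / "reference.fa"), "fasta")
        }
        trnas = []
        for row in meta.itertuples():
            mature = seqs[row.family_id]
            body = mature[1:] if row.has_minus1_g else mature
            body = body[:-3]  # strip CCA
            trnas.append(
                TRNARecord(
                    family_id=row.family_id,
                    body_seq=body,
                    anticodon_start=int(row.anticodon_start),
                    has_minus1_g=bool(row.has_minus1_g),
                    isodecoder_ids=tuple(str(row.isodecoder_ids).split(",")),
                )
            )
        rrnas = []
        rfa = refdir / "rrna.fa"
        if rfa.exists():
            rrnas = [
                RRNARecord(rec.id, normalize_seq(str(rec.seq), what=rec.id))
                for rec in SeqIO.parse(str(rfa), "fasta")
            ]
        return cls(trnas=_sorted_trnas(trnas), rrnas=rrnas)


def _sorted_trnas(trnas: list[TRNARecord]) -> list[TRNARecord]:
    return sorted(trnas, key=lambda t: (t.family_id, t.mature_seq))


def load_reference(
    trna_fasta: str | Path,
    trna_meta: str | Path,
    rrna_fasta: str | Path | None = None,
    assume_cca_present: bool = False,
) -> ReferenceSet:
    """Build a ReferenceSet from a body FASTA plus a metadata table.

    The metadata TSV must have a header row with columns
    ``id``, ``family_id``, ``anticodon_start``.  Isodecoders whose mature
    sequences are identical are merged into a single record; ordering is
    deterministic (family_id, then sequence).

    ``assume_cca_present`` skips CCA appending for references whose
    sequences already carry the 3'-CCA.
    """
    meta = pd.read_csv(trna_meta, sep="\t", dtype={"id": str, "family_id": str})
    required = {"id", "family_id", "anticodon_start"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if meta["id"].duplicated().any():
        dups = sorted(meta.loc[meta["id"].duplicated(), "id"])
        raise ValueError(f"duplicate metadata rows for ids: {dups}")
    meta = meta.set_index("id")

    records: dict[str, TRNARecord] = {}  # mature_seq -> record
    missing = []
    for rec in SeqIO.parse(str(trna_fasta), "fasta"):
        if rec.id not in meta.index:
            missing.append(rec.id)
            continue
        row = meta.loc[rec.id]
        body = normalize_seq(str(rec.seq), what=rec.id)
        if assume_cca_present:
            if not body.endswith("CCA"):
                raise ValueError(f"{rec.id}: assume_cca_present but sequence lacks CCA")
            body = body[:-3]
        r = build_mature_trna(
            body,
            str(row["family_id"]),
            (int(row["anticodon_start"]), int(row["anticodon_start"]) + 2),
            isodecoder_ids=(rec.id,),
        )
        key = r.mature_seq
        if key in records:
            prev = records[key]
            if prev.family_id != r.family_id:
                raise ValueError(
                    f"identical mature sequences assigned to two families: "
                    f"{prev.family_id} and {r.family_id}"
                )
            records[key] = TRNARecord(
                family_id=prev.family_id,
                body_seq=prev.body_seq,
                anticodon_start=prev.anticodon_start,
                has_minus1_g=prev.has_minus1_g,
                isodecoder_ids=prev.isodecoder_ids + (rec.id,),
            )
        else:
            records[key] = r
    if missing:
        raise ValueError(f"FASTA ids missing from metadata: {sorted(missing)}")

    rrnas: list[RRNARecord] = []
    if rrna_fasta is not None and Path(rrna_fasta).exists():
        rrnas = [
            RRNARecord(rec.id, normalize_seq(str(rec.seq), what=rec.id))
            for rec in SeqIO.parse(str(rrna_fasta), "fasta")
        ]
    return ReferenceSet(trnas=_sorted_trnas(list(records.values())), rrnas=rrnas)
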