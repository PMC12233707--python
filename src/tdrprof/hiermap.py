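"""Hierarchical exact mapping: tRNA reference first, then rRNA, then unmapped.

An insert that occurs anywhere in a mature tRNA is a tRNA read even if
it also occurs in an rRNA — the hierarchy is a total priority order, the
same order the sequencing reads were originally assigned in.  rRNA is a
mapping sink only; no coordinates are kept for it.  Matching is exact
(no mismatches or indels), which makes the naive substring scan an exact
oracle and the simulator round trip lossless.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .readprep import CollapsedReads
from .tref import ReferenceSet, TRNARecord, position_label

logger = logging.getLogger(__name__)

_INSERT_ALPHABET = re.compile(r"^[ACGT]+$")

CAT_TRNA = "tRNA"
CAT_RRNA = "rRNA"
CAT_UNMAPPED = "unmapped"


@dataclass(frozen=True)
class MappingHit:
    insert: str
    family_id: str
    start_label: int
    end_label: int
    weight: float = 1.0


@dataclass
class MappingSummary:
    """Read-count totals per category for one sample."""

    sample_id: str
    n_total: int = 0
    n_trna: int = 0
    n_rrna: int = 0
    n_unmapped: int = 0


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, pos = [], haystack.find(needle)
    while pos >= 0:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def resolve_multimap(hits: list[MappingHit]) -> list[MappingHit]:
    """Collapse duplicate hits and split weight across families.

    Hits are first collapsed to distinct (family, start) pairs
    (isodecoder-merged references can only produce exact duplicates);
    when one family still carries several starts, the count is assigned
    to the 5'-most start of that family.  Each surviving hit gets weight
    1/k with k the number of distinct families, so weights always sum
    to 1 per insert.
    """
    if not hits:
        raise ValueError("resolve_multimap requires at least one hit")
    by_family: dict[str, MappingHit] = {}
    for h in sorted(hits, key=lambda h: (h.family_id, h.start_label, h.end_label)):
        prev = by_family.get(h.family_id)
        if prev is None:
            by_family[h.family_id] = h
        elif (h.start_label, h.end_label) != (prev.start_label, prev.end_label):
            logger.info(
                "insert %s hits %s at multiple positions; keeping 5'-most start %d",
                h.insert, h.family_id, prev.start_label,
            )
    k = len(by_family)
    return [
        MappingHit(h.insert, h.family_id, h.start_label, h.end_label, 1.0 / k)
        for h in by_family.values()
    ]


def map_insert(insert: str, ref: ReferenceSet) -> tuple[list[MappingHit], str]:
    """Map one insert; returns (hits, category).

    Hits carry signed labels in the reference coordinate convention;
    fragment length is always the number of labelled positions covered
    (via the label<->offset bijection), never a label difference — the
    -1 -> 1 gap would make the latter wrong for His G-1 fragments.
    """
    if not _INSERT_ALPHABET.fullmatch(insert):
        raise ValueError(f"insert contains characters outside A/C/G/T: {insert!r}")
    raw: list[MappingHit] = []
    for t in ref.trnas:
        for off in _occurrences(t.mature_seq, insert):
            raw.append(
                MappingHit(
                    insert=insert,
                    family_id=t.family_id,
                    start_label=position_label(t, off),
                    end_label=position_label(t, off + len(insert) - 1),
                )
            )
    if raw:
        return resolve_multimap(raw), CAT_TRNA
    for r in ref.rrnas:
        if insert in r.seq:
            return [], CAT_RRNA
    return [], CAT_UNMAPPED


@dataclass
class SampleAssignments:
    """Per-insert mapping results for one sample."""

    sample_id: str
    hits: dict[str, list[MappingHit]]
    categories: dict[str, str]
    read_counts: dict[str, int]


def map_collapsed(collapsed: CollapsedReads, ref: ReferenceSet) -> SampleAssignments:
    hits: dict[str, list[MappingHit]] = {}
    cats: dict[str, str] = {}
    for insert in collapsed.counts:
        h, cat = map_insert(insert, ref)
        hits[insert] = h
        cats[insert] = cat
    return SampleAssignments(
        sample_id=collapsed.sample_id,
        hits=hits,
        categories=cats,
        read_counts=dict(collapsed.counts),
    )


def summarize_mapping(collapsed: CollapsedReads, assignments: SampleAssignments) -> MappingSummary:
    """Read-count-weighted category totals; conservation is exact."""
    s = MappingSummary(sample_id=collapsed.sample_id)
    for insert, n in collapsed.counts.items():
        cat = assignments.categories[insert]
        s.n_total += n
        if cat == CAT_TRNA:
            s.n_trna += n
        elif cat == CAT_RRNA:
            s.n_rrna += n
        else:
            s.n_unmapped += n
    return s


def write_assignments(assignments: SampleAssignments, outdir: str | Path) -> Path:
    """``assignments/{sample}.tsv``: one row per (insert, family) hit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for insert in sorted(assignments.hits):
        n = assignments.read_counts[insert]
        for h in assignments.hits[insert]:
            rows.append(
                dict(
                    sequence=insert,
                    family_id=h.family_id,
                    start_label=h.start_label,
                    end_label=h.end_label,
                    weight=h.weight,
                    read_count=n,
                )
            )
    path = outdir / f"{assignments.sample_id}.tsv"
    pd.DataFrame(
        rows,
        columns=["sequence", "family_id", "start_label", "end_label", "weight", "read_count"],
    ).to_csv(path, sep="\t", index=False)
    return path


def write_mapping_summary(summaries: list[MappingSummary], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            dict(
                sample=s.sample_id,
                n_total=s.n_total,
                n_trna=s.n_trna,
                n_rrna=s.n_rrna,
                n_unmapped=s.n_unmapped,
            )
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)
    return path
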