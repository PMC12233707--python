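"""Fragment naming, classification and proportional distributions.

A fragment is identified by (family, start label, end label) in the
reference coordinate convention.  Classes follow the anatomy of
angiogenin cleavage: a 5'-half runs from the mature 5' end (label <= 1,
admitting the His G-1 isoform) into the anticodon loop; a 3'-half runs
from the loop to the 3' terminus; shorter 5'/3'-anchored species are
tRFs; everything else is internal.  All proportions are read-count
weighted, not species weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .hiermap import CAT_TRNA, SampleAssignments
from .tref import ReferenceSet, TRNARecord

logger = logging.getLogger(__name__)

FIVE_HALF = "five_half"
FIVE_TRF = "five_tRF"
THREE_HALF = "three_half"
THREE_TRF = "three_tRF"
INTERNAL = "internal"
FRAG_CLASSES = (FIVE_HALF, FIVE_TRF, THREE_HALF, THREE_TRF, INTERNAL)

#: fragments ending at CCA, CC or C before the terminus all count as
#: 3'-anchored (3' trailing heterogeneity is common)
THREE_PRIME_TOLERANCE = 3


class FragmentKey(NamedTuple):
    family_id: str
    start_label: int
    end_label: int


@dataclass
class FragmentRecord:
    key: FragmentKey
    frag_class: str
    name: str
    counts: dict[str, float] = field(default_factory=dict)


def _fmt_label(label: int, minus1_as_zero: bool) -> str:
    if label == -1 and minus1_as_zero:
        return "0"
    return str(label)


def name_fragment(key: FragmentKey, ref: ReferenceSet, minus1_as_zero: bool = False) -> str:
    """Display name "{startBase}{startLabel}-{endBase}{endLabel}".

    The canonical His 5'-half (1, 34) renders "G1-G34"; the G-1 isoform
    renders "G-1-G34" (or "G0-G34" with ``minus1_as_zero``, the display
    alias some figures use for the extra G).
    """
    rec = ref.trna(key.family_id)
    sb = rec.base_at(key.start_label)
    eb = rec.base_at(key.end_label)
    return (
        f"{sb}{_fmt_label(key.start_label, minus1_as_zero)}"
        f"-{eb}{_fmt_label(key.end_label, minus1_as_zero)}"
    )


def classify_fragment(key: FragmentKey, record: TRNARecord) -> str:
    """Assign one of the five mutually exclusive fragment classes.

    The anticodon-loop window comes from the record; the 3' anchor
    tolerates up to 3 nt of CCA trimming.  Rules are applied in fixed
    precedence (halves before tRFs) so the classes partition all keys.
    """
    lo, hi = record.loop_window
    start, end = key.start_label, key.end_label
    three_anchored = end >= record.body_len + 4 - THREE_PRIME_TOLERANCE
    if start <= 1 and lo <= end <= hi:
        return FIVE_HALF
    if three_anchored and lo <= start <= hi:
        return THREE_HALF
    if start <= 1 and end < lo:
        return FIVE_TRF
    if three_anchored and start > hi:
        return THREE_TRF
    return INTERNAL


def build_fragment_table(
    assignments: Iterable[SampleAssignments],
    ref: ReferenceSet,
    minus1_as_zero: bool = False,
) -> pd.DataFrame:
    """Aggregate weighted read counts into a fragment x sample table.

    Every tRNA-assigned weighted read lands in exactly one fragment row;
    per-sample column sums equal that sample's tRNA-mapped read count.
    Columns: family_id, name, start_label, end_label, frag_class, then
    one count column per sample.  Row order is deterministic.
    """
    samples: list[str] = []
    agg: dict[FragmentKey, dict[str, float]] = {}
    for asg in assignments:
        samples.append(asg.sample_id)
        for insert, hits in asg.hits.items():
            if asg.categories[insert] != CAT_TRNA:
                continue
            n = asg.read_counts[insert]
            for h in hits:
                key = FragmentKey(h.family_id, h.start_label, h.end_label)
                agg.setdefault(key, {})[asg.sample_id] = (
                    agg.get(key, {}).get(asg.sample_id, 0.0) + h.weight * n
                )
    rows = []
    for key in sorted(agg):
        rec = ref.trna(key.family_id)
        row = dict(
            family_id=key.family_id,
            name=name_fragment(key, ref, minus1_as_zero),
            start_label=key.start_label,
            end_label=key.end_label,
            frag_class=classify_fragment(key, rec),
        )
        for s in samples:
            row[s] = agg[key].get(s, 0.0)
        rows.append(row)
    cols = ["family_id", "name", "start_label", "end_label", "frag_class"] + samples
    return pd.DataFrame(rows, columns=cols)


META_COLS = ["family_id", "name", "start_label", "end_label", "frag_class"]


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def five_half_fraction(table: pd.DataFrame, family_id: str, sample_id: str) -> dict:
    """Fraction of a family's weighted reads classified 5'-half.

    Computed on read counts, not distinct fragment species; a family
    with zero reads yields NA, not 0.
    """
    fam = table[table["family_id"] == family_id]
    total = float(fam[sample_id].sum())
    if total == 0:
        return dict(
            family_id=family_id, sample_id=sample_id,
            five_half_fraction=np.nan, total_family_reads=0.0,
        )
    half = float(fam.loc[fam["frag_class"] == FIVE_HALF, sample_id].sum())
    return dict(
        family_id=family_id, sample_id=sample_id,
        five_half_fraction=half / total, total_family_reads=total,
    )


def first_base_split(table: pd.DataFrame, family_id: str, sample_id: str) -> dict:
    """Split a family's 5'-half reads by start: G-1 vs G1 vs other.

    Because the 5'-half rule admits only start <= 1, every half read
    starts at -1 or 1 and frac_other_start is 0 by construction; it is
    kept as an audit column.
    """
    halves = table[(table["family_id"] == family_id) & (table["frag_class"] == FIVE_HALF)]
    total = float(halves[sample_id].sum())
    if total == 0:
        return dict(
            family_id=family_id, sample_id=sample_id,
            frac_minus1_start=np.nan, frac_plus1_start=np.nan, frac_other_start=np.nan,
        )
    m1 = float(halves.loc[halves["start_label"] == -1, sample_id].sum())
    p1 = float(halves.loc[halves["start_label"] == 1, sample_id].sum())
    return dict(
        family_id=family_id, sample_id=sample_id,
        frac_minus1_start=m1 / total,
        frac_plus1_start=p1 / total,
        frac_other_start=(total - m1 - p1) / total,
    )


def proportion_tables(table: pd.DataFrame, family_ids: Iterable[str] | None = None):
    """Per-family, per-sample 5'-half fractions and first-base splits."""
    fams = list(family_ids) if family_ids is not None else sorted(table["family_id"].unique())
    samples = sample_columns(table)
    frac = pd.DataFrame([five_half_fraction(table, f, s) for f in fams for s in samples])
    split = pd.DataFrame([first_base_split(table, f, s) for f in fams for s in samples])
    return frac, split


def write_fragment_outputs(
    table: pd.DataFrame, outdir: str | Path, family_ids: Iterable[str] | None = None
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fragments.tsv": outdir / "fragments.tsv"}
    table.to_csv(paths["fragments.tsv"], sep="\t", index=False)
    frac, split = proportion_tables(table, family_ids)
    paths["five_half_fraction.tsv"] = outdir / "five_half_fraction.tsv"
    frac.to_csv(paths["five_half_fraction.tsv"], sep="\t", index=False, na_rep="NA")
    paths["first_base_split.tsv"] = outdir / "first_base_split.tsv"
    split.to_csv(paths["first_base_split.tsv"], sep="\t", index=False, na_rep="NA")
    return paths
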