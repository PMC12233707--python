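"""Synthetic small-RNA libraries with full ground truth.

Emulates the study design the analysis assumes: 3 timepoints (0 h, 6 h,
24 h of PMA stimulation) x 3 replicates of adapter-ligated 20-50 nt
inserts drawn from mature tRNA coordinates, with negative-binomial
counts, per-sample depth jitter, an rRNA decoy and a few unmappable
sequences.  The default fragment roster encodes the qualitative biology
the pipeline must recover: the His-GUG 5'-half dominates its family
(>80% of mapped reads at every timepoint, dipping slightly at 24 h), is
strongly downregulated at 24 h, and shifts from the G-1-starting
isoform toward the canonical G1 isoform over time (first-base split
0.7 -> 0.5 -> 0.3).

Reads are error-free and exactly round-trippable: pipeline fragment
counts on simulator output equal the truth counts exactly.  The
generator audits, by brute-force substring search, that every
configured insert occurs exactly once in the reference space, and
regenerates with a derived seed when the audit fails.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import DesignInfo
from .fragannot import FIVE_HALF, FragmentKey, classify_fragment
from .readprep import ReadFilterConfig, trim_3p_adapter
from .tref import ReferenceSet, RRNARecord, build_mature_trna

#: 63-nt 3' adapter (TruSeq-small-RNA-style); a declared convention of
#: the simulator, not a claim about any deposited library
DEFAULT_ADAPTER_3P = (
    "TGGAATTCTCGGGTGCCAAGG" "AACTCCAGTCAC" "ATCACG" "ATCTCGTATGCCGTCTTCTGCTTG"
)

DEFAULT_READ_LENGTH = 75


@dataclass(frozen=True)
class FragmentSpec:
    """One programmed tRNA fragment: coordinates, abundance, regulation."""

    family_id: str
    start_label: int
    end_label: int
    baseline_mean: float
    log2fc: tuple[float, ...]  # aligned with SimConfig.timepoints
    alpha: float = 0.1


@dataclass(frozen=True)
class DecoySpec:
    """A non-tRNA read source: an rRNA window or an unmappable sequence."""

    name: str
    category: str  # "rRNA" or "unmapped"
    baseline_mean: float
    rrna_window: tuple[int, int] | None = None  # 0-based [start, end) on the decoy
    length: int = 30
    alpha: float = 0.1


# anticodon sits at body positions 34-36 in every simulated family,
# giving the canonical loop window [32, 39] and a G1-G34 5'-half
ANTICODON_START = 34

_FAMILY_POOL = [
    ("Gly-GCC", "GCC"),
    ("Asp-GUC", "GTC"),
    ("Val-CAC", "CAC"),
    ("Ala-AGC", "AGC"),
    ("Phe-GAA", "GAA"),
    ("Ser-GCU", "GCT"),
]


def default_fragment_specs(n_other_families: int = 4) -> list[FragmentSpec]:
    """The study-shaped roster (log2fc tuples are (0 h, 6 h, 24 h))."""
    specs = [
        # His-GUG: halves 20000/22400 = 89% of family reads at baseline,
        # 84% at 24 h; G-1:G1 split 0.70 -> 0.50 -> 0.30; halves jointly
        # down ~2 log2 units at 24 h
        FragmentSpec("His-GUG", -1, 34, 14000, (0.0, -0.81, -3.22)),
        FragmentSpec("His-GUG", 1, 34, 6000, (0.0, 0.42, -0.78)),
        FragmentSpec("His-GUG", 1, 22, 900, (0.0, 0.0, -1.3)),
        FragmentSpec("His-GUG", 40, 75, 900, (0.0, 0.0, -1.3)),
        FragmentSpec("His-GUG", 18, 50, 600, (0.0, 0.0, -1.3)),
        # Lys-CUU: heterogeneous, no consistent direction
        FragmentSpec("Lys-CUU", 1, 35, 4000, (0.0, 0.5, -0.4)),
        FragmentSpec("Lys-CUU", 1, 24, 1500, (0.0, 0.0, 0.8)),
        FragmentSpec("Lys-CUU", 42, 76, 1200, (0.0, -0.3, 0.5)),
        FragmentSpec("Lys-CUU", 18, 45, 800, (0.0, 0.0, -0.6)),
        # Glu-CUC: upregulated at 24 h
        FragmentSpec("Glu-CUC", 1, 35, 3000, (0.0, 0.3, 1.5)),
        FragmentSpec("Glu-CUC", 43, 77, 1000, (0.0, 0.0, 1.0)),
    ]
    fc24_half = [1.2, -1.5, 0.9, -1.0, 0.8, -0.7]
    fc6_half = [0.3, -0.4, 0.2, -0.2, 0.1, -0.1]
    fc24_trf = [-0.8, 0.6, -0.5, 0.4, -0.3, 0.2]
    for i in range(n_other_families):
        fam, _anticodon = _FAMILY_POOL[i % len(_FAMILY_POOL)]
        body_len = 72 + (i % 5)
        specs.append(
            FragmentSpec(fam, 1, 33, 1500, (0.0, fc6_half[i % 6], fc24_half[i % 6]))
        )
        specs.append(
            FragmentSpec(fam, 44, body_len + 3, 700, (0.0, 0.0, fc24_trf[i % 6]))
        )
    return specs


def null_fragment_specs(
    n_fragments: int,
    seed: int,
    timepoints: int = 3,
    alpha: float = 0.1,
    mean_log: float = float(np.log(300)),
    mean_sigma: float = 0.8,
) -> list[FragmentSpec]:
    """A roster of unregulated fragments with lognormal baselines.

    Used for calibration measurements that need many exchangeable
    fragments (size-factor recovery, null differential tests) rather
    than the study-shaped default roster.
    """
    rng = np.random.default_rng([seed % 2**31, 424_243])
    fams = [
        ("His-GUG", 72), ("Lys-CUU", 73), ("Glu-CUC", 74),
        ("Gly-GCC", 72), ("Asp-GUC", 73), ("Val-CAC", 74), ("Ala-AGC", 75),
    ]
    specs: list[FragmentSpec] = []
    seen: set[tuple] = set()
    while len(specs) < n_fragments:
        fam, body_len = fams[int(rng.integers(len(fams)))]
        start = int(rng.integers(1, body_len - 20))
        end = start + int(rng.integers(20, 31)) - 1
        if end > body_len + 3:
            continue
        key = (fam, start, end)
        if key in seen:
            continue
        seen.add(key)
        specs.append(
            FragmentSpec(
                fam, start, end,
                float(rng.lognormal(mean_log, mean_sigma)),
                (0.0,) * timepoints, alpha,
            )
        )
    return specs


def default_decoy_specs() -> list[DecoySpec]:
    return [
        DecoySpec("rRNA_w1", "rRNA", 800, rrna_window=(10, 40)),
        DecoySpec("rRNA_w2", "rRNA", 400, rrna_window=(60, 95)),
        DecoySpec("random_1", "unmapped", 300, length=30),
        DecoySpec("random_2", "unmapped", 200, length=28),
    ]


@dataclass
class SimConfig:
    seed: int = 0
    n_other_families: int = 4
    timepoints: tuple[str, ...] = ("0h", "6h", "24h")
    replicates_per_timepoint: int = 3
    adapter_3p: str = DEFAULT_ADAPTER_3P
    read_length: int = DEFAULT_READ_LENGTH
    library_depth_jitter: tuple[float, float] = (0.8, 1.2)
    fragment_specs: list[FragmentSpec] = field(default_factory=list)
    decoy_specs: list[DecoySpec] = field(default_factory=list)

    def __post_init__(self):
        if not self.fragment_specs:
            self.fragment_specs = default_fragment_specs(self.n_other_families)
        if not self.decoy_specs:
            self.decoy_specs = default_decoy_specs()
        for s in self.fragment_specs:
            if s.baseline_mean <= 0 or s.alpha < 0:
                raise ValueError(f"bad fragment spec {s}")
            if len(s.log2fc) != len(self.timepoints):
                raise ValueError(f"log2fc length mismatch in {s}")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{tp}_r{r}"
            for tp in self.timepoints
            for r in range(1, self.replicates_per_timepoint + 1)
        ]

    def design(self) -> DesignInfo:
        return DesignInfo(
            samples=tuple(self.sample_ids),
            timepoints=tuple(
                tp for tp in self.timepoints for _ in range(self.replicates_per_timepoint)
            ),
            replicates=tuple(
                r
                for _tp in self.timepoints
                for r in range(1, self.replicates_per_timepoint + 1)
            ),
        )

    def read_filter(self) -> ReadFilterConfig:
        return ReadFilterConfig(adapter_3p=self.adapter_3p)


def _random_body(rng: np.random.Generator, length: int, anticodon_dna: str) -> str:
    bases = rng.choice(list("ACGT"), size=length)
    body = "".join(bases)
    a = ANTICODON_START - 1
    return body[:a] + anticodon_dna + body[a + 3 :]


def _family_table(cfg: SimConfig) -> list[tuple[str, str, int]]:
    """(family_id, anticodon_dna, body_len) for every simulated family."""
    fams = [("His-GUG", "GTG", 72), ("Lys-CUU", "CTT", 73), ("Glu-CUC", "CTC", 74)]
    for i in range(cfg.n_other_families):
        fam, anticodon = _FAMILY_POOL[i % len(_FAMILY_POOL)]
        fams.append((fam, anticodon, 72 + (i % 5)))
    return fams


def _audit(cfg: SimConfig, ref: ReferenceSet, decoys: dict[str, str]) -> bool:
    """Brute-force uniqueness audit of every configured read sequence.

    Each tRNA insert must occur exactly once across all mature tRNA
    sequences (so mapping is unique and the 5'-most tie-break never
    fires) and nowhere in the rRNA; decoy sequences must not occur in
    any tRNA; everything must survive the adapter trim round trip.
    """
    cat = [t.mature_seq for t in ref.trnas]
    rrna = [r.seq for r in ref.rrnas]
    rf = cfg.read_filter()

    def occurrences(needle: str, seqs: list[str]) -> int:
        total = 0
        for s in seqs:
            pos = s.find(needle)
            while pos >= 0:
                total += 1
                pos = s.find(needle, pos + 1)
        return total

    for spec in cfg.fragment_specs:
        ins = ref.trna(spec.family_id).fragment_seq(spec.start_label, spec.end_label)
        if not rf.min_len <= len(ins) <= rf.max_len:
            raise ValueError(
                f"fragment {spec.family_id}:{spec.start_label}..{spec.end_label} "
                f"is {len(ins)} nt, outside the {rf.min_len}-{rf.max_len} window"
            )
        if occurrences(ins, cat) != 1 or occurrences(ins, rrna) != 0:
            return False
        read = (ins + cfg.adapter_3p)[: cfg.read_length]
        if trim_3p_adapter(read, rf) != ins:
            return False
    for name, seq in decoys.items():
        category = next(d.category for d in cfg.decoy_specs if d.name == name)
        if occurrences(seq, cat) != 0:
            return False
        if category == "unmapped" and occurrences(seq, rrna) != 0:
            return False
        read = (seq + cfg.adapter_3p)[: cfg.read_length]
        if trim_3p_adapter(read, rf) != seq:
            return False
    return True


def make_reference(cfg: SimConfig) -> tuple[ReferenceSet, dict[str, str]]:
    """Generate the toy reference and decoy sequences; audit uniqueness.

    Returns (reference, decoy name -> sequence).  Up to 100 derived
    seeds are tried before giving up.
    """
    for attempt in range(100):
        rng = np.random.default_rng([cfg.seed % 2**31, attempt])
        trnas = []
        for fam, anticodon, body_len in _family_table(cfg):
            body = _random_body(rng, body_len, anticodon)
            if fam == "His-GUG":
                body = "G" + body[1:]  # canonical G1 so the half names G1-G34
            trnas.append(
                build_mature_trna(
                    body, fam, (ANTICODON_START, ANTICODON_START + 2),
                    isodecoder_ids=(f"{fam}-sim",), check_anticodon=True,
                )
            )
        rrna_seq = "".join(rng.choice(list("ACGT"), size=120))
        ref = ReferenceSet(
            trnas=sorted(trnas, key=lambda t: (t.family_id, t.mature_seq)),
            rrnas=[RRNARecord("rRNA_decoy", rrna_seq)],
        )
        decoys: dict[str, str] = {}
        for d in cfg.decoy_specs:
            if d.category == "rRNA":
                lo, hi = d.rrna_window
                decoys[d.name] = rrna_seq[lo:hi]
            else:
                decoys[d.name] = "".join(rng.choice(list("ACGT"), size=d.length))
        if _audit(cfg, ref, decoys):
            return ref, decoys
    raise RuntimeError("could not generate a cross-mapping-free reference in 100 attempts")


@dataclass
class TruthTable:
    """Ground truth: per-fragment per-sample means and sampled counts."""

    table: pd.DataFrame  # name, family_id, start/end, category, insert, sample, expected_mean, count
    depth_factors: dict[str, float]
    config: SimConfig
    reference: ReferenceSet

    def counts_wide(self, category: str = "tRNA") -> pd.DataFrame:
        sub = self.table[self.table["category"] == category]
        wide = sub.pivot_table(
            index=["family_id", "start_label", "end_label"],
            columns="sample", values="count", aggfunc="sum",
        )
        return wide[self.config.sample_ids]

    def five_half_fraction(self, family_id: str, sample_id: str) -> float:
        """Truth 5'-half fraction, recomputed from sampled counts."""
        rec = self.reference.trna(family_id)
        sub = self.table[
            (self.table["family_id"] == family_id) & (self.table["sample"] == sample_id)
        ]
        total = sub["count"].sum()
        if total == 0:
            return float("nan")
        mask = [
            classify_fragment(FragmentKey(family_id, int(s), int(e)), rec) == FIVE_HALF
            for s, e in zip(sub["start_label"], sub["end_label"])
        ]
        return float(sub.loc[mask, "count"].sum()) / float(total)

    def first_base_split(self, family_id: str, sample_id: str) -> tuple[float, float]:
        """Truth (frac -1 start, frac +1 start) among 5'-half reads."""
        rec = self.reference.trna(family_id)
        sub = self.table[
            (self.table["family_id"] == family_id) & (self.table["sample"] == sample_id)
        ]
        mask = [
            classify_fragment(FragmentKey(family_id, int(s), int(e)), rec) == FIVE_HALF
            for s, e in zip(sub["start_label"], sub["end_label"])
        ]
        halves = sub.loc[mask]
        total = halves["count"].sum()
        if total == 0:
            return (float("nan"), float("nan"))
        m1 = halves.loc[halves["start_label"] == -1, "count"].sum()
        p1 = halves.loc[halves["start_label"] == 1, "count"].sum()
        return (float(m1) / total, float(p1) / total)


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if alpha <= 0:
        return int(rng.poisson(mean))
    size = 1.0 / alpha
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def simulate_counts(cfg: SimConfig, ref: ReferenceSet, decoys: dict[str, str]) -> TruthTable:
    """Sample NB counts for every (fragment, sample); seeded, reproducible.

    count ~ NB(mean = baseline * 2^log2fc(timepoint) * depth_factor,
    dispersion alpha); alpha = 0 degenerates to Poisson.
    """
    rng = np.random.default_rng([cfg.seed % 2**31, 10_007])
    design = cfg.design()
    lo, hi = cfg.library_depth_jitter
    depth = {s: float(rng.uniform(lo, hi)) for s in cfg.sample_ids}
    rows = []
    for spec in cfg.fragment_specs:
        insert = ref.trna(spec.family_id).fragment_seq(spec.start_label, spec.end_label)
        name = f"{spec.family_id}:{spec.start_label}..{spec.end_label}"
        for sample, tp in zip(design.samples, design.timepoints):
            fc = spec.log2fc[cfg.timepoints.index(tp)]
            mean = spec.baseline_mean * 2.0**fc * depth[sample]
            rows.append(
                dict(
                    name=name, family_id=spec.family_id,
                    start_label=spec.start_label, end_label=spec.end_label,
                    category="tRNA", insert=insert, sample=sample,
                    expected_mean=mean, count=_nb_draw(rng, mean, spec.alpha),
                )
            )
    for d in cfg.decoy_specs:
        insert = decoys[d.name]
        for sample in cfg.sample_ids:
            mean = d.baseline_mean * depth[sample]
            rows.append(
                dict(
                    name=d.name, family_id="", start_label=0, end_label=0,
                    category=d.category, insert=insert, sample=sample,
                    expected_mean=mean, count=_nb_draw(rng, mean, d.alpha),
                )
            )
    return TruthTable(
        table=pd.DataFrame(rows), depth_factors=depth, config=cfg, reference=ref
    )


def emit_fastq(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    """Write one gzipped FASTQ per sample: insert + adapter, 75 nt, Q40.

    Read ids encode the source fragment and ordinal for audit; file
    content is deterministic given the truth table.
    """
    cfg = truth.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample in cfg.sample_ids:
        sub = truth.table[truth.table["sample"] == sample]
        path = outdir / f"{sample}.fastq.gz"
        with gzip.open(path, "wt") as fh:
            for name, insert, count in zip(sub["name"], sub["insert"], sub["count"]):
                if len(insert) > cfg.read_length:
                    raise ValueError(f"insert longer than read length: {name}")
                seq = (insert + cfg.adapter_3p)[: cfg.read_length]
                qual = "I" * len(seq)
                for i in range(int(count)):
                    fh.write(f"@{sample}:{name}:{i}\n{seq}\n+\n{qual}\n")
        paths[sample] = path
    return paths


def write_truth(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["truth_counts.tsv"] = outdir / "truth_counts.tsv"
    truth.table.to_csv(paths["truth_counts.tsv"], sep="\t", index=False)
    cfg = truth.config
    cfg_json = dict(
        seed=cfg.seed,
        n_other_families=cfg.n_other_families,
        timepoints=list(cfg.timepoints),
        replicates_per_timepoint=cfg.replicates_per_timepoint,
        adapter_3p=cfg.adapter_3p,
        read_length=cfg.read_length,
        library_depth_jitter=list(cfg.library_depth_jitter),
        depth_factors=truth.depth_factors,
        fragment_specs=[asdict(s) for s in cfg.fragment_specs],
        decoy_specs=[asdict(d) for d in cfg.decoy_specs],
    )
    paths["truth_config.json"] = outdir / "truth_config.json"
    paths["truth_config.json"].write_text(json.dumps(cfg_json, indent=2) + "\n")
    return paths


def simulate_library(cfg: SimConfig, outdir: str | Path) -> TruthTable:
    """End-to-end generation: reference + truth + FASTQ + design table."""
    outdir = Path(outdir)
    ref, decoys = make_reference(cfg)
    ref.write(outdir / "ref")
    truth = simulate_counts(cfg, ref, decoys)
    emit_fastq(truth, outdir / "fastq")
    write_truth(truth, outdir)
    cfg.design().write(outdir / "design.tsv")
    return truth
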