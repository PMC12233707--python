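"""End-to-end orchestration: reference -> collapse -> map -> annotate ->
counts -> differential abundance -> profiles, with a config file, stage
counters and a hashed output manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, fragannot, hiermap, profiles, readprep, tref

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_STAGE = 4


class ConfigError(Exception):
    exit_code = EXIT_CONFIG


class DataError(Exception):
    exit_code = EXIT_DATA


class StageError(Exception):
    exit_code = EXIT_STAGE

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run.

    The reference is given either as a directory written by
    ``ReferenceSet.write`` (``refdir``) or as body FASTA + metadata TSV
    (+ optional rRNA FASTA).  FASTQ files must be named
    ``{sample_id}.fastq[.gz]`` under ``fastq_dir`` and match the design
    table 1:1.
    """

    fastq_dir: str = "fastq"
    design_table: str = "design.tsv"
    outdir: str = "out"
    refdir: str | None = None
    trna_fasta: str | None = None
    trna_meta: str | None = None
    rrna_fasta: str | None = None
    assume_cca_present: bool = False
    adapter_3p: str = ""
    min_overlap: int = 7
    min_len: int = 20
    max_len: int = 50
    discard_no_adapter: bool = True
    padj_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    top_n: int = 20
    minus1_as_zero: bool = False
    seed: int = 0
    heatmap_families: list[str] = field(default_factory=lambda: ["His-GUG", "Lys-CUU"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return Path(path)

    def read_filter(self) -> readprep.ReadFilterConfig:
        if not self.adapter_3p:
            raise ConfigError("adapter_3p is required (the library's 3' adapter)")
        return readprep.ReadFilterConfig(
            adapter_3p=self.adapter_3p,
            min_overlap=self.min_overlap,
            min_len=self.min_len,
            max_len=self.max_len,
            discard_no_adapter=self.discard_no_adapter,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_pipeline_reference(cfg: PipelineConfig) -> tref.ReferenceSet:
    if cfg.refdir:
        return tref.ReferenceSet.read(cfg.refdir)
    if cfg.trna_fasta and cfg.trna_meta:
        return tref.load_reference(
            cfg.trna_fasta, cfg.trna_meta, cfg.rrna_fasta,
            assume_cca_present=cfg.assume_cca_present,
        )
    raise ConfigError("config must set refdir or trna_fasta + trna_meta")


def find_fastqs(cfg: PipelineConfig, design: diffexpr.DesignInfo) -> dict[str, Path]:
    """Match design samples to FASTQ files before any compute."""
    d = Path(cfg.fastq_dir)
    out = {}
    missing = []
    for s in design.samples:
        for suffix in (".fastq.gz", ".fastq", ".fq.gz", ".fq"):
            p = d / f"{s}{suffix}"
            if p.exists():
                out[s] = p
                break
        else:
            missing.append(s)
    if missing:
        raise DataError(f"no FASTQ found for design samples: {missing}")
    return out


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the output manifest (also written).

    Deterministic given config and inputs: re-running yields identical
    content hashes.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage_log: dict[str, dict] = {}

    try:
        design = diffexpr.DesignInfo.read(cfg.design_table)
    except Exception as exc:
        raise ConfigError(f"cannot read design table: {exc}") from exc
    fastqs = find_fastqs(cfg, design)
    rf = cfg.read_filter()

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except (ConfigError, DataError):
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return deco

    @stage("build-ref")
    def ref():
        r = load_pipeline_reference(cfg)
        outputs.update({f"ref/{k}": v for k, v in r.write(outdir / "ref").items()})
        stage_log["build-ref"] = dict(n_trnas=len(r.trnas), n_rrnas=len(r.rrnas))
        return r

    @stage("collapse")
    def collapsed():
        out = {}
        for s in design.samples:
            cr = readprep.collapse_fastq(fastqs[s], s, rf)
            outputs[f"collapsed/{s}.tsv"] = readprep.write_collapsed(cr, outdir / "collapsed")
            stage_log.setdefault("collapse", {})[s] = cr.counters()
            out[s] = cr
        return out

    @stage("map")
    def mapped():
        asgs, summaries = {}, []
        for s in design.samples:
            a = hiermap.map_collapsed(collapsed[s], ref)
            outputs[f"assignments/{s}.tsv"] = hiermap.write_assignments(a, outdir / "assignments")
            summaries.append(hiermap.summarize_mapping(collapsed[s], a))
            asgs[s] = a
        outputs["mapping_summary.tsv"] = hiermap.write_mapping_summary(
            summaries, outdir / "mapping_summary.tsv"
        )
        stage_log["map"] = {
            s.sample_id: dict(n_total=s.n_total, n_trna=s.n_trna,
                              n_rrna=s.n_rrna, n_unmapped=s.n_unmapped)
            for s in summaries
        }
        return asgs

    @stage("annotate")
    def frag_table():
        t = fragannot.build_fragment_table(
            [mapped[s] for s in design.samples], ref, minus1_as_zero=cfg.minus1_as_zero
        )
        outputs.update(
            {k: v for k, v in fragannot.write_fragment_outputs(t, outdir).items()}
        )
        stage_log["annotate"] = dict(n_fragments=len(t))
        return t

    @stage("counts")
    def counts():
        cm = diffexpr.count_matrix(frag_table, design)
        sf = diffexpr.size_factors(cm)
        cm.to_csv(outdir / "count_matrix.tsv", sep="\t", index_label="fragment")
        sf.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t", index_label="sample")
        outputs["count_matrix.tsv"] = outdir / "count_matrix.tsv"
        outputs["size_factors.tsv"] = outdir / "size_factors.tsv"
        return cm, sf

    cm, sf = counts

    @stage("diffexp")
    def de_results():
        base = design.timepoint_order[0]
        res = {}
        for tp in design.timepoint_order[1:]:
            r = diffexpr.wald_test(cm, design, (base, tp), sf=sf)
            key = f"de_{tp}_vs_{base}.tsv"
            outputs[key] = diffexpr.write_de_table(
                r, outdir / key, cfg.padj_cutoff, cfg.lfc_cutoff
            )
            res[tp] = r
        return res

    @stage("profile")
    def _profiles():
        vst = profiles.variance_stabilize(cm, sf)
        proj = profiles.run_pca(vst)
        outputs["pca.tsv"] = proj.write(outdir / "pca.tsv")
        for fam in cfg.heatmap_families:
            top = profiles.top_n_fragments(frag_table, fam, cfg.top_n)
            rows = [f"{fam}:{name}" for name in top]
            rows = [r for r in rows if r in vst.index]
            if not rows:
                continue
            hm = profiles.zscore_heatmap(vst.loc[rows])
            outputs[f"heatmap_{fam}.tsv"] = hm.write(outdir / f"heatmap_{fam}.tsv")
        base = design.timepoint_order[0]
        for tp, r in de_results.items():
            vt = profiles.volcano_table(r, cfg.padj_cutoff, cfg.lfc_cutoff)
            key = f"volcano_{tp}_vs_{base}.tsv"
            vt.to_csv(outdir / key, sep="\t", index=False)
            outputs[key] = outdir / key
        trends = profiles.family_trends(cm / sf, design)
        trends.to_csv(outdir / "family_trends.tsv", sep="\t", index=False)
        outputs["family_trends.tsv"] = outdir / "family_trends.tsv"

    manifest = {
        "outputs": {k: _sha256(Path(v)) for k, v in sorted(outputs.items())},
        "stages": stage_log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "stage_counters.json").write_text(json.dumps(stage_log, indent=2) + "\n")
    return manifest
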