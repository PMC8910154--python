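"""End-to-end workflow orchestration with plain-text intermediates.

The pipeline runs seven stages — simulate, annotate, quantify, context,
signatures, de, classify — writing every intermediate as TSV/BED/GTF/FASTQ
(never binary), a deterministic manifest of outputs and checksums, and a log
with wall times. Any stage can be re-run from the intermediates of the
previous ones, so deleting a downstream file and re-running reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, align_annotate, context, io_formats, quantify, signatures
from . import classify as classify_mod
from . import stats as stats_mod
from . import synthetic_data as synth
from .intervals import AnnotationTrack

STAGES = ["simulate", "annotate", "quantify", "context", "signatures", "de", "classify"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


_KNOWN_KEYS = {
    "seed", "simulate", "adapter", "min_len", "max_len", "max_mismatch",
    "max_positions", "presence_rule", "alpha", "z_threshold", "de_groups",
    "component_grid", "keepx_grid", "min_pirna_overlap_frac", "exclusion_min_bp",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    adapter: str = ""
    min_len: int = 20
    max_len: int = 32
    max_mismatch: int = 1
    max_positions: int = 50
    min_pirna_overlap_frac: float = 0.5
    exclusion_min_bp: int = 1
    presence_rule: dict = field(default_factory=lambda: {"min_all": 2, "min_half": 10})
    alpha: float = 0.05
    z_threshold: float = signatures.PINGPONG_Z_THRESHOLD
    de_groups: list = field(default_factory=lambda: ["control", "PD"])
    component_grid: list = field(default_factory=lambda: list(range(1, 11)))
    keepx_grid: list | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "simulate": self.simulate, "adapter": self.adapter,
            "min_len": self.min_len, "max_len": self.max_len,
            "max_mismatch": self.max_mismatch, "max_positions": self.max_positions,
            "min_pirna_overlap_frac": self.min_pirna_overlap_frac,
            "exclusion_min_bp": self.exclusion_min_bp,
            "presence_rule": self.presence_rule, "alpha": self.alpha,
            "z_threshold": self.z_threshold, "de_groups": self.de_groups,
            "component_grid": self.component_grid, "keepx_grid": self.keepx_grid,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_config(self) -> synth.SimConfig:
        overrides = dict(self.simulate)
        groups = overrides.pop("groups", None)
        cfg = synth.SimConfig(seed=self.seed, adapter=self.adapter)
        for key, val in overrides.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown simulate key {key!r}")
            setattr(cfg, key, tuple(val) if isinstance(getattr(cfg, key), tuple) else val)
        if groups is not None:
            cfg.groups = [synth.GroupSpec(g["name"], g["n_samples"],
                                          dict(g.get("fold_change", {})))
                          for g in groups]
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, **params) -> None:
    io_formats.write_tsv(df, path, params={"config_hash": cfg.config_hash, **params})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------- simulate


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    sim_cfg = cfg.sim_config()
    genome = synth.simulate_genome(sim_cfg)
    cohort = synth.simulate_reads(sim_cfg, genome)
    sdir = out / "simulate"
    sdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(genome.genome, sdir / "genome.fa")
    io_formats.write_bed(genome.pirna, sdir / "pirna.bed")
    io_formats.write_bed(genome.ncrna, sdir / "ncrna.bed")
    io_formats.write_bed(genome.repeats, sdir / "repeats.bed")
    io_formats.write_gtf_features(genome.transcripts, sdir / "transcripts.gtf")
    io_formats.write_sample_sheet(cohort.sample_sheet, sdir / "samples.tsv")
    (sdir / "reads").mkdir(exist_ok=True)
    for sample, reads in cohort.reads.items():
        io_formats.write_fastq(reads, sdir / "reads" / f"{sample}.fastq")
    _write_tsv(cohort.read_truth, sdir / "truth_reads.tsv", cfg)
    _write_tsv(cohort.locus_truth, sdir / "truth_loci.tsv", cfg)
    _write_tsv(genome.locus_table, sdir / "locus_table.tsv", cfg)
    return {"genome": genome, "cohort": cohort}


def _load_simulate(out: Path) -> dict:
    sdir = out / "simulate"
    genome_seq = io_formats.read_fasta(sdir / "genome.fa")
    pirna = io_formats.read_bed(sdir / "pirna.bed")
    ncrna = io_formats.read_bed(sdir / "ncrna.bed")
    repeats = io_formats.read_bed(sdir / "repeats.bed")
    for iv in repeats:
        iv.attrs["class"] = iv.label.split("-")[0]
    transcripts = io_formats.read_gtf_features(sdir / "transcripts.gtf")
    sheet = io_formats.read_sample_sheet(sdir / "samples.tsv")
    genome = synth.SimGenome(genome_seq, pirna, ncrna, repeats, transcripts,
                             io_formats.read_tsv(sdir / "locus_table.tsv"))
    reads = {s: io_formats.read_fastq(sdir / "reads" / f"{s}.fastq")
             for s in sheet.sample_ids}
    cohort = synth.SimCohort(reads, sheet,
                             io_formats.read_tsv(sdir / "truth_reads.tsv"),
                             io_formats.read_tsv(sdir / "truth_loci.tsv"))
    return {"genome": genome, "cohort": cohort}


# ---------------------------------------------------------------- annotate


def _serialize_annotated(anns: list[align_annotate.AnnotatedRead]) -> pd.DataFrame:
    rows = []
    for ann in anns:
        r = ann.read
        placements = ";".join(f"{p.chrom}:{p.start}:{p.strand}:{p.mismatches}"
                              for p in r.placements)
        pids = ";".join("|".join(ids) for ids in ann.pirna_ids) if ann.pirna_ids else ""
        rows.append({"read_id": r.read_id, "seq": r.seq, "category": ann.category,
                     "placements": placements, "pirna_ids": pids})
    return pd.DataFrame(rows, columns=["read_id", "seq", "category", "placements", "pirna_ids"])


def _deserialize_annotated(df: pd.DataFrame) -> list[align_annotate.AnnotatedRead]:
    out = []
    for row in df.itertuples(index=False):
        placements = []
        for item in str(row.placements).split(";"):
            chrom, start, strand, mm = item.rsplit(":", 3)
            placements.append(align_annotate.Placement(chrom, int(start), strand, int(mm)))
        read = align_annotate.AlignedRead(row.read_id, row.seq, placements)
        pids_field = "" if pd.isna(row.pirna_ids) else str(row.pirna_ids)
        pirna_ids = ([ids.split("|") if ids else [] for ids in pids_field.split(";")]
                     if pids_field else [])
        out.append(align_annotate.AnnotatedRead(read, row.category, pirna_ids))
    return out


def stage_annotate(cfg: RunConfig, out: Path, state: dict) -> dict:
    genome, cohort = state["genome"], state["cohort"]
    adir = out / "annotate"
    adir.mkdir(parents=True, exist_ok=True)
    index = align_annotate.GenomeIndex(genome.genome, seed_len=cfg.min_len // 2)
    ncrna_track = AnnotationTrack(genome.ncrna)
    pirna_track = AnnotationTrack(genome.pirna)
    annotated: dict[str, list] = {}
    lib_sizes: dict[str, int] = {}
    summary_rows = []
    for sample in cohort.sample_sheet.sample_ids:
        kept, report = align_annotate.trim_and_filter(
            cohort.reads[sample], cfg.adapter, cfg.min_len, cfg.max_len)
        aligned = align_annotate.mini_align(kept, index, cfg.max_mismatch,
                                            cfg.max_positions)
        anns = align_annotate.classify_reads(
            aligned, ncrna_track, pirna_track,
            cfg.min_pirna_overlap_frac, cfg.exclusion_min_bp)
        annotated[sample] = anns
        lib_sizes[sample] = len(aligned)
        counts = align_annotate.classification_summary(anns)
        summary_rows.append({"sample": sample, **report, "aligned": len(aligned),
                             **{k: v for k, v in counts.items() if k != "total"}})
        _write_tsv(_serialize_annotated(anns), adir / f"{sample}.tsv", cfg)
    _write_tsv(pd.DataFrame(summary_rows), adir / "summary.tsv", cfg)
    _write_tsv(pd.DataFrame(lib_sizes.items(), columns=["sample", "lib_size"]),
               adir / "lib_sizes.tsv", cfg)
    return {"annotated": annotated, "lib_sizes": lib_sizes}


def _load_annotate(out: Path, state: dict) -> dict:
    adir = out / "annotate"
    sheet = state["cohort"].sample_sheet
    annotated = {s: _deserialize_annotated(io_formats.read_tsv(adir / f"{s}.tsv"))
                 for s in sheet.sample_ids}
    lib_df = io_formats.read_tsv(adir / "lib_sizes.tsv")
    return {"annotated": annotated,
            "lib_sizes": dict(zip(lib_df["sample"], lib_df["lib_size"]))}


# ---------------------------------------------------------------- quantify


def stage_quantify(cfg: RunConfig, out: Path, state: dict) -> dict:
    qdir = out / "quantify"
    qdir.mkdir(parents=True, exist_ok=True)
    cohort = state["cohort"]
    cm = quantify.build_counts(state["annotated"], cohort.sample_sheet,
                               state["lib_sizes"])
    rule = quantify.PresenceRule(**cfg.presence_rule)
    present = quantify.call_present(cm, rule)
    counts_out = cm.counts.reset_index().rename(columns={"index": "pirna_id"})
    _write_tsv(counts_out, qdir / "counts.tsv", cfg)
    _write_tsv(pd.DataFrame({"pirna_id": sorted(present)}), qdir / "present.tsv", cfg)

    chrom_lengths = state["genome"].chrom_lengths
    rpkm_rows = []
    for sample in cm.sample_ids:
        if not present:
            break
        dist = quantify.chromosome_rpkm(state["annotated"][sample], chrom_lengths, present)
        for chrom, val in pd.concat([dist.rpkm, dist.mito]).items():
            rpkm_rows.append({"sample": sample, "chrom": chrom, "rpkm": val,
                              "mitochondrial": chrom in quantify.MT_NAMES})
    _write_tsv(pd.DataFrame(rpkm_rows), qdir / "rpkm.tsv", cfg)

    groups = cohort.sample_sheet.table.groupby("group")["sample"].apply(list)
    sets = {}
    for group, smp in groups.items():
        sub = quantify.CountMatrix(cm.counts[smp], cm.lib_size[smp], cohort.sample_sheet)
        sets[group] = quantify.call_present(sub, rule)
    if len(sets) >= 2:
        _write_tsv(quantify.compare_sets(sets), qdir / "venn.tsv", cfg)
    return {"count_matrix": cm, "present": present}


def _load_quantify(out: Path, state: dict) -> dict:
    qdir = out / "quantify"
    counts = io_formats.read_tsv(qdir / "counts.tsv").set_index("pirna_id")
    lib = pd.Series(state["lib_sizes"], dtype=float)[counts.columns]
    cm = quantify.CountMatrix(counts, lib, state["cohort"].sample_sheet)
    present = set(io_formats.read_tsv(qdir / "present.tsv")["pirna_id"])
    return {"count_matrix": cm, "present": present}


# ---------------------------------------------------------------- context


def stage_context(cfg: RunConfig, out: Path, state: dict) -> dict:
    cdir = out / "context"
    cdir.mkdir(parents=True, exist_ok=True)
    genome = state["genome"]
    repeat_track = AnnotationTrack(genome.repeats)
    tx_track = AnnotationTrack(genome.transcripts)
    profiles = {}
    rows = []
    for sample, anns in state["annotated"].items():
        prof = context.profile_context(anns, repeat_track, tx_track)
        profiles[sample] = prof
        ratio = prof.ratio
        for (cls, ori), row in ratio.iterrows():
            rows.append({"sample": sample, "class": cls, "orientation": ori,
                         "count": row["count"], "ratio": row["ratio"]})
    _write_tsv(pd.DataFrame(rows), cdir / "context.tsv", cfg)

    gene_counts = context.gene_pirna_counts(state["annotated"], tx_track)
    _write_tsv(gene_counts.reset_index().rename(columns={"index": "gene_id"}),
               cdir / "gene_counts.tsv", cfg)
    stringent = context.filter_genes(gene_counts, context.GeneAlignmentRule("stringent"))
    relaxed = context.filter_genes(gene_counts, context.GeneAlignmentRule("relaxed"))
    _write_tsv(pd.DataFrame({"gene_id": sorted(set(stringent) | set(relaxed)),
                             "stringent": [g in stringent for g in
                                           sorted(set(stringent) | set(relaxed))],
                             "relaxed": [g in relaxed for g in
                                         sorted(set(stringent) | set(relaxed))]}),
               cdir / "pirna_aligned_genes.tsv", cfg)

    sheet = state["cohort"].sample_sheet
    groups = list(dict.fromkeys(sheet.table["group"]))
    comp_rows = []
    if len(groups) >= 2:
        prof_a = [profiles[s] for s in sheet.samples_in_group(groups[0])]
        prof_b = [profiles[s] for s in sheet.samples_in_group(groups[1])]
        if len(prof_a) >= 3 and len(prof_b) >= 3:
            for cls in context.REPEAT_PANEL + context.BIOTYPE_PANEL:
                for ori in context.ORIENTATIONS:
                    comp_rows.append(context.compare_context(prof_a, prof_b, cls, ori))
    _write_tsv(pd.DataFrame(comp_rows), cdir / "context_comparison.tsv", cfg)
    return {"profiles": profiles, "gene_counts": gene_counts}


# ---------------------------------------------------------------- signatures


def stage_signatures(cfg: RunConfig, out: Path, state: dict) -> dict:
    sdir = out / "signatures"
    sdir.mkdir(parents=True, exist_ok=True)
    rows, spec_rows = [], []
    profiles = {}
    for sample, anns in state["annotated"].items():
        prof = signatures.signature_report(anns)
        profiles[sample] = prof
        rows.append({"sample": sample, "n_reads": prof.n_reads,
                     "u1_fraction": prof.u1_fraction, "a10_fraction": prof.a10_fraction,
                     "pingpong_z": "" if prof.pingpong_z is None else prof.pingpong_z,
                     "verdict": signatures.verdict(prof, cfg.z_threshold)})
        for k, val in enumerate(prof.overlap_spectrum, start=1):
            spec_rows.append({"sample": sample, "overlap": k, "weighted_count": val})
    _write_tsv(pd.DataFrame(rows), sdir / "signatures.tsv", cfg)
    _write_tsv(pd.DataFrame(spec_rows), sdir / "spectra.tsv", cfg)
    return {"signature_profiles": profiles}


# ---------------------------------------------------------------- de


def stage_de(cfg: RunConfig, out: Path, state: dict) -> dict:
    ddir = out / "de"
    ddir.mkdir(parents=True, exist_ok=True)
    cm = state["count_matrix"]
    present = sorted(state["present"])
    sub = quantify.CountMatrix(cm.counts.loc[[p for p in present if p in cm.counts.index]],
                               cm.lib_size, cm.meta) if present else cm
    group_a, group_b = cfg.de_groups[:2]
    de = stats_mod.diff_expression(sub, group_a, group_b, cfg.alpha)
    _write_tsv(de, ddir / "de.tsv", cfg, group_a=group_a, group_b=group_b)
    return {"de": de}


# ---------------------------------------------------------------- classify


def stage_classify(cfg: RunConfig, out: Path, state: dict) -> dict:
    kdir = out / "classify"
    kdir.mkdir(parents=True, exist_ok=True)
    cm = state["count_matrix"]
    x = cm.cpm().T  # samples x features
    y = [cm.meta.group_of(s) for s in x.index]
    report = classify_mod.tune_and_evaluate(
        x, y, component_grid=cfg.component_grid,
        keepx_grid=cfg.keepx_grid)
    _write_tsv(report.component_grid, kdir / "component_grid.tsv", cfg)
    _write_tsv(report.keepx_grid, kdir / "keepx_grid.tsv", cfg)
    _write_tsv(report.fold_predictions, kdir / "fold_predictions.tsv", cfg)
    vip_scores = classify_mod.vip(report.model)
    _write_tsv(vip_scores.reset_index().rename(columns={"index": "feature"}),
               kdir / "vip.tsv", cfg)
    summary = pd.DataFrame([{"chosen_components": report.chosen_components,
                             "chosen_keepX": ",".join(map(str, report.chosen_keepX)),
                             "loo_accuracy": report.accuracy, "loo_auc": report.auc}])
    _write_tsv(summary, kdir / "cv_summary.tsv", cfg)
    return {"cv_report": report}


# ---------------------------------------------------------------- driver


_LOADERS = {
    "simulate": lambda cfg, out, state: _load_simulate(out),
    "annotate": lambda cfg, out, state: _load_annotate(out, state),
    "quantify": lambda cfg, out, state: _load_quantify(out, state),
}


def run_pipeline(cfg: RunConfig, out_dir: str | Path, from_stage: str | None = None) -> Path:
    """Execute the workflow, optionally resuming from a later stage.

    With ``from_stage`` set, earlier stages are loaded from their on-disk
    intermediates instead of recomputed; outputs are otherwise identical. A
    manifest (stage, outputs, checksums) and a wall-time log are written at
    the end; the manifest is deterministic for a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start_idx = STAGES.index(from_stage) if from_stage else 0
    runners = {
        "simulate": lambda: stage_simulate(cfg, out),
        "annotate": lambda: stage_annotate(cfg, out, state),
        "quantify": lambda: stage_quantify(cfg, out, state),
        "context": lambda: stage_context(cfg, out, state),
        "signatures": lambda: stage_signatures(cfg, out, state),
        "de": lambda: stage_de(cfg, out, state),
        "classify": lambda: stage_classify(cfg, out, state),
    }
    state: dict = {}
    manifest_rows = []
    log_lines = [f"soma-pirna v{__version__} config_hash={cfg.config_hash}"]
    for i, stage in enumerate(STAGES):
        t0 = time.perf_counter()
        try:
            if i < start_idx:
                if stage in _LOADERS:
                    state.update(_LOADERS[stage](cfg, out, state))
                    log_lines.append(f"{stage}: loaded from intermediates")
                continue
            state.update(runners[stage]())
        except Exception as exc:
            (out / "run.log").write_text("\n".join(
                log_lines + [f"{stage}: FAILED ({exc})"]) + "\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        log_lines.append(f"{stage}: ok ({elapsed:.2f}s)")
        stage_dir = out / stage
        if stage_dir.is_dir():
            for path in sorted(stage_dir.rglob("*")):
                if path.is_file():
                    manifest_rows.append({
                        "stage": stage,
                        "output": str(path.relative_to(out)),
                        "sha256": _sha256(path),
                    })
    manifest = pd.DataFrame(manifest_rows)
    io_formats.write_tsv(manifest, out / "manifest.tsv",
                         params={"config_hash": cfg.config_hash})
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
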