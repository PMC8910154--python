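"""Synthetic genomes, annotation tracks, and read cohorts with known truth.

The generator emulates the statistical structure of small-RNA cohorts used
for somatic piRNA analysis: multi-sample groups with planted fold changes on
piRNA loci, reads from transposons on both strands, transcript 3'UTRs,
pseudogenes and lncRNAs, decoy small-ncRNA loci whose reads must be excluded,
multi-mapping reads from duplicated sequence, germline-like ping-pong read
pairs with 1U/10A bias, and per-sample library-size variation. Truth tables
(per-read source and per-locus expected group means) are part of the public
API so downstream stages can be tested against them.

Reads are exact substrings of the genome; the aligner's one-mismatch
tolerance is exercised separately by mutating a configurable read fraction by
exactly one substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, SampleSheet, _revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DECOY_CLASSES = ("tRNA", "rRNA", "miRNA", "snoRNA")
REPEAT_CLASSES = ("LINE", "SINE", "LTR", "DNA", "simple_repeat")
TRANSPOSON_CLASSES = ("LINE", "SINE", "LTR", "DNA")


@dataclass
class GroupSpec:
    """One cohort group: name, size, and planted per-locus fold changes."""

    name: str
    n_samples: int
    fold_change: dict[str, float] = field(default_factory=dict)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate a two-group brain cohort (14 control vs 14 disease
    samples, matching the amygdala arm of the motivating study) with six
    4-fold dysregulated piRNA loci, ~20% of piRNA loci hosted in transposons,
    and somatic-like biogenesis (no ping-pong pairs, uniform first-base
    composition). Germline-like conditions are available via
    :func:`germline_config`.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 60_000
    n_pirna_loci: int = 60
    n_decoy_ncrna_loci: int = 20
    n_repeat_loci: dict[str, int] = field(
        default_factory=lambda: {c: 8 for c in REPEAT_CLASSES}
    )
    n_genes: int = 20
    n_lncrna: int = 8
    n_pseudogenes: int = 10
    pirna_locus_len_range: tuple[int, int] = (60, 90)
    pirna_len_range: tuple[int, int] = (20, 30)  # somatic-like read lengths
    # fraction of piRNA loci hosted in each genomic context (rest intergenic)
    context_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "transposon": 0.20,
            "3UTR": 0.15,
            "pseudogene": 0.15,
            "lncRNA": 0.10,
        }
    )
    utr_repeat_gene_fraction: float = 0.25  # genes with a repeat fragment in the 3'UTR
    groups: list[GroupSpec] = field(
        default_factory=lambda: [
            GroupSpec("control", 14),
            GroupSpec("PD", 14, {f"piR-sim-{i:04d}": 4.0 for i in range(1, 7)}),
        ]
    )
    pingpong_enabled: bool = False
    pingpong_pair_fraction: float = 0.0
    u1_fraction: float = 0.25  # uniform base composition when 0.25
    a10_fraction: float = 0.25
    libsize_mean: float = 3000.0  # expected reads per sample
    libsize_sigma: float = 0.25  # lognormal sd of per-sample depth factor
    decoy_read_fraction: float = 0.15
    background_read_fraction: float = 0.05
    multimap_fraction: float = 0.10  # piRNA loci duplicated elsewhere in genome
    mutate_fraction: float = 0.0  # reads given exactly one substitution
    adapter: str = ""
    tissue: str = "brain_like"
    # Minimum gap between top-level planted loci. Real piRNA loci are separated
    # by distances orders of magnitude beyond read length; keeping the gap well
    # above the 20-nt ping-pong window prevents reads of adjacent opposite-strand
    # loci from fabricating 5'-overlap geometry that real data does not contain.
    locus_margin: int = 100

    def __post_init__(self) -> None:
        for name, frac in [
            ("pingpong_pair_fraction", self.pingpong_pair_fraction),
            ("u1_fraction", self.u1_fraction),
            ("a10_fraction", self.a10_fraction),
            ("decoy_read_fraction", self.decoy_read_fraction),
            ("background_read_fraction", self.background_read_fraction),
            ("multimap_fraction", self.multimap_fraction),
            ("mutate_fraction", self.mutate_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        for g in self.groups:
            if any(fc <= 0 for fc in g.fold_change.values()):
                raise ValueError(f"fold changes must be > 0 (group {g.name})")
        if sum(self.context_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("context fractions must sum to <= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def germline_config(**overrides) -> SimConfig:
    """Germline-like preset: ping-pong pairs, strong 1U/10A bias, 24-32 nt reads."""
    cfg = SimConfig(
        pirna_len_range=(24, 32),
        pingpong_enabled=True,
        pingpong_pair_fraction=0.3,
        u1_fraction=0.75,
        a10_fraction=0.5,
        groups=[GroupSpec("germline", 4)],
        tissue="testis_like",
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@dataclass
class SimGenome:
    """A simulated genome plus its annotation tracks and locus table."""

    genome: dict[str, str]
    pirna: list[GenomicInterval]
    ncrna: list[GenomicInterval]
    repeats: list[GenomicInterval]
    transcripts: list[GenomicInterval]  # GTF-style gene features
    locus_table: pd.DataFrame  # locus_id, chrom, start, end, strand, context, n_copies
    # every planted interval incl. unannotated duplicate copies; background
    # reads are drawn outside these so their truth label stays unambiguous
    occupied: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


@dataclass
class SimCohort:
    """Per-sample reads plus truth tables."""

    reads: dict[str, list[tuple[str, str]]]
    sample_sheet: SampleSheet
    read_truth: pd.DataFrame  # sample, read_id, locus_id, source, pair_id, mutated
    locus_truth: pd.DataFrame  # locus_id, group, expected_mean_reads


class _Placer:
    """Non-overlapping top-level interval placement on a multi-chrom genome."""

    def __init__(self, chrom_lengths: dict[str, int], rng: np.random.Generator):
        self.lengths = chrom_lengths
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def place(self, length: int, margin: int = 100, max_tries: int = 2000) -> tuple[str, int]:
        chroms = list(self.lengths)
        for _ in range(max_tries):
            chrom = chroms[self.rng.integers(len(chroms))]
            limit = self.lengths[chrom] - length
            if limit <= 0:
                continue
            start = int(self.rng.integers(0, limit))
            lo, hi = start - margin, start + length + margin
            if all(e <= lo or s >= hi for s, e in self.occupied[chrom]):
                self.occupied[chrom].append((start, start + length))
                return chrom, start
        raise ValueError(
            f"could not place a {length} bp locus: genome too crowded for the "
            "requested locus counts"
        )


def _random_genome(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    genome = {}
    for i in range(cfg.n_chroms):
        arr = _BASES[rng.integers(0, 4, size=cfg.chrom_len)]
        genome[f"chr{i + 1}"] = arr.tobytes().decode()
    return genome


def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Build a random genome with planted, non-overlapping annotation tracks.

    piRNA loci are allocated across genomic contexts per
    ``cfg.context_fractions`` (hosted inside transposon repeats, protein-coding
    3'UTRs, pseudogene and lncRNA exons; remainder intergenic). A
    ``multimap_fraction`` of piRNA loci have their sequence copied verbatim to
    an unannotated second location, so their reads map twice. A fraction of
    protein-coding genes carry a diverged repeat fragment inside the 3'UTR.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    genome = _random_genome(cfg, rng)
    seqs = {c: bytearray(s.encode()) for c, s in genome.items()}
    placer = _Placer({c: len(s) for c, s in genome.items()}, rng)

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    repeats: list[GenomicInterval] = []
    for cls, n in cfg.n_repeat_loci.items():
        for i in range(n):
            length = int(rng.integers(150, 400))
            chrom, start = placer.place(length, cfg.locus_margin)
            repeats.append(
                GenomicInterval(chrom, start, start + length, rand_strand(), f"{cls}-sim-{i + 1}",
                                {"class": cls})
            )

    transcripts: list[GenomicInterval] = []
    utr3_hosts: list[GenomicInterval] = []
    utr5_len, cds_len, utr3_len = 60, 300, 200
    gene_len = utr5_len + cds_len + utr3_len
    n_utr_repeat = int(round(cfg.utr_repeat_gene_fraction * cfg.n_genes))
    transposon_repeats = [r for r in repeats if r.attrs["class"] in TRANSPOSON_CLASSES]
    for i in range(cfg.n_genes):
        gid = f"gene{i + 1:03d}"
        chrom, start = placer.place(gene_len, cfg.locus_margin)
        strand = rand_strand()
        if strand == "+":
            parts = [("5UTR", start, start + utr5_len),
                     ("CDS", start + utr5_len, start + utr5_len + cds_len),
                     ("3UTR", start + utr5_len + cds_len, start + gene_len)]
        else:
            parts = [("3UTR", start, start + utr3_len),
                     ("CDS", start + utr3_len, start + utr3_len + cds_len),
                     ("5UTR", start + utr3_len + cds_len, start + gene_len)]
        for kind, s, e in parts:
            transcripts.append(GenomicInterval(chrom, s, e, strand, gid,
                                               {"feature": kind, "biotype": "protein_coding"}))
        transcripts.append(GenomicInterval(chrom, start, start + gene_len, strand, gid,
                                           {"feature": "exon", "biotype": "protein_coding"}))
        utr3 = next(iv for iv in transcripts if iv.label == gid and iv.attrs["feature"] == "3UTR")
        utr3_hosts.append(utr3)
        if i < n_utr_repeat and transposon_repeats:
            # plant a diverged transposon fragment inside this 3'UTR
            src = transposon_repeats[int(rng.integers(len(transposon_repeats)))]
            frag_len = 80
            frag = bytearray(seqs[src.chrom][src.start : src.start + frag_len])
            n_mut = max(1, frag_len // 10)
            for pos in rng.choice(frag_len, size=n_mut, replace=False):
                frag[pos] = _BASES[rng.integers(0, 4)][0]
            offset = int(rng.integers(0, utr3_len - frag_len))
            dest = utr3.start + offset
            seqs[utr3.chrom][dest : dest + frag_len] = frag
            repeats.append(GenomicInterval(
                utr3.chrom, dest, dest + frag_len, src.strand,
                f"{src.attrs['class']}-utr-{i + 1}", {"class": src.attrs["class"]}))

    lnc_hosts: list[GenomicInterval] = []
    for i in range(cfg.n_lncrna):
        length = int(rng.integers(300, 600))
        chrom, start = placer.place(length, cfg.locus_margin)
        iv = GenomicInterval(chrom, start, start + length, rand_strand(), f"lnc{i + 1:03d}",
                             {"feature": "exon", "biotype": "lncRNA"})
        transcripts.append(iv)
        lnc_hosts.append(iv)

    pseudo_hosts: list[GenomicInterval] = []
    for i in range(cfg.n_pseudogenes):
        length = int(rng.integers(200, 400))
        chrom, start = placer.place(length, cfg.locus_margin)
        iv = GenomicInterval(chrom, start, start + length, rand_strand(), f"gene{i + 1:03d}P",
                             {"feature": "exon", "biotype": "pseudogene"})
        transcripts.append(iv)
        pseudo_hosts.append(iv)

    ncrna: list[GenomicInterval] = []
    for i in range(cfg.n_decoy_ncrna_loci):
        cls = DECOY_CLASSES[i % len(DECOY_CLASSES)]
        length = int(rng.integers(70, 150))
        chrom, start = placer.place(length, cfg.locus_margin)
        ncrna.append(GenomicInterval(chrom, start, start + length, rand_strand(),
                                     f"{cls}-sim-{i + 1}", {"class": cls}))

    # --- piRNA loci across contexts ---
    n_ctx = {ctx: int(round(frac * cfg.n_pirna_loci))
             for ctx, frac in cfg.context_fractions.items()}
    n_intergenic = cfg.n_pirna_loci - sum(n_ctx.values())
    if n_intergenic < 0:
        raise ValueError("context fractions allocate more loci than n_pirna_loci")
    host_pools = {
        "transposon": [r for r in repeats if r.attrs["class"] in TRANSPOSON_CLASSES],
        "3UTR": utr3_hosts,
        "pseudogene": pseudo_hosts,
        "lncRNA": lnc_hosts,
    }
    plan: list[tuple[str, GenomicInterval | None]] = [("intergenic", None)] * n_intergenic
    for ctx in ("transposon", "3UTR", "pseudogene", "lncRNA"):
        hosts = host_pools[ctx]
        need = n_ctx.get(ctx, 0)
        if need > len(hosts):
            raise ValueError(f"not enough {ctx} hosts for {need} piRNA loci")
        order = rng.permutation(len(hosts))[:need]
        plan.extend((ctx, hosts[j]) for j in order)

    pirna: list[GenomicInterval] = []
    rows = []
    lo, hi = cfg.pirna_locus_len_range
    for idx, (ctx, host) in enumerate(plan, start=1):
        pid = f"piR-sim-{idx:04d}"
        length = int(rng.integers(lo, hi + 1))
        if host is None:
            chrom, start = placer.place(length, cfg.locus_margin)
            strand = rand_strand()
        else:
            chrom = host.chrom
            length = min(length, len(host))
            start = host.start + int(rng.integers(0, len(host) - length + 1))
            # hosted loci sit on either strand of the host feature
            strand = host.strand if rng.random() < 0.5 else ("-" if host.strand == "+" else "+")
        n_copies = 1
        if rng.random() < cfg.multimap_fraction:
            # duplicate the locus sequence verbatim at an unannotated position
            dchrom, dstart = placer.place(length, cfg.locus_margin)
            seqs[dchrom][dstart : dstart + length] = seqs[chrom][start : start + length]
            n_copies = 2
        pirna.append(GenomicInterval(chrom, start, start + length, strand, pid, {"context": ctx}))
        rows.append({"locus_id": pid, "chrom": chrom, "start": start, "end": start + length,
                     "strand": strand, "context": ctx, "n_copies": n_copies})

    genome = {c: bytes(b).decode() for c, b in seqs.items()}
    return SimGenome(genome, pirna, ncrna, repeats, transcripts, pd.DataFrame(rows),
                     {c: sorted(iv) for c, iv in placer.occupied.items()})


def _pick_read(seq: str, locus_start: int, locus_end: int, strand: str,
               len_range: tuple[int, int], want_u1: bool, want_a10: bool,
               rng: np.random.Generator) -> tuple[int, int]:
    """Choose (start, length) for a read inside a locus honoring base biases.

    The read is an exact genome substring, so biases are planted by choosing
    5' positions whose genomic base already satisfies them; if no position
    does, the requirement is dropped (rejection-free fallback).
    """
    length = int(rng.integers(len_range[0], len_range[1] + 1))
    length = min(length, locus_end - locus_start)
    starts = np.arange(locus_start, locus_end - length + 1)
    if len(starts) == 0:
        return locus_start, length
    ok = np.ones(len(starts), dtype=bool)
    if want_u1 or want_a10:
        for i, s in enumerate(starts):
            if strand == "+":
                b1, b10 = seq[s], seq[s + 9]
            else:
                b1 = _revcomp(seq[s + length - 1])
                b10 = _revcomp(seq[s + length - 10])
            if want_u1 and b1 != "T":
                ok[i] = False
            elif want_a10 and b10 != "A":
                ok[i] = False
        if not ok.any():
            ok[:] = True
    return int(rng.choice(starts[ok])), length


def simulate_reads(cfg: SimConfig, sim: SimGenome) -> SimCohort:
    """Draw per-sample reads from locus expression with planted structure.

    Per-locus baseline expression is log-normal; each sample's expected count
    is baseline x group fold change x a per-sample log-normal depth factor
    with unit mean, and realized counts are Poisson. Germline-like runs emit
    ping-pong mates: for ``pingpong_pair_fraction`` of piRNA reads, an
    opposite-strand mate whose 5' end overlaps the primary's 5' end by exactly
    10 nt, with 1U on the primary (hence 10A on the mate by complementarity).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    pirna_share = 1.0 - cfg.decoy_read_fraction - cfg.background_read_fraction
    if pirna_share <= 0:
        raise ValueError("decoy + background read fractions must leave room for piRNA reads")

    def _baselines(loci: list[GenomicInterval], total: float) -> dict[str, float]:
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=len(loci))
        raw *= total / raw.sum()
        return {iv.label: float(b) for iv, b in zip(loci, raw)}

    base_pirna = _baselines(sim.pirna, cfg.libsize_mean * pirna_share)
    base_decoy = _baselines(sim.ncrna, cfg.libsize_mean * cfg.decoy_read_fraction)
    bg_mean = cfg.libsize_mean * cfg.background_read_fraction

    locus_rows = []
    for g in cfg.groups:
        for iv in sim.pirna:
            fc = g.fold_change.get(iv.label, 1.0)
            locus_rows.append({"locus_id": iv.label, "group": g.name,
                               "expected_mean_reads": base_pirna[iv.label] * fc})
    pirna_by_id = {iv.label: iv for iv in sim.pirna}
    decoy_by_id = {iv.label: iv for iv in sim.ncrna}

    sheet_rows, reads, truth_rows = [], {}, []
    # unit-mean lognormal depth factor
    mu = -0.5 * cfg.libsize_sigma**2
    for g in cfg.groups:
        for si in range(g.n_samples):
            sample = f"{g.name}_{si + 1:02d}"
            sheet_rows.append({"sample": sample, "group": g.name,
                               "tissue": cfg.tissue, "batch": ""})
            depth = float(rng.lognormal(mu, cfg.libsize_sigma))
            sample_reads: list[tuple[str, str]] = []
            ridx = 0

            def emit(seq_str: str, locus_id: str, source: str, pair_id: str = "") -> None:
                nonlocal ridx
                ridx += 1
                read_id = f"{sample}:r{ridx:06d}"
                mutated = 0
                if cfg.mutate_fraction > 0 and rng.random() < cfg.mutate_fraction:
                    pos = int(rng.integers(len(seq_str)))
                    alt = "ACGT".replace(seq_str[pos], "")[int(rng.integers(3))]
                    seq_str = seq_str[:pos] + alt + seq_str[pos + 1 :]
                    mutated = 1
                if cfg.adapter:
                    seq_str += cfg.adapter
                sample_reads.append((read_id, seq_str))
                truth_rows.append({"sample": sample, "read_id": read_id,
                                   "locus_id": locus_id, "source": source,
                                   "pair_id": pair_id, "mutated": mutated})

            # force the 5' base only often enough that the *final* fraction,
            # including the ~1/4 background rate at unforced positions,
            # matches the configured bias
            force_u1 = max(0.0, (cfg.u1_fraction - 0.25) / 0.75)
            force_a10 = max(0.0, (cfg.a10_fraction - 0.25) / 0.75)
            for locus_id, baseline in base_pirna.items():
                iv = pirna_by_id[locus_id]
                fc = g.fold_change.get(locus_id, 1.0)
                count = int(rng.poisson(baseline * fc * depth))
                chrom_seq = sim.genome[iv.chrom]
                for _ in range(count):
                    make_pair = cfg.pingpong_enabled and rng.random() < cfg.pingpong_pair_fraction
                    want_u1 = make_pair or rng.random() < force_u1
                    want_a10 = (not make_pair) and rng.random() < force_a10
                    start, length = _pick_read(chrom_seq, iv.start, iv.end, iv.strand,
                                               cfg.pirna_len_range, want_u1, want_a10, rng)
                    frag = chrom_seq[start : start + length]
                    seq_str = frag if iv.strand == "+" else _revcomp(frag)
                    pair_id = f"{sample}:pp{ridx + 1}" if make_pair else ""
                    emit(seq_str, locus_id, "pirna", pair_id)
                    if make_pair:
                        # mate on the opposite strand, 5' ends overlapping by 10 nt
                        mlen = int(rng.integers(cfg.pirna_len_range[0],
                                                cfg.pirna_len_range[1] + 1))
                        if iv.strand == "+":
                            m5 = start + 9  # minus-strand mate 5' end (plus coords)
                            mstart = max(iv.start, m5 - mlen + 1)
                            mseq = _revcomp(chrom_seq[mstart : m5 + 1])
                        else:
                            p5 = start + length - 1  # primary 5' on minus strand
                            m5 = p5 - 9  # plus-strand mate 5' end
                            mend = min(iv.end, m5 + mlen)
                            mseq = chrom_seq[m5:mend]
                        if len(mseq) >= cfg.pirna_len_range[0]:
                            emit(mseq, locus_id, "pirna_mate", pair_id)

            for locus_id, baseline in base_decoy.items():
                iv = decoy_by_id[locus_id]
                count = int(rng.poisson(baseline * depth))
                chrom_seq = sim.genome[iv.chrom]
                for _ in range(count):
                    start, length = _pick_read(chrom_seq, iv.start, iv.end, iv.strand,
                                               cfg.pirna_len_range, False, False, rng)
                    frag = chrom_seq[start : start + length]
                    emit(frag if iv.strand == "+" else _revcomp(frag), locus_id, "decoy")

            n_bg = int(rng.poisson(bg_mean * depth))
            chroms = list(sim.genome)
            for _ in range(n_bg):
                length = int(rng.integers(cfg.pirna_len_range[0], cfg.pirna_len_range[1] + 1))
                # intergenic noise: rejection-sample positions clear of every
                # planted interval so truth labels stay unambiguous
                for _attempt in range(100):
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    start = int(rng.integers(0, len(sim.genome[chrom]) - length))
                    end = start + length
                    if all(e <= start or s >= end
                           for s, e in sim.occupied.get(chrom, [])):
                        break
                else:
                    continue
                frag = sim.genome[chrom][start:end]
                emit(frag if rng.random() < 0.5 else _revcomp(frag), "", "background")

            reads[sample] = sample_reads

    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return SimCohort(reads, sheet, pd.DataFrame(truth_rows), pd.DataFrame(locus_rows))
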