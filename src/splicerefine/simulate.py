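"""Synthetic ciliate transcriptome generator with planted truth.

The generator emulates the statistical structure of the Tetrahymena
macronuclear transcriptome: highly A+T-rich noncoding sequence (~87%),
moderately A+T-rich coding sequence (~75%), short introns (mean ~135 bp
within TopHat-style bounds of 10–10,000 bp), multi-intron gene models with
GT..AG introns and ATG..TGA coding sequences under the ciliate nuclear
code, four classes of planted alternative-splicing isoforms with intron
retention dominant, stage-dependent expression spanning several orders of
magnitude across five life-cycle samples, planted annotation defects
(wrong boundaries, missing/extra introns, wrongly merged and wrongly split
models), intergenic novel transcribed regions, and per-gene microarray
probe sets with multiplicative log-scale noise.

Reads are not simulated at the sequence level; the generator emits the
alignment-level evidence the downstream pipeline actually consumes:
junction records with per-sample non-redundant support (Poisson around the
isoform expression), per-base coverage tracks (deterministic, proportional
to expression), per-gene read counts (Poisson) and probe intensities.

Everything is driven by a single :class:`SimConfig`; the same config (and
seed) reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .genetics import first_inframe_stop, longest_orf_either_strand, revcomp
from .models import (
    Annotation,
    CoverageTrack,
    GeneModel,
    Interval,
    Junction,
    SAMPLES,
    STAGE_GROUPS,
)

log = logging.getLogger(__name__)

AS_TYPES = ("cassette", "alt5", "alt3", "IR")


class SimSizeError(ValueError):
    """The requested genes/regions do not fit on the configured scaffolds."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic transcriptome.

    Defaults follow the organism's reported statistics where available
    (A+T fractions, intron length mean and bounds, AS class mix with IR
    dominant, UTRs mostly < 300 bp); scale parameters (gene number,
    scaffold sizes, depth) are desk-scale choices documented in the
    methods note.
    """

    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length: int = 200_000
    n_genes: int = 300
    exons_per_gene: tuple[int, int] = (1, 8)
    intron_mean: float = 135.0
    intron_min: int = 10
    intron_max: int = 10_000
    exon_len_range: tuple[int, int] = (60, 300)
    at_fraction_noncoding: float = 0.87
    at_fraction_coding: float = 0.75
    utr5_range: tuple[int, int] = (30, 180)
    utr3_range: tuple[int, int] = (60, 280)
    intergenic_min: int = 600

    # expression
    expr_log10_range: tuple[float, float] = (-1.0, 3.5)
    stage_profiles: dict = field(
        default_factory=lambda: {s: 1.0 for s in SAMPLES}
    )
    stage_up_fraction: float = 0.08
    stage_up_fold: float = 25.0
    stage_up_min_expr: float = 10.0

    # alternative splicing
    as_rates: dict = field(
        default_factory=lambda: {
            "cassette": 0.006,
            "alt5": 0.010,
            "alt3": 0.010,
            "IR": 0.034,
        }
    )
    minor_isoform_fraction: float = 0.5
    as_min_expr: float = 10.0
    as_stage_specific_fraction: float = 0.12
    ir_secondary_retention: float = 0.0
    ir_dominant_share: float = 1.0

    # annotation defects
    boundary_defect_fraction: float = 0.10
    intron_defect_fraction: float = 0.08
    merged_annotation_fraction: float = 0.03
    split_annotation_fraction: float = 0.03
    defect_min_expr: float = 10.0

    # novel transcribed regions
    novel_count: int = 15
    novel_len_mean: float = 918.0
    novel_len_min: int = 300
    short_novel_count: int = 5
    novel_coding_fraction: float = 0.7
    novel_expr_range: tuple[float, float] = (5.0, 50.0)

    # evidence scale
    depth: float = 4.0  # per-base coverage per expression unit, per sample
    count_depth: float = 50.0  # reads per kb of exon per expression unit
    junction_read_factor: float = 1.0
    anchor_range: tuple[int, int] = (8, 40)

    # microarray / GO
    probe_count_per_gene: int = 5
    probe_length: int = 50
    probe_noise_sd: float = 0.25
    n_go_terms: int = 30
    go_terms_per_gene: tuple[int, int] = (0, 4)

    samples: tuple[str, ...] = SAMPLES

    def validate(self) -> None:
        for name in (
            "at_fraction_noncoding",
            "at_fraction_coding",
            "minor_isoform_fraction",
            "as_stage_specific_fraction",
            "stage_up_fraction",
            "boundary_defect_fraction",
            "intron_defect_fraction",
            "merged_annotation_fraction",
            "split_annotation_fraction",
            "novel_coding_fraction",
            "ir_secondary_retention",
            "ir_dominant_share",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for r in self.as_rates.values():
            if not (0.0 <= r <= 1.0):
                raise ValueError("as_rates must be proportions")
        if not (1 <= self.intron_min <= self.intron_mean <= self.intron_max):
            raise ValueError("intron length parameters inconsistent")
        if self.depth < 0 or self.count_depth < 0:
            raise ValueError("depths must be non-negative")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class PlantedEvent:
    """One planted alternative-splicing event, in genomic coordinates."""

    gene_id: str
    event_type: str
    ref_introns: tuple[Interval, ...]
    alt_interval: Interval
    stage_group: str | None  # None = constitutive across stages
    ptc: bool
    retention_fraction: float = 0.0  # IR only: minor-isoform share of reads

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.event_type, self.ref_introns, self.alt_interval)


@dataclass
class TruthGene:
    model: GeneModel  # major-isoform model (the correct annotation)
    utr5: Interval
    utr3: Interval
    base_expr: float = 1.0
    up_stage: str | None = None

    @property
    def footprint(self) -> Interval:
        lo = min(self.model.span[0], self.utr5[0], self.utr3[0])
        hi = max(self.model.span[1], self.utr5[1], self.utr3[1])
        return (lo, hi)


@dataclass
class TruthNovel:
    id: str
    scaffold: str
    start: int
    end: int
    coding: bool
    expr: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthTable:
    """Everything the acceptance tests need to score the pipeline."""

    scaffold_lengths: dict[str, int]
    genes: dict[str, TruthGene]
    events: list[PlantedEvent]
    annotation: Annotation  # the (defective) input annotation
    truth_annotation: Annotation  # the correct models
    expression: pd.DataFrame  # gene x sample expression units
    stage_up: dict[str, list[str]]  # stage group -> gene ids
    novels: list[TruthNovel]
    merged_defects: dict[str, tuple[str, str]]  # model id -> merged gene ids
    split_defects: dict[str, tuple[str, str]]  # gene id -> its two model ids
    boundary_defects: list[str]
    intron_defects: list[str]
    #: input-annotation model id -> [(truth gene id, exonic bp contributed)];
    #: read counts are emitted per annotation model, as a real counter would.
    model_sources: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def event_keys(self) -> set[tuple]:
        return {e.key for e in self.events}

    def stage_specific_event_keys(self) -> set[tuple]:
        return {e.key for e in self.events if e.stage_group is not None}

    def expected_novel_ids(self, min_len: int = 300) -> set[str]:
        return {n.id for n in self.novels if n.length >= min_len}


# ------------------------------------------------------------------ RNG


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _random_dna(rng, n: int, at_fraction: float) -> np.ndarray:
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return rng.choice(
        np.frombuffer(b"ATGC", dtype="S1"), size=n, p=[p_at, p_at, p_gc, p_gc]
    )


def _random_seq(rng, n: int, at_fraction: float) -> str:
    return _random_dna(rng, n, at_fraction).tobytes().decode()


def _random_codons(rng, n_codons: int, at_fraction: float) -> str:
    """Random coding sequence with no in-frame TGA (TGA is the only stop)."""
    out = []
    while len(out) < n_codons:
        chunk = _random_seq(rng, 3 * (n_codons - len(out)), at_fraction)
        for i in range(0, len(chunk), 3):
            codon = chunk[i : i + 3]
            if codon != "TGA":
                out.append(codon)
                if len(out) == n_codons:
                    break
    return "".join(out)


def _intron_length(rng, config: SimConfig) -> int:
    L = config.intron_min + int(
        round(rng.exponential(config.intron_mean - config.intron_min))
    )
    return min(L, config.intron_max)


# -------------------------------------------------------- gene building


@dataclass
class _GeneDraft:
    """A gene in transcript orientation, before genomic placement."""

    gid: str
    exon_lens: list[int]
    intron_lens: list[int]
    utr5_len: int
    utr3_len: int
    seq: str = ""  # utr5 + exon/intron chain + utr3, transcript orientation
    strand: str = "+"
    events: list[dict] = field(default_factory=list)

    @property
    def region_len(self) -> int:
        return (
            self.utr5_len
            + sum(self.exon_lens)
            + sum(self.intron_lens)
            + self.utr3_len
        )

    def tx_exons(self) -> list[Interval]:
        """Exon intervals in transcript-oriented region coordinates."""
        out = []
        pos = self.utr5_len
        for i, el in enumerate(self.exon_lens):
            out.append((pos, pos + el))
            pos += el
            if i < len(self.intron_lens):
                pos += self.intron_lens[i]
        return out

    def tx_introns(self) -> list[Interval]:
        ex = self.tx_exons()
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


def _build_gene_draft(rng, config: SimConfig, gid: str) -> _GeneDraft:
    k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    exon_lens = [
        int(rng.integers(config.exon_len_range[0], config.exon_len_range[1] + 1))
        for _ in range(k)
    ]
    total = sum(exon_lens)
    exon_lens[-1] += (3 - total % 3) % 3
    intron_lens = [_intron_length(rng, config) for _ in range(k - 1)]
    g = _GeneDraft(
        gid=gid,
        exon_lens=exon_lens,
        intron_lens=intron_lens,
        utr5_len=int(rng.integers(*config.utr5_range)),
        utr3_len=int(rng.integers(*config.utr3_range)),
        strand="+" if rng.random() < 0.5 else "-",
    )
    return g


def _plant_as(rng, config: SimConfig, g: _GeneDraft) -> None:
    """Decide the gene's planted AS events (transcript-oriented indices)."""
    n_introns = len(g.intron_lens)
    used: set[int] = set()
    group_names = list(STAGE_GROUPS)
    for etype in AS_TYPES:
        if rng.random() >= config.as_rates.get(etype, 0.0):
            continue
        stage_group = None
        if rng.random() < config.as_stage_specific_fraction:
            stage_group = group_names[
                int(rng.choice(3, p=[0.2, 0.2, 0.6]))
            ]
        if etype == "cassette":
            candidates = [
                e
                for e in range(1, len(g.exon_lens) - 1)
                if (e - 1) not in used and e not in used
            ]
            if not candidates:
                continue
            e = int(rng.choice(candidates))
            used.update((e - 1, e))
            g.events.append(
                {"type": "cassette", "exon": e, "group": stage_group}
            )
        elif etype in ("alt5", "alt3"):
            candidates = [
                i
                for i in range(n_introns)
                if i not in used and g.intron_lens[i] >= 40
            ]
            if not candidates:
                continue
            i = int(rng.choice(candidates))
            used.add(i)
            d = int(rng.integers(6, min(30, g.intron_lens[i] - 10) + 1))
            g.events.append(
                {"type": etype, "intron": i, "d": d, "group": stage_group}
            )
        else:  # IR
            candidates = [i for i in range(n_introns) if i not in used]
            if not candidates:
                continue
            i = int(rng.choice(candidates))
            used.add(i)
            secondary = None
            if (
                config.ir_secondary_retention > 0
                and rng.random() < config.ir_secondary_retention
            ):
                rest = [x for x in range(n_introns) if x not in used]
                if rest:
                    secondary = int(rng.choice(rest))
                    used.add(secondary)
            g.events.append(
                {
                    "type": "IR",
                    "intron": i,
                    "secondary": secondary,
                    "group": stage_group,
                }
            )


def _build_gene_sequence(rng, config: SimConfig, g: _GeneDraft) -> None:
    n_codons = sum(g.exon_lens) // 3
    cds = "ATG" + _random_codons(rng, n_codons - 2, config.at_fraction_coding) + "TGA"
    exon_seqs = []
    pos = 0
    for el in g.exon_lens:
        exon_seqs.append(cds[pos : pos + el])
        pos += el
    intron_seqs = []
    for L in g.intron_lens:
        s = list(_random_seq(rng, L, config.at_fraction_noncoding))
        s[0:2] = "GT"
        s[-2:] = "AG"
        intron_seqs.append(s)
    # plant alternative splice sites inside introns
    for ev in g.events:
        if ev["type"] == "alt5":
            s = intron_seqs[ev["intron"]]
            s[ev["d"] : ev["d"] + 2] = "GT"
        elif ev["type"] == "alt3":
            s = intron_seqs[ev["intron"]]
            L = len(s)
            s[L - ev["d"] - 2 : L - ev["d"]] = "AG"
    intron_strs = ["".join(s) for s in intron_seqs]

    parts = [_random_seq(rng, g.utr5_len, config.at_fraction_noncoding)]
    for i, es in enumerate(exon_seqs):
        parts.append(es)
        if i < len(intron_strs):
            parts.append(intron_strs[i])
    parts.append(_random_seq(rng, g.utr3_len, config.at_fraction_noncoding))
    g.seq = "".join(parts)

    # truth PTC flags: translate each minor-isoform mRNA (ciliate code)
    for ev in g.events:
        minor = _minor_mrna(exon_seqs, intron_strs, ev)
        p = first_inframe_stop(minor, 0)
        ev["ptc"] = bool(p is not None and p < len(minor) - 3)


def _minor_mrna(exon_seqs, intron_strs, ev) -> str:
    if ev["type"] == "IR":
        parts = []
        for i, es in enumerate(exon_seqs):
            parts.append(es)
            if i == ev["intron"]:
                parts.append(intron_strs[i])
            if ev.get("secondary") is not None and i == ev["secondary"]:
                parts.append(intron_strs[i])
        return "".join(parts)
    if ev["type"] == "cassette":
        return "".join(
            es for i, es in enumerate(exon_seqs) if i != ev["exon"]
        )
    if ev["type"] == "alt5":
        parts = []
        for i, es in enumerate(exon_seqs):
            parts.append(es)
            if i == ev["intron"]:
                parts.append(intron_strs[i][: ev["d"]])
        return "".join(parts)
    # alt3
    parts = []
    for i, es in enumerate(exon_seqs):
        if i - 1 == ev["intron"]:
            parts.append(intron_strs[i - 1][-ev["d"] :])
        parts.append(es)
    return "".join(parts)


# ---------------------------------------------------------- truth build


def generate_truth(config: SimConfig):
    """Generate the genome, the (defective) input annotation and the truth
    table.  Returns ``(genome, annotation, truth)``."""
    config.validate()
    rng = _rng(config, 0)

    drafts = [
        _build_gene_draft(rng, config, f"TTHERM_SIM{i + 1:05d}")
        for i in range(config.n_genes)
    ]
    for g in drafts:
        _plant_as(rng, config, g)
        _build_gene_sequence(rng, config, g)

    # novel transcribed regions (planted intergenic transcripts)
    novel_specs = []
    for i in range(config.novel_count + config.short_novel_count):
        if i < config.novel_count:
            L = config.novel_len_min + int(
                round(rng.exponential(config.novel_len_mean - config.novel_len_min))
            )
        else:
            L = int(rng.integers(60, config.novel_len_min - 50))
        coding = i < config.novel_count and rng.random() < config.novel_coding_fraction
        if coding and L >= 240:
            n_cod = int(rng.integers(60, max(61, (L - 40) // 3)))
            orf = "ATG" + _random_codons(rng, n_cod - 2, config.at_fraction_coding) + "TGA"
            pad = L - len(orf)
            left = int(rng.integers(0, pad + 1))
            seq = (
                _random_seq(rng, left, config.at_fraction_noncoding)
                + orf
                + _random_seq(rng, pad - left, config.at_fraction_noncoding)
            )
        else:
            coding = False
            seq = _random_seq(rng, L, config.at_fraction_noncoding)
        # the truth label reflects the emitted sequence: A+T-rich random
        # sequence occasionally carries a long chance ORF
        coding = longest_orf_either_strand(seq, 50) is not None
        expr = float(rng.uniform(*config.novel_expr_range))
        novel_specs.append({"id": f"NOVEL_SIM{i + 1:04d}", "seq": seq, "coding": coding, "expr": expr})

    # placement: interleave genes and novel regions across scaffolds
    items = [("gene", g) for g in drafts] + [("novel", n) for n in novel_specs]
    order = rng.permutation(len(items))
    scaffolds = [f"scf_{i + 1}" for i in range(config.n_scaffolds)]
    placements = []  # (kind, obj, scaffold, offset)
    si, cursor = 0, 0
    for idx in order:
        kind, obj = items[idx]
        length = obj.region_len if kind == "gene" else len(obj["seq"])
        gap = config.intergenic_min + int(rng.integers(0, 401))
        while True:
            if si >= len(scaffolds):
                raise SimSizeError(
                    f"{config.n_genes} genes + {len(novel_specs)} novel regions "
                    f"do not fit on {config.n_scaffolds} x {config.scaffold_length} bp"
                )
            start = cursor + gap
            if start + length + config.intergenic_min <= config.scaffold_length:
                placements.append((kind, obj, scaffolds[si], start))
                cursor = start + length
                break
            si += 1
            cursor = 0

    # genome sequences: A+T-rich background, gene/novel regions written in
    genome: dict[str, str] = {}
    arrays = {
        name: _random_dna(_rng(config, 10 + i), config.scaffold_length,
                          config.at_fraction_noncoding)
        for i, name in enumerate(scaffolds)
    }
    truth_genes: dict[str, TruthGene] = {}
    novels: list[TruthNovel] = []
    events: list[PlantedEvent] = []

    for kind, obj, scaffold, start in placements:
        if kind == "novel":
            seq = obj["seq"]
            arrays[scaffold][start : start + len(seq)] = np.frombuffer(
                seq.encode(), dtype="S1"
            )
            novels.append(
                TruthNovel(
                    id=obj["id"], scaffold=scaffold, start=start,
                    end=start + len(seq), coding=obj["coding"], expr=obj["expr"],
                )
            )
            continue
        g: _GeneDraft = obj
        L = g.region_len
        region = g.seq if g.strand == "+" else revcomp(g.seq)
        arrays[scaffold][start : start + L] = np.frombuffer(region.encode(), dtype="S1")

        def to_genomic(iv: Interval) -> Interval:
            a, b = iv
            if g.strand == "+":
                return (start + a, start + b)
            return (start + L - b, start + L - a)

        exons = sorted(to_genomic(iv) for iv in g.tx_exons())
        span = (exons[0][0], exons[-1][1])
        model = GeneModel(
            id=g.gid, scaffold=scaffold, strand=g.strand, exons=exons, cds=span
        )
        utr5 = to_genomic((0, g.utr5_len))
        utr3 = to_genomic((L - g.utr3_len, L))
        truth_genes[g.gid] = TruthGene(model=model, utr5=utr5, utr3=utr3)

        tx_introns = g.tx_introns()
        for ev in g.events:
            if ev["type"] == "cassette":
                e = ev["exon"]
                j1 = to_genomic(tx_introns[e - 1])
                j2 = to_genomic(tx_introns[e])
                ref = tuple(sorted((j1, j2)))
                alt = (min(j1[0], j2[0]), max(j1[1], j2[1]))
            elif ev["type"] in ("alt5", "alt3"):
                i, d = ev["intron"], ev["d"]
                a, b = tx_introns[i]
                minor_tx = (a + d, b) if ev["type"] == "alt5" else (a, b - d)
                ref = (to_genomic(tx_introns[i]),)
                alt = to_genomic(minor_tx)
            else:  # IR
                i = ev["intron"]
                ref = (to_genomic(tx_introns[i]),)
                alt = ref[0]
            events.append(
                PlantedEvent(
                    gene_id=g.gid,
                    event_type=ev["type"],
                    ref_introns=ref,
                    alt_interval=alt,
                    stage_group=ev["group"],
                    ptc=ev["ptc"],
                    retention_fraction=(
                        config.minor_isoform_fraction * config.ir_dominant_share
                        if ev["type"] == "IR"
                        else 0.0
                    ),
                )
            )
            if ev["type"] == "IR" and ev.get("secondary") is not None:
                iv = to_genomic(tx_introns[ev["secondary"]])
                events.append(
                    PlantedEvent(
                        gene_id=g.gid,
                        event_type="IR",
                        ref_introns=(iv,),
                        alt_interval=iv,
                        stage_group=ev["group"],
                        ptc=ev["ptc"],
                        retention_fraction=config.minor_isoform_fraction
                        * (1.0 - config.ir_dominant_share),
                    )
                )

    genome = {
        name: arr.tobytes().decode() for name, arr in sorted(arrays.items())
    }
    scaffold_lengths = {name: config.scaffold_length for name in scaffolds}

    # ---- expression -------------------------------------------------
    gene_ids = sorted(truth_genes)
    as_genes = {e.gene_id for e in events}
    base = 10.0 ** rng.uniform(*config.expr_log10_range, size=len(gene_ids))
    base_expr = dict(zip(gene_ids, base))
    for gid in as_genes:
        base_expr[gid] = max(base_expr[gid], config.as_min_expr)

    # stage-specific up-regulation, planted in non-AS genes
    n_up = int(round(config.stage_up_fraction * len(gene_ids)))
    candidates = [gid for gid in gene_ids if gid not in as_genes]
    up_ids = list(rng.choice(candidates, size=min(n_up, len(candidates)), replace=False))
    stage_up: dict[str, list[str]] = {g: [] for g in STAGE_GROUPS}
    group_names = list(STAGE_GROUPS)
    for i, gid in enumerate(sorted(up_ids)):
        stage = group_names[i % len(group_names)]
        stage_up[stage].append(gid)
        base_expr[gid] = max(base_expr[gid], config.stage_up_min_expr)
        truth_genes[gid].up_stage = stage

    # ---- defective input annotation ---------------------------------
    annotation, merged, split, boundary, introndef, sources = _defective_annotation(
        rng, config, truth_genes, as_genes, set(sum(stage_up.values(), []))
    )
    defect_gids = set(boundary) | set(introndef) | set(split)
    for _, (ga, gb) in merged.items():
        defect_gids.update((ga, gb))
    for gid in defect_gids:
        base_expr[gid] = max(base_expr[gid], config.defect_min_expr)

    expr = pd.DataFrame(index=gene_ids, columns=list(config.samples), dtype=float)
    for s in config.samples:
        col = np.array([base_expr[gid] for gid in gene_ids])
        col = col * float(config.stage_profiles.get(s, 1.0))
        for stage, members in STAGE_GROUPS.items():
            if s in members:
                up = np.array(
                    [truth_genes[g].up_stage == stage for g in gene_ids]
                )
                col = np.where(up, col * config.stage_up_fold, col)
        expr[s] = col
    for gid, tg in truth_genes.items():
        tg.base_expr = base_expr[gid]

    truth_ann = Annotation(
        models={gid: tg.model for gid, tg in truth_genes.items()},
        scaffold_lengths=scaffold_lengths,
        provenance="truth",
    )
    truth = TruthTable(
        scaffold_lengths=scaffold_lengths,
        genes=truth_genes,
        events=events,
        annotation=annotation,
        truth_annotation=truth_ann,
        expression=expr,
        stage_up=stage_up,
        novels=novels,
        merged_defects=merged,
        split_defects=split,
        boundary_defects=boundary,
        intron_defects=introndef,
        model_sources=sources,
    )
    return genome, annotation, truth


def _defective_annotation(rng, config, truth_genes, as_genes, up_genes):
    """Build the '2008-release-like' annotation with planted mispredictions."""
    protected = set(as_genes) | set(up_genes)
    clean = [gid for gid in sorted(truth_genes) if gid not in protected]
    rng.shuffle(clean)
    n = len(truth_genes)
    take = lambda k: [clean.pop() for _ in range(min(k, len(clean)))]

    boundary = take(int(round(config.boundary_defect_fraction * n)))
    introndef = take(int(round(config.intron_defect_fraction * n)))
    split_ids = take(int(round(config.split_annotation_fraction * n)))
    n_merge = int(round(config.merged_annotation_fraction * n))

    # merged defects need adjacent same-strand clean pairs
    by_scaffold: dict[str, list] = {}
    for gid, tg in truth_genes.items():
        by_scaffold.setdefault(tg.model.scaffold, []).append((tg.model.span[0], gid))
    merged_pairs = []
    available = set(clean)
    for scaffold in sorted(by_scaffold):
        entries = sorted(by_scaffold[scaffold])
        for (s1, g1), (s2, g2) in zip(entries[:-1], entries[1:]):
            if len(merged_pairs) >= n_merge:
                break
            if g1 in available and g2 in available:
                if truth_genes[g1].model.strand == truth_genes[g2].model.strand:
                    merged_pairs.append((g1, g2))
                    available.discard(g1)
                    available.discard(g2)

    models: dict[str, GeneModel] = {}
    merged: dict[str, tuple[str, str]] = {}
    split: dict[str, tuple[str, str]] = {}
    sources: dict[str, list[tuple[str, int]]] = {}
    in_pair = {g for pair in merged_pairs for g in pair}

    for gid in sorted(truth_genes):
        tg = truth_genes[gid]
        m = tg.model
        if gid in in_pair:
            continue
        if gid in boundary and m.introns:
            exons = [list(e) for e in m.exons]
            i = int(rng.integers(0, len(m.introns)))
            exons[i][1] += 4  # donor pushed 4 bp into the intron
            models[gid] = GeneModel(gid, m.scaffold, m.strand,
                                    [tuple(e) for e in exons],
                                    (exons[0][0], exons[-1][1]))
        elif gid in introndef:
            exons = [tuple(e) for e in m.exons]
            if m.introns and rng.random() < 0.5:
                i = int(rng.integers(0, len(m.introns)))
                exons = exons[:i] + [(exons[i][0], exons[i + 1][1])] + exons[i + 2:]
            else:
                widths = [e - s for s, e in exons]
                big = [k for k, w in enumerate(widths) if w >= 120]
                if big:
                    k = int(rng.choice(big))
                    s, e = exons[k]
                    mid = (s + e) // 2
                    exons = exons[:k] + [(s, mid - 20), (mid + 20, e)] + exons[k + 1:]
            models[gid] = GeneModel(gid, m.scaffold, m.strand, list(exons),
                                    (exons[0][0], exons[-1][1]))
        elif gid in split_ids and len(m.exons) >= 2:
            cut = int(rng.integers(1, len(m.exons)))
            a_ex, b_ex = list(m.exons[:cut]), list(m.exons[cut:])
            ida, idb = f"{gid}a", f"{gid}b"
            models[ida] = GeneModel(ida, m.scaffold, m.strand, a_ex,
                                    (a_ex[0][0], a_ex[-1][1]))
            models[idb] = GeneModel(idb, m.scaffold, m.strand, b_ex,
                                    (b_ex[0][0], b_ex[-1][1]))
            split[gid] = (ida, idb)
            sources[ida] = [(gid, models[ida].exon_length)]
            sources[idb] = [(gid, models[idb].exon_length)]
        else:
            models[gid] = GeneModel(gid, m.scaffold, m.strand, list(m.exons), m.cds)

    for g1, g2 in merged_pairs:
        m1, m2 = truth_genes[g1].model, truth_genes[g2].model
        exons = sorted(list(m1.exons) + list(m2.exons))
        models[g1] = GeneModel(g1, m1.scaffold, m1.strand, exons,
                               (exons[0][0], exons[-1][1]))
        merged[g1] = (g1, g2)
        sources[g1] = [(g1, m1.exon_length), (g2, m2.exon_length)]

    for mid, m in models.items():
        sources.setdefault(mid, [(mid, m.exon_length)])

    ann = Annotation(
        models=models,
        scaffold_lengths={
            f"scf_{i + 1}": config.scaffold_length
            for i in range(config.n_scaffolds)
        },
        provenance="2008-like",
    )
    # only genes whose model actually differs from truth count as defects
    boundary = [
        g for g in boundary
        if g in models and models[g].exons != truth_genes[g].model.exons
    ]
    introndef = [
        g for g in introndef
        if g in models and models[g].exons != truth_genes[g].model.exons
    ]
    return ann, merged, split, boundary, introndef, sources


# ------------------------------------------------------- observables


def _active(ev: PlantedEvent, sample: str) -> bool:
    if ev.stage_group is None:
        return True
    return sample in STAGE_GROUPS[ev.stage_group]


def simulate_observables(truth: TruthTable, config: SimConfig):
    """Emit per-sample junction records, coverage tracks and read counts.

    Junction support is Poisson around isoform expression x depth; coverage
    is deterministic (round of expression x depth) so that planted
    retention depths are exactly reproducible; counts are Poisson around
    expression x exon kb x count depth.  Returns
    ``(junctions, coverage tracks by sample, counts, totals)``.
    """
    rng = _rng(config, 1)
    samples = list(config.samples)
    covs = {s: CoverageTrack(truth.scaffold_lengths) for s in samples}
    jmap: dict[tuple, Junction] = {}
    minor = config.minor_isoform_fraction

    def junction(scaffold, iv, strand) -> Junction:
        key = (scaffold, iv[0], iv[1], strand)
        if key not in jmap:
            jmap[key] = Junction(
                scaffold=scaffold, start=iv[0], end=iv[1], strand=strand,
                support={s: 0 for s in samples},
                min_anchor=int(rng.integers(*config.anchor_range)),
            )
        return jmap[key]

    events_by_gene: dict[str, list[PlantedEvent]] = {}
    for e in truth.events:
        events_by_gene.setdefault(e.gene_id, []).append(e)

    for gid in sorted(truth.genes):
        tg = truth.genes[gid]
        m = tg.model
        evs = events_by_gene.get(gid, [])
        x = truth.expression.loc[gid]

        # per-intron spliced fraction and retention fraction per sample
        introns = [tuple(iv) for iv in m.introns]
        for iv in introns:
            jn = junction(m.scaffold, iv, m.strand)
            for s in samples:
                frac = 1.0
                for e in evs:
                    if not _active(e, s):
                        continue
                    if e.event_type == "IR" and e.ref_introns[0] == iv:
                        frac -= e.retention_fraction
                    elif e.event_type in ("alt5", "alt3") and e.ref_introns[0] == iv:
                        frac -= minor
                    elif e.event_type == "cassette" and iv in e.ref_introns:
                        frac -= minor
                mean = config.junction_read_factor * config.depth * x[s] * max(frac, 0.0)
                jn.support[s] += int(rng.poisson(mean))
        for e in evs:
            if e.event_type == "IR":
                continue
            jn = junction(m.scaffold, e.alt_interval, m.strand)
            for s in samples:
                if _active(e, s):
                    mean = config.junction_read_factor * config.depth * x[s] * minor
                    jn.support[s] += int(rng.poisson(mean))

        # coverage: UTRs + exons at full depth, event regions adjusted
        lo5, hi5 = tg.utr5
        lo3, hi3 = tg.utr3
        for s in samples:
            arr = covs[s].depth[m.scaffold]
            d = int(round(config.depth * x[s]))
            if d <= 0:
                continue
            arr[lo5:hi5] = np.maximum(arr[lo5:hi5], d)
            arr[lo3:hi3] = np.maximum(arr[lo3:hi3], d)
            for a, b in m.exons:
                arr[a:b] = np.maximum(arr[a:b], d)
            for e in evs:
                if not _active(e, s):
                    continue
                if e.event_type == "IR":
                    iv = e.ref_introns[0]
                    dr = int(round(config.depth * x[s] * e.retention_fraction))
                    arr[iv[0]:iv[1]] = np.maximum(arr[iv[0]:iv[1]], dr)
                elif e.event_type in ("alt5", "alt3"):
                    ref, alt = e.ref_introns[0], e.alt_interval
                    ext = (ref[0], alt[0]) if alt[0] > ref[0] else (alt[1], ref[1])
                    dm = int(round(config.depth * x[s] * minor))
                    arr[ext[0]:ext[1]] = np.maximum(arr[ext[0]:ext[1]], dm)
                elif e.event_type == "cassette":
                    j1, j2 = e.ref_introns
                    exon = (j1[1], j2[0])
                    di = int(round(config.depth * x[s] * (1.0 - minor)))
                    arr[exon[0]:exon[1]] = di

    for nv in truth.novels:
        for s in samples:
            d = int(round(config.depth * nv.expr))
            if d > 0:
                arr = covs[s].depth[nv.scaffold]
                arr[nv.start:nv.end] = np.maximum(arr[nv.start:nv.end], d)

    # read counts per input-annotation model (as a real counter would emit);
    # merged models accumulate both source genes, split halves pro-rate by
    # their exonic length
    model_ids = sorted(truth.model_sources)
    counts = pd.DataFrame(0, index=model_ids, columns=samples, dtype=int)
    for mid in model_ids:
        for s in samples:
            mean = sum(
                truth.expression.loc[gid, s] * length / 1000.0 * config.count_depth
                for gid, length in truth.model_sources[mid]
            )
            counts.loc[mid, s] = int(rng.poisson(mean))
    totals = counts.sum(axis=0)

    junctions = [jmap[k] for k in sorted(jmap)]
    junctions = [j for j in junctions if j.total_support > 0]
    for i, j in enumerate(junctions):
        j.id = f"JUNC{i + 1:06d}"
    return junctions, covs, counts, totals


def simulate_microarray(truth: TruthTable, config: SimConfig):
    """Place probes within exons of the truth models and emit per-stage
    intensities = log2 true expression + Gaussian noise.

    Returns ``(probe table, probe -> truth gene map)``.
    """
    if config.probe_count_per_gene < 1:
        raise ValueError("probe_count_per_gene must be >= 1")
    rng = _rng(config, 2)
    samples = list(config.samples)
    rows = []
    probe_map = {}
    for gid in sorted(truth.genes):
        m = truth.genes[gid].model
        fitting = [e for e in m.exons if e[1] - e[0] >= config.probe_length]
        if not fitting:
            raise ValueError(
                f"{gid}: probe length {config.probe_length} exceeds every exon"
            )
        x = truth.expression.loc[gid]
        for k in range(config.probe_count_per_gene):
            s, e = fitting[int(rng.integers(0, len(fitting)))]
            pos = int(rng.integers(s, e - config.probe_length + 1))
            pid = f"{gid}_p{k + 1}"
            noise = rng.normal(0.0, config.probe_noise_sd, size=len(samples))
            row = {
                "probe_id": pid,
                "scaffold": m.scaffold,
                "start": pos,
                "end": pos + config.probe_length,
            }
            for si, smp in enumerate(samples):
                row[smp] = float(np.log2(x[smp]) + (noise[si] if config.probe_noise_sd > 0 else 0.0))
            rows.append(row)
            probe_map[pid] = gid
    probes = pd.DataFrame(rows, columns=["probe_id", "scaffold", "start", "end", *samples])
    return probes, probe_map


def simulate_go(truth: TruthTable, config: SimConfig) -> dict[str, set[str]]:
    """Random GO-term assignment, with a marker term enriched in each
    planted stage-up set so enrichment has signal to find."""
    rng = _rng(config, 3)
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    lo, hi = config.go_terms_per_gene
    out: dict[str, set[str]] = {}
    for gid in sorted(truth.genes):
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        out[gid] = {terms[i] for i in chosen}
    for stage, gids in truth.stage_up.items():
        marker = f"GO:ENR_{stage.upper()}"
        for gid in gids:
            if rng.random() < 0.8:
                out[gid].add(marker)
    return out


@dataclass
class SimDataset:
    """A complete simulated study: inputs plus truth."""

    config: SimConfig
    genome: dict[str, str]
    annotation: Annotation
    truth: TruthTable
    junctions: list[Junction]
    coverage: dict[str, CoverageTrack]
    counts: pd.DataFrame
    totals: pd.Series
    probes: pd.DataFrame
    probe_map: dict[str, str]
    go_map: dict[str, set[str]]


def simulate_dataset(config: SimConfig) -> SimDataset:
    genome, annotation, truth = generate_truth(config)
    junctions, covs, counts, totals = simulate_observables(truth, config)
    probes, probe_map = simulate_microarray(truth, config)
    go_map = simulate_go(truth, config)
    return SimDataset(
        config=config, genome=genome, annotation=annotation, truth=truth,
        junctions=junctions, coverage=covs, counts=counts, totals=totals,
        probes=probes, probe_map=probe_map, go_map=go_map,
    )


def write_dataset(ds: SimDataset, outdir) -> dict[str, Path]:
    """Write every input file (and the truth tables) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "junctions_bed": outdir / "junctions.bed",
        "junction_support": outdir / "junction_support.tsv",
        "counts": outdir / "counts.tsv",
        "totals": outdir / "totals.tsv",
        "probes": outdir / "probes.tsv",
        "go": outdir / "go_terms.tsv",
        "config": outdir / "sim_config.json",
    }
    sio.write_genome(ds.genome, paths["genome"])
    sio.write_annotation(ds.annotation, paths["annotation"])
    sio.write_junctions(
        ds.junctions, paths["junctions_bed"], paths["junction_support"],
        list(ds.config.samples),
    )
    for s in ds.config.samples:
        p = outdir / f"coverage_{s}.bedGraph"
        sio.write_bedgraph(ds.coverage[s], p)
        paths[f"coverage_{s}"] = p
    sio.write_counts(ds.counts, ds.totals, paths["counts"], paths["totals"])
    sio.write_probes(ds.probes, paths["probes"])
    go_rows = [
        {"gene_id": g, "terms": ",".join(sorted(ts))}
        for g, ts in sorted(ds.go_map.items())
    ]
    pd.DataFrame(go_rows, columns=["gene_id", "terms"]).to_csv(
        paths["go"], sep="\t", index=False
    )
    cfg = dataclasses.asdict(ds.config)
    cfg["samples"] = list(cfg["samples"])
    paths["config"].write_text(json.dumps(cfg, indent=1, sort_keys=True) + "\n")

    # truth tables
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    sio.write_annotation(ds.truth.truth_annotation, truth_dir / "truth_annotation.gff3")
    ev_rows = [
        {
            "gene_id": e.gene_id,
            "event_type": e.event_type,
            "ref_introns": ";".join(f"{a}-{b}" for a, b in e.ref_introns),
            "alt_interval": f"{e.alt_interval[0]}-{e.alt_interval[1]}",
            "stage_group": e.stage_group or "all",
            "ptc": int(e.ptc),
        }
        for e in ds.truth.events
    ]
    pd.DataFrame(
        ev_rows,
        columns=["gene_id", "event_type", "ref_introns", "alt_interval", "stage_group", "ptc"],
    ).to_csv(truth_dir / "events.tsv", sep="\t", index=False)
    ds.truth.expression.sort_index().to_csv(
        truth_dir / "expression.tsv", sep="\t", index_label="gene_id"
    )
    pd.DataFrame(
        [{"probe_id": p, "gene_id": g} for p, g in sorted(ds.probe_map.items())],
        columns=["probe_id", "gene_id"],
    ).to_csv(truth_dir / "probe_map.tsv", sep="\t", index=False)
    nov_rows = [
        {
            "id": n.id, "scaffold": n.scaffold, "start": n.start, "end": n.end,
            "length": n.length, "coding": int(n.coding), "expr": n.expr,
        }
        for n in sorted(ds.truth.novels, key=lambda n: (n.scaffold, n.start))
    ]
    pd.DataFrame(
        nov_rows,
        columns=["id", "scaffold", "start", "end", "length", "coding", "expr"],
    ).to_csv(truth_dir / "novel_regions.tsv", sep="\t", index=False)
    return paths
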