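"""End-to-end orchestration: filter -> assemble -> compare -> novel/UTR ->
AS -> expression -> enrichment, plus the summary report.

`run_analysis` works on in-memory objects (what the tests and the
acceptance script use); `run_pipeline` wraps it with file I/O driven by a
:class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as xp
from . import io as sio
from . import refine, splicing
from .junctions import validate_and_filter
from .models import (
    Annotation,
    CoverageTrack,
    IR_GROUPS,
    SAMPLES,
    STAGE_GROUPS,
)

log = logging.getLogger(__name__)


# --------------------------------------------------- headline arithmetic


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage at the report's printed precision (1 decimal place)."""
    return round(100.0 * numerator / denominator, digits)


def introns_per_gene(n_introns: int, n_genes: int, digits: int = 2) -> float:
    return round(n_introns / n_genes, digits)


def total_as_events(per_type_counts) -> int:
    return int(sum(per_type_counts))


# ------------------------------------------------------------- config


@dataclass
class Thresholds:
    min_anchor: int = 8
    min_support: int = 1
    min_intron: int = 10
    max_intron: int = 10000
    min_cov: int = 2
    max_gap: int = 25
    zero_gap: int = 50
    novel_min_len: int = 300
    min_orf_codons: int = 50
    ir_min_depth: int = 10
    min_spliced: int = 2
    min_rpkm: float = 5.0
    min_fold: float = 5.0
    go_alpha: float = 0.01


@dataclass
class RunConfig:
    genome: str
    annotation: str
    junctions_bed: str
    junction_support: str
    coverage: dict[str, str]  # sample -> bedGraph path
    counts: str
    totals: str
    outdir: str
    probes: str | None = None
    go_terms: str | None = None
    samples: tuple[str, ...] = SAMPLES
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        th = Thresholds(**raw.pop("thresholds", {}))
        samples = tuple(raw.pop("samples", SAMPLES))
        cfg = cls(samples=samples, thresholds=th, **raw)
        return cfg

    def validate(self) -> None:
        for p in [self.genome, self.annotation, self.junctions_bed,
                  self.junction_support, self.counts, self.totals,
                  *self.coverage.values()]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class PipelineResult:
    junctions: list
    transcripts: list
    statuses: dict
    corrected: Annotation
    novel: list
    events: list
    stage_specific_events: list
    ir_table: pd.DataFrame
    rpkm: pd.DataFrame
    stage_vals: pd.DataFrame
    stage_up: dict[str, list[str]]
    renormalized: pd.DataFrame | None
    probe_assign: pd.DataFrame | None
    correlations: dict[str, float]
    enrichment: dict[str, list]
    report: dict


# ------------------------------------------------------------ IR table

_BIN_LABELS = [str(i) for i in range(2, 9)] + [">8"]


def _intron_bin(n: int) -> str:
    return str(n) if n <= 8 else ">8"


def summarize_ir_table(
    events,
    corrected: Annotation,
    statuses,
    covs: dict[str, CoverageTrack],
    groups: dict[str, tuple[str, ...]] = IR_GROUPS,
) -> pd.DataFrame:
    """Distribution and specificity of IR among confirmed multi-intron genes.

    Rows are binned by intron count (2..8, >8); per row: gene count, IR gene
    count, IR genes by number of retained introns (all / one / several), and
    the mean most-retained-intron frequency per stage group.  The total row
    carries gene-count-weighted average frequencies.
    """
    ir_by_gene: dict[str, set] = {}
    for e in events:
        if e.event_type == "IR":
            ir_by_gene.setdefault(e.gene_id, set()).add(e.alt_interval)

    rows = {
        label: {
            "introns": label, "genes": 0, "ir_genes": 0,
            "all_retained": 0, "one_retained": 0, "multi_retained": 0,
            **{f"freq_{g}": [] for g in groups},
        }
        for label in _BIN_LABELS
    }
    for m in corrected.sorted_models():
        st = statuses.get(m.id)
        if st is None or st.status != "complete_match":
            continue
        n = len(m.introns)
        if n < 2:
            continue
        row = rows[_intron_bin(n)]
        row["genes"] += 1
        retained = ir_by_gene.get(m.id, set())
        r = len(retained)
        if r == 0:
            continue
        row["ir_genes"] += 1
        if r == n:
            row["all_retained"] += 1
        elif r == 1:
            row["one_retained"] += 1
        else:
            row["multi_retained"] += 1
        summary = splicing.ir_gene_summary(m, covs, groups)
        for g in groups:
            f = summary.most_retained_frequency(g)
            if f is not None:
                row[f"freq_{g}"].append(f)

    out_rows = []
    for label in _BIN_LABELS:
        row = rows[label]
        rec = {k: v for k, v in row.items() if not k.startswith("freq_")}
        for g in groups:
            vals = row[f"freq_{g}"]
            rec[f"freq_{g}"] = round(float(np.mean(vals)), 2) if vals else np.nan
        out_rows.append(rec)
    total = {
        "introns": "total",
        "genes": sum(r["genes"] for r in out_rows),
        "ir_genes": sum(r["ir_genes"] for r in out_rows),
        "all_retained": sum(r["all_retained"] for r in out_rows),
        "one_retained": sum(r["one_retained"] for r in out_rows),
        "multi_retained": sum(r["multi_retained"] for r in out_rows),
    }
    for g in groups:
        cats = [
            (r["ir_genes"], r[f"freq_{g}"])
            for r in out_rows
            if r["ir_genes"] > 0 and not pd.isna(r[f"freq_{g}"])
        ]
        if cats:
            total[f"freq_{g}"] = splicing.ir_weighted_average(
                [c for c, _ in cats], [f for _, f in cats]
            )
        else:
            total[f"freq_{g}"] = np.nan
    out_rows.append(total)
    return pd.DataFrame(out_rows)


# ------------------------------------------------------------- analysis


def run_analysis(
    genome: dict[str, str],
    annotation: Annotation,
    junctions: list,
    coverage: dict[str, CoverageTrack],
    counts: pd.DataFrame,
    totals: pd.Series,
    probes: pd.DataFrame | None = None,
    go_map: dict[str, set[str]] | None = None,
    thresholds: Thresholds | None = None,
    samples: tuple[str, ...] = SAMPLES,
) -> PipelineResult:
    th = thresholds or Thresholds()
    samples = [s for s in samples if s in coverage]

    accepted = validate_and_filter(
        genome, junctions,
        min_anchor=th.min_anchor, min_support=th.min_support,
        min_intron=th.min_intron, max_intron=th.max_intron,
    )
    pooled = CoverageTrack.pooled([coverage[s] for s in samples]) if samples else \
        CoverageTrack(annotation.scaffold_lengths)

    transcripts = refine.assemble_transcripts(
        pooled, accepted, min_cov=th.min_cov, max_gap=th.max_gap
    )
    statuses, corrected = refine.compare_to_annotation(
        transcripts, annotation, zero_gap=th.zero_gap, cov=pooled,
        genome=genome, min_orf_codons=th.min_orf_codons,
    )
    corrected = refine.infer_utrs(pooled, corrected, statuses)
    novel = refine.detect_novel_regions(
        transcripts, corrected, min_len=th.novel_min_len,
        genome=genome, min_orf_codons=th.min_orf_codons,
    )

    events = []
    for m in corrected.sorted_models():
        events.extend(
            splicing.enumerate_as_events(
                accepted, coverage, m,
                groups=STAGE_GROUPS,
                min_spliced=th.min_spliced, min_depth=th.ir_min_depth,
                genome=genome,
            )
        )
    stage_specific = splicing.stage_specific_as(events)
    ir_table = summarize_ir_table(events, corrected, statuses, coverage)

    exon_lengths = pd.Series(
        {m.id: m.exon_length for m in annotation.models.values()}
    )
    rpkm = xp.rpkm_matrix(counts, exon_lengths, totals)
    stage_vals = xp.stage_rpkm(rpkm[[s for s in samples]],
                               {g: tuple(s for s in ss if s in samples)
                                for g, ss in STAGE_GROUPS.items()})
    stage_up = xp.call_stage_upregulated(
        stage_vals, min_rpkm=th.min_rpkm, min_fold=th.min_fold
    )

    renorm = assign = None
    correlations: dict[str, float] = {}
    if probes is not None and len(probes):
        renorm, assign = xp.reassign_and_renormalize(probes, corrected, samples)
        for s in samples:
            shared = renorm.index.intersection(rpkm.index)
            if len(shared) >= 3:
                correlations[s] = round(
                    xp.correlate_platforms(rpkm.loc[shared, s], renorm.loc[shared, s]), 3
                )

    enrichment: dict[str, list] = {}
    if go_map:
        for stage, gids in stage_up.items():
            test = [g for g in gids if g in go_map]
            dropped = len(gids) - len(test)
            if dropped:
                log.info("%s: %d up-regulated genes absent from GO universe", stage, dropped)
            if test:
                enrichment[stage] = xp.go_enrichment(test, go_map, alpha=th.go_alpha)
            else:
                enrichment[stage] = []

    report = _build_report(
        annotation, statuses, transcripts, novel, events, stage_specific,
        ir_table, stage_up, correlations, enrichment, corrected,
    )
    return PipelineResult(
        junctions=accepted, transcripts=transcripts, statuses=statuses,
        corrected=corrected, novel=novel, events=events,
        stage_specific_events=stage_specific, ir_table=ir_table,
        rpkm=rpkm, stage_vals=stage_vals, stage_up=stage_up,
        renormalized=renorm, probe_assign=assign,
        correlations=correlations, enrichment=enrichment, report=report,
    )


def _build_report(
    annotation, statuses, transcripts, novel, events, stage_specific,
    ir_table, stage_up, correlations, enrichment, corrected,
) -> dict:
    n_models = len(annotation.models)
    status_counts = {s: 0 for s in
                     ("complete_match", "boundary_mismatch",
                      "missing_or_extra_intron", "fused", "split", "undetected")}
    for st in statuses.values():
        status_counts[st.status] += 1
    n_detected = n_models - status_counts["undetected"]
    per_type = {t: 0 for t in ("cassette", "alt5", "alt3", "IR")}
    for e in events:
        per_type[e.event_type] += 1
    as_genes = sorted({e.gene_id for e in events})
    utr5 = [m.utr5[1] - m.utr5[0] for m in corrected.models.values() if m.utr5]
    utr3 = [m.utr3[1] - m.utr3[0] for m in corrected.models.values() if m.utr3]
    stage_specific_by_group = {g: 0 for g in STAGE_GROUPS}
    for e in stage_specific:
        for g, flag in e.stage_detected.items():
            if flag:
                stage_specific_by_group[g] += 1
    ir_total = ir_table.iloc[-1]
    report = {
        "n_models": n_models,
        "model_status_counts": status_counts,
        "pct_models_detected": percent(n_detected, n_models) if n_models else 0.0,
        "pct_models_completely_confirmed": percent(
            status_counts["complete_match"], n_models
        ) if n_models else 0.0,
        "n_transcripts": len(transcripts),
        "n_novel_regions": len(novel),
        "mean_novel_length": round(float(np.mean([n.length for n in novel])), 1)
        if novel else 0.0,
        "n_novel_coding": sum(1 for n in novel if n.coding),
        "as_event_counts": per_type,
        "n_as_events": total_as_events(per_type.values()),
        "n_as_genes": len(as_genes),
        "pct_genes_with_as": percent(len(as_genes), n_models) if n_models else 0.0,
        "n_stage_specific_as": len(stage_specific),
        "stage_specific_as_by_group": stage_specific_by_group,
        "n_ptc_events": sum(1 for e in events if e.ptc),
        "stage_up_counts": {g: len(v) for g, v in stage_up.items()},
        "ir_weighted_avg": {
            g: (None if pd.isna(ir_total[f"freq_{g}"]) else float(ir_total[f"freq_{g}"]))
            for g in IR_GROUPS
        },
        "n_ir_genes_multi_intron": int(ir_total["ir_genes"]),
        "platform_correlations": correlations,
        "mean_utr5_length": round(float(np.mean(utr5)), 1) if utr5 else 0.0,
        "mean_utr3_length": round(float(np.mean(utr3)), 1) if utr3 else 0.0,
        "n_enriched_terms": {
            g: sum(1 for r in res if r.significant)
            for g, res in enrichment.items()
        },
    }
    return report


# --------------------------------------------------------------- files


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """File-driven pipeline run; writes the report bundle under
    ``cfg.outdir`` and returns the in-memory result."""
    cfg.validate()
    genome = sio.read_genome(cfg.genome)
    scaffold_lengths = {name: len(s) for name, s in genome.items()}
    annotation = sio.read_annotation(cfg.annotation, scaffold_lengths)
    junctions = sio.read_junctions(cfg.junctions_bed, cfg.junction_support)
    coverage = {
        s: sio.read_bedgraph(p, scaffold_lengths) for s, p in cfg.coverage.items()
    }
    counts, totals = sio.read_counts(cfg.counts, cfg.totals)
    probes = sio.read_probes(cfg.probes) if cfg.probes else None
    go_map = None
    if cfg.go_terms:
        df = pd.read_csv(cfg.go_terms, sep="\t")
        go_map = {
            r["gene_id"]: set(str(r["terms"]).split(",")) if pd.notna(r["terms"]) and r["terms"] else set()
            for _, r in df.iterrows()
        }
    result = run_analysis(
        genome, annotation, junctions, coverage, counts, totals,
        probes=probes, go_map=go_map,
        thresholds=cfg.thresholds, samples=cfg.samples,
    )
    write_result(result, cfg.outdir)
    return result


def write_result(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "gene_id": st.gene_id,
                "status": st.status,
                "transcripts": ",".join(st.transcript_ids),
            }
            for st in sorted(result.statuses.values(), key=lambda s: s.gene_id)
        ]
    ).to_csv(outdir / "model_status.tsv", sep="\t", index=False)

    sio.write_annotation(result.corrected, outdir / "corrected_annotation.gff3")

    with open(outdir / "novel_regions.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for n in result.novel:
            fh.write(
                f"{n.scaffold}\tsplicerefine\tnovel_transcribed_region\t"
                f"{n.start + 1}\t{n.end}\t.\t.\t.\t"
                f"ID={n.id};coding={'yes' if n.coding else 'no'}\n"
            )

    pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "type": e.event_type,
                "scaffold": e.scaffold,
                "ref_introns": ";".join(f"{a}-{b}" for a, b in e.ref_introns),
                "alt_interval": f"{e.alt_interval[0]}-{e.alt_interval[1]}",
                "stages": ",".join(g for g, v in e.stage_detected.items() if v),
                "ptc": "" if e.ptc is None else int(e.ptc),
                "mean_as_intron_length": round(e.mean_as_intron_length, 2),
            }
            for e in result.events
        ],
        columns=["gene_id", "type", "scaffold", "ref_introns", "alt_interval",
                 "stages", "ptc", "mean_as_intron_length"],
    ).to_csv(outdir / "as_events.tsv", sep="\t", index=False)

    result.ir_table.to_csv(outdir / "ir_table.tsv", sep="\t", index=False)
    result.rpkm.round(4).sort_index().to_csv(
        outdir / "rpkm.tsv", sep="\t", index_label="gene_id"
    )
    pd.DataFrame(
        [
            {"stage": g, "gene_id": gid}
            for g, gids in result.stage_up.items()
            for gid in gids
        ],
        columns=["stage", "gene_id"],
    ).to_csv(outdir / "stage_upregulated.tsv", sep="\t", index=False)
    if result.renormalized is not None:
        result.renormalized.round(4).sort_index().to_csv(
            outdir / "renormalized_expression.tsv", sep="\t", index_label="gene_id"
        )
    for stage, res in result.enrichment.items():
        pd.DataFrame(
            [dataclasses.asdict(r) for r in res],
            columns=["term", "k", "K", "n", "N", "p_raw", "p_corrected", "significant"],
        ).to_csv(outdir / f"enrichment_{stage}.tsv", sep="\t", index=False)

    (outdir / "report.json").write_text(
        json.dumps(result.report, indent=1, sort_keys=True) + "\n"
    )
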