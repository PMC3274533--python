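"""Alternative-splicing detection and intron-retention statistics.

Four basic event classes are called per gene from the accepted junction
set and per-sample coverage, under stringent evidence rules:

* **alt5 / alt3** — two junctions sharing one splice site (the 3' or 5'
  site respectively, strand-aware) with differing partners; every junction
  must carry >= 2 non-redundant spliced reads in a sample for the event to
  count as detected there.
* **cassette** — a skipping junction from one intron's donor to the next
  intron's acceptor coexisting with both inclusion junctions, where the
  skipped exon is a complete annotated internal exon.  Junction pairs that
  belong to a cassette triple are not double-reported as alt5/alt3.
* **IR** (intron retention) — every base of the intron at >= 10x coverage
  *and* the spliced junction supported by >= 2 reads, so both isoforms are
  evidenced.

Events are flagged per life-cycle stage group; an event is stage-specific
when its full criteria are met in exactly one group.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np

from .genetics import first_inframe_stop
from .models import (
    ASEvent,
    CoverageTrack,
    GeneModel,
    Interval,
    IRGeneSummary,
    Junction,
    STAGE_GROUPS,
    IR_GROUPS,
)
from .refine import spliced_sequence, transcript_position

log = logging.getLogger(__name__)


# ------------------------------------------------------------ primitives


def detect_intron_retention(
    intron: Interval,
    cov: CoverageTrack,
    scaffold: str,
    spliced_support: int,
    min_depth: int = 10,
    min_spliced: int = 2,
) -> bool:
    """True iff every base of the intron has depth >= ``min_depth`` and the
    spliced junction has support >= ``min_spliced`` (both isoforms seen)."""
    if spliced_support < min_spliced:
        return False
    return cov.min_depth(scaffold, *intron) >= min_depth


def as_intron_mean_length(event: ASEvent) -> float:
    """Average AS intron length: mean of the two introns for alt5/alt3,
    mean of the three (two inclusion + skipping) for cassette, and simply
    the intron length for IR."""
    if event.event_type == "IR":
        lengths = [event.alt_interval[1] - event.alt_interval[0]]
    elif event.event_type == "cassette":
        lengths = [e - s for s, e in event.ref_introns] + [
            event.alt_interval[1] - event.alt_interval[0]
        ]
    else:
        lengths = [e - s for s, e in event.ref_introns] + [
            event.alt_interval[1] - event.alt_interval[0]
        ]
    return float(np.mean(lengths))


def ir_specificity(retention_counts) -> float:
    """Most-retained-intron frequency: max per-intron retention count over
    the total retention count.  Ties go to the 5'-most intron (the value is
    unaffected).  Undefined (ValueError) for a zero total."""
    counts = list(retention_counts)
    total = sum(counts)
    if total <= 0:
        raise ValueError("ir_specificity undefined for zero retention total")
    return max(counts) / total


def ir_weighted_average(counts, freqs) -> float:
    """Weighted average of per-category frequencies, weights = gene counts,
    rounded to 2 decimals for reporting."""
    counts = list(counts)
    freqs = list(freqs)
    if len(counts) != len(freqs):
        raise ValueError("counts and freqs must have equal length")
    if any(c <= 0 for c in counts):
        raise ValueError("counts must be positive")
    value = sum(c * f for c, f in zip(counts, freqs)) / sum(counts)
    return round(value, 2)


# ------------------------------------------------------------- PTC scan


def scan_ptc(isoform_seq: str, cds_start: int, annotated_stop: int | None = None) -> bool:
    """True iff an in-frame TGA occurs strictly upstream of the annotated
    stop in the isoform.

    ``cds_start`` is the transcript coordinate of the ATG; ``annotated_stop``
    is the transcript coordinate of the annotated stop codon's first base,
    or None when the annotated stop no longer maps (then any in-frame stop
    that is not the last complete codon counts as premature).
    """
    if cds_start < 0 or cds_start > len(isoform_seq) - 3:
        raise ValueError("CDS start not found in isoform")
    p = first_inframe_stop(isoform_seq, cds_start)
    if p is None:
        return False
    if annotated_stop is None:
        last_codon = cds_start + 3 * ((len(isoform_seq) - cds_start) // 3 - 1)
        return p < last_codon
    return p < annotated_stop


def _alt_exon_chain(gene: GeneModel, event: ASEvent) -> list[Interval] | None:
    """Exon chain of the alternative isoform implied by an event."""
    exons = [tuple(e) for e in gene.exons]
    if event.event_type == "IR":
        a, b = event.alt_interval
        out = []
        for ex in exons:
            if out and out[-1][1] == a and ex[0] == b:
                out[-1] = (out[-1][0], ex[1])
            else:
                out.append(ex)
        return out
    if event.event_type == "cassette":
        a, d = event.alt_interval
        (j1, j2) = event.ref_introns
        skipped = (j1[1], j2[0])
        out = [ex for ex in exons if ex != skipped]
        return out if len(out) < len(exons) else None
    # alt5 / alt3: the reference intron is replaced by the alternative one
    ref = event.ref_introns[0]
    alt = event.alt_interval
    out = []
    for ex in exons:
        s, e = ex
        if e == ref[0]:
            e = alt[0]
        if s == ref[1]:
            s = alt[1]
        if e <= s:
            return None
        out.append((s, e))
    return out


def event_ptc(genome: dict[str, str], gene: GeneModel, event: ASEvent) -> bool | None:
    """PTC flag for an event's alternative isoform, or None when the gene
    has no usable CDS."""
    if gene.cds is None:
        return None
    chain = _alt_exon_chain(gene, event)
    if chain is None:
        return None
    seq = spliced_sequence(genome, gene.scaffold, chain, gene.strand)
    if gene.strand == "+":
        g_start, g_stop = gene.cds[0], gene.cds[1] - 3
    else:
        g_start, g_stop = gene.cds[1] - 1, gene.cds[0] + 2
    t_start = transcript_position(chain, gene.strand, g_start)
    if t_start is None:
        return None
    t_stop = transcript_position(chain, gene.strand, g_stop)
    return scan_ptc(seq, t_start, t_stop)


# ------------------------------------------------------- event calling


def _five_three(j: Junction, strand: str) -> tuple[int, int]:
    """(5' site, 3' site) genomic coordinates of a junction on a strand."""
    return (j.start, j.end) if strand == "+" else (j.end, j.start)


def enumerate_as_events(
    junctions: list[Junction],
    covs: dict[str, CoverageTrack],
    gene: GeneModel,
    groups: dict[str, tuple[str, ...]] = STAGE_GROUPS,
    min_spliced: int = 2,
    min_depth: int = 10,
    genome: dict[str, str] | None = None,
) -> list[ASEvent]:
    """Classify all AS events of one gene.

    Junctions are assigned to the gene by span containment; junctions
    crossing the gene boundary are ignored with a log entry.  An event is
    emitted once per gene, with per-stage-group detected flags; events
    whose criteria are met in no sample are not emitted.
    """
    lo, hi = gene.span
    if gene.utr5:
        lo, hi = min(lo, gene.utr5[0]), max(hi, gene.utr5[1])
    if gene.utr3:
        lo, hi = min(lo, gene.utr3[0]), max(hi, gene.utr3[1])
    js = []
    for j in junctions:
        if j.scaffold != gene.scaffold or j.end <= lo or j.start >= hi:
            continue
        if j.start < lo or j.end > hi:
            log.info("junction %s crosses gene %s boundary; ignored", j.id or j.interval, gene.id)
            continue
        if j.strand in "+-" and j.strand != gene.strand:
            continue
        if j.total_support >= min_spliced:
            js.append(j)

    samples = [s for ss in groups.values() for s in ss]
    introns = set(map(tuple, gene.introns))
    internal_exons = {tuple(e) for e in gene.exons[1:-1]}
    by_interval = {j.interval: j for j in js}

    def sample_ok(j: Junction, sample: str) -> bool:
        return j.support.get(sample, 0) >= min_spliced

    def group_flags(check) -> dict[str, bool]:
        return {
            g: any(check(s) for s in members) for g, members in groups.items()
        }

    events: list[ASEvent] = []

    # cassette: skipping junction + both inclusion junctions + annotated exon
    cassette_pairs: set[frozenset] = set()
    for j1, j2 in combinations(sorted(js, key=lambda j: j.interval), 2):
        if j1.end >= j2.start:
            continue
        exon = (j1.end, j2.start)
        if exon not in internal_exons:
            continue
        skip = by_interval.get((j1.start, j2.end))
        if skip is None:
            continue
        flags = group_flags(
            lambda s, trio=(j1, j2, skip): all(sample_ok(j, s) for j in trio)
        )
        cassette_pairs.add(frozenset((j1.interval, skip.interval)))
        cassette_pairs.add(frozenset((j2.interval, skip.interval)))
        if any(flags.values()):
            events.append(
                ASEvent(
                    gene_id=gene.id,
                    event_type="cassette",
                    scaffold=gene.scaffold,
                    ref_introns=(j1.interval, j2.interval),
                    alt_interval=skip.interval,
                    stage_detected=flags,
                )
            )

    # alt5 / alt3: shared site pairs (strand-aware), excluding cassette pairs
    for j1, j2 in combinations(sorted(js, key=lambda j: j.interval), 2):
        if frozenset((j1.interval, j2.interval)) in cassette_pairs:
            continue
        f1, t1 = _five_three(j1, gene.strand)
        f2, t2 = _five_three(j2, gene.strand)
        if t1 == t2 and f1 != f2:
            etype = "alt5"
        elif f1 == f2 and t1 != t2:
            etype = "alt3"
        else:
            continue
        pair = sorted((j1.interval, j2.interval))
        annotated = [iv for iv in pair if iv in introns]
        if len(annotated) == 1:
            ref = annotated[0]
            alt = pair[0] if pair[1] == ref else pair[1]
        else:
            ref, alt = pair[0], pair[1]
        flags = group_flags(
            lambda s, duo=(j1, j2): all(sample_ok(j, s) for j in duo)
        )
        if any(flags.values()):
            events.append(
                ASEvent(
                    gene_id=gene.id,
                    event_type=etype,
                    scaffold=gene.scaffold,
                    ref_introns=(ref,),
                    alt_interval=alt,
                    stage_detected=flags,
                )
            )

    # IR: annotated introns with full-depth retention plus spliced evidence
    for intron in gene.introns:
        j = by_interval.get(tuple(intron))
        if j is None:
            continue
        flags = group_flags(
            lambda s, iv=tuple(intron), jj=j: (
                s in covs
                and detect_intron_retention(
                    iv, covs[s], gene.scaffold, jj.support.get(s, 0),
                    min_depth=min_depth, min_spliced=min_spliced,
                )
            )
        )
        if any(flags.values()):
            events.append(
                ASEvent(
                    gene_id=gene.id,
                    event_type="IR",
                    scaffold=gene.scaffold,
                    ref_introns=(tuple(intron),),
                    alt_interval=tuple(intron),
                    stage_detected=flags,
                )
            )

    for e in events:
        e.mean_as_intron_length = as_intron_mean_length(e)
        if genome is not None:
            e.ptc = event_ptc(genome, gene, e)
    events.sort(key=lambda e: (e.ref_introns, e.alt_interval, e.event_type))
    return events


def stage_specific_as(events: list[ASEvent]) -> list[ASEvent]:
    """Events whose full stringent criteria are met in exactly one
    stage group."""
    return [e for e in events if sum(bool(v) for v in e.stage_detected.values()) == 1]


# ----------------------------------------------- IR gene summaries


def ir_gene_summary(
    gene: GeneModel,
    covs: dict[str, CoverageTrack],
    groups: dict[str, tuple[str, ...]] = IR_GROUPS,
) -> IRGeneSummary:
    """Per-intron retention evidence for one gene.

    The retention read count of an intron in a stage group is approximated
    by the minimum per-base depth over the intron, summed over the group's
    samples — a conservative proxy for reads indicating retention.
    Introns are listed 5'-most first (transcript orientation).
    """
    introns = gene.introns
    if gene.strand == "-":
        introns = introns[::-1]
    counts = {}
    for g, members in groups.items():
        per_intron = []
        for iv in introns:
            c = sum(
                covs[s].min_depth(gene.scaffold, *iv) for s in members if s in covs
            )
            per_intron.append(int(c))
        counts[g] = per_intron
    return IRGeneSummary(
        gene_id=gene.id, n_introns=len(introns), retention_counts=counts
    )
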