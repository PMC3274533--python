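"""Transcript assembly and gene-model refinement.

This module holds the simplified coverage-island assembler that stands in
for a full isoform assembler, plus the comparison of assembled transcripts
against the existing annotation (confirm / correct / split / fuse), novel
transcribed-region calling and UTR inference from read coverage.

Assembler sketch
----------------
1. Per scaffold, maximal runs with depth >= ``min_cov`` become coverage
   islands; gaps <= ``max_gap`` are bridged **unless** an accepted junction's
   intron spans the gap (junction evidence wins over gap bridging, so short
   introns are not erased).
2. Islands are cut into segments at the boundaries of accepted junctions.
3. Segments are nodes in a graph with two edge kinds: adjacency (contiguous
   coverage, e.g. a retained intron) and junction edges (splicing).
4. Each maximal path through the graph is one transcript; retained introns
   and alternative junctions therefore yield the expected multiple isoform
   paths.  Components with more than ``max_paths`` paths fall back to a
   single greedy maximum-support path.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from .genetics import longest_orf, longest_orf_either_strand, revcomp
from .models import (
    Annotation,
    CoverageTrack,
    GeneModel,
    Interval,
    Junction,
    ModelStatus,
    NovelRegion,
    Transcript,
)

log = logging.getLogger(__name__)


# ----------------------------------------------------------- sequences


def spliced_sequence(genome: dict[str, str], scaffold: str, exons, strand: str) -> str:
    """Transcript-orientation sequence of an exon chain."""
    s = "".join(genome[scaffold][a:b] for a, b in sorted(exons))
    return revcomp(s) if strand == "-" else s


def transcript_position(exons, strand: str, genomic_pos: int) -> int | None:
    """Map a genomic position to its transcript coordinate, or None if the
    position falls in an intron."""
    offsets = []
    walked = 0
    for a, b in sorted(exons):
        if a <= genomic_pos < b:
            offsets.append(walked + (genomic_pos - a))
            break
        walked += b - a
    if not offsets:
        return None
    total = sum(b - a for a, b in exons)
    return offsets[0] if strand != "-" else total - 1 - offsets[0]


# -------------------------------------------------------------- islands


def _islands(depth: np.ndarray, min_cov: int, max_gap: int, junction_introns) -> list[Interval]:
    mask = (depth >= min_cov).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
    runs = list(zip(edges[0::2], edges[1::2]))
    if not runs:
        return []
    spans = sorted(junction_introns)
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        gap = (merged[-1][1], s)
        spliced = any(js <= gap[0] and je >= gap[1] for js, je in spans)
        if gap[1] - gap[0] <= max_gap and not spliced:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(int(s), int(e)) for s, e in merged]


class _Node:
    __slots__ = ("start", "end", "adj_out", "adj_in", "junc_out", "junc_in")

    def __init__(self, start, end):
        self.start, self.end = start, end
        self.adj_out = None
        self.adj_in = None
        self.junc_out: list[tuple[Junction, "_Node"]] = []
        self.junc_in: list[Junction] = []


def assemble_transcripts(
    cov: CoverageTrack,
    junctions: list[Junction],
    min_cov: int = 2,
    max_gap: int = 25,
    max_paths: int = 64,
) -> list[Transcript]:
    """Assemble transcripts from a (pooled) coverage track and the accepted
    junction set.  See the module docstring for the algorithm."""
    raw: list[tuple[str, str, tuple[Interval, ...]]] = []
    for scaffold in sorted(cov.depth):
        depth = cov.depth[scaffold]
        js = [j for j in junctions if j.scaffold == scaffold]
        islands = _islands(depth, min_cov, max_gap, [j.interval for j in js])
        if not islands:
            continue
        starts = np.array([s for s, _ in islands])
        ends = np.array([e for _, e in islands])

        def island_of(pos: int) -> int | None:
            i = int(np.searchsorted(ends, pos, side="right"))
            if i < len(islands) and starts[i] <= pos < ends[i]:
                return i
            return None

        usable = []
        cuts: dict[int, set[int]] = defaultdict(set)
        for j in js:
            di = island_of(j.start - 1)
            ai = island_of(j.end)
            if di is None or ai is None:
                log.info("junction %s anchors outside covered islands; unused", j.id or j.interval)
                continue
            usable.append(j)
            if starts[di] < j.start < ends[di]:
                cuts[di].add(j.start)
            if starts[ai] < j.end < ends[ai]:
                cuts[ai].add(j.end)

        nodes: list[_Node] = []
        start_at: dict[int, _Node] = {}
        end_at: dict[int, _Node] = {}
        for i, (s, e) in enumerate(islands):
            bounds = sorted({s, e, *cuts.get(i, ())})
            prev = None
            for a, b in zip(bounds[:-1], bounds[1:]):
                node = _Node(a, b)
                nodes.append(node)
                start_at[a] = node
                end_at[b] = node
                if prev is not None:
                    prev.adj_out = node
                    node.adj_in = prev
                prev = node

        best_edge: dict[tuple[int, int], Junction] = {}
        for j in usable:
            key = (j.start, j.end)
            cur = best_edge.get(key)
            if cur is None or j.total_support > cur.total_support:
                best_edge[key] = j
        for (a, b), j in sorted(best_edge.items()):
            end_at[a].junc_out.append((j, start_at[b]))
            start_at[b].junc_in.append(j)
        for node in nodes:
            node.junc_out.sort(key=lambda e: (e[1].start, e[0].end))

        # connected components, then path enumeration
        comp = {id(n): None for n in nodes}
        comp_id = 0
        for node in nodes:
            if comp[id(node)] is not None:
                continue
            stack = [node]
            members = []
            while stack:
                n = stack.pop()
                if comp[id(n)] is not None:
                    continue
                comp[id(n)] = comp_id
                members.append(n)
                nbrs = [n.adj_out, n.adj_in] + [t for _, t in n.junc_out]
                nbrs += [end_at[j.start] for j in n.junc_in]
                for nb in nbrs:
                    if nb is not None and comp[id(nb)] is None:
                        stack.append(nb)
            sources = [
                n for n in members if n.adj_in is None and not n.junc_in
            ]
            sources.sort(key=lambda n: n.start)
            paths = []
            overflow = False
            for src in sources:

                def walk(n, open_exon, exons, juncs):
                    nonlocal overflow
                    if overflow:
                        return
                    open_exon = [open_exon[0], n.end]
                    outs = []
                    if n.adj_out is not None:
                        outs.append(("adj", n.adj_out, None))
                    for j, tgt in n.junc_out:
                        outs.append(("junc", tgt, j))
                    if not outs:
                        paths.append((exons + [tuple(open_exon)], list(juncs)))
                        if len(paths) > max_paths:
                            overflow = True
                        return
                    for kind, tgt, j in outs:
                        if kind == "adj":
                            walk(tgt, open_exon, exons, juncs)
                        else:
                            walk(
                                tgt,
                                [tgt.start, tgt.end],
                                exons + [tuple(open_exon)],
                                juncs + [j],
                            )

                walk(src, [src.start, src.end], [], [])
            if overflow:
                paths = []
                for src in sources:
                    exons = [[src.start, src.end]]
                    juncs = []
                    n = src
                    while True:
                        if n.junc_out:
                            j, tgt = max(
                                n.junc_out,
                                key=lambda e: (e[0].total_support, -e[1].start),
                            )
                            exons[-1][1] = n.end
                            exons.append([tgt.start, tgt.end])
                            juncs.append(j)
                            n = tgt
                        elif n.adj_out is not None:
                            n = n.adj_out
                            exons[-1][1] = n.end
                        else:
                            break
                    paths.append(([tuple(e) for e in exons], juncs))
                log.info(
                    "scaffold %s: component with >%d isoform paths; greedy fallback",
                    scaffold, max_paths,
                )
            for exons, juncs in paths:
                strands = {j.strand for j in juncs if j.strand in "+-"}
                if len(strands) == 1:
                    strand = strands.pop()
                elif not strands:
                    strand = "."
                else:
                    strand = "+"
                    log.info("mixed-strand junction path at %s:%d; forced '+'", scaffold, exons[0][0])
                raw.append((scaffold, strand, tuple(exons)))
            comp_id += 1

    raw = sorted(set(raw), key=lambda r: (r[0], r[2][0][0], r[2], r[1]))
    out = []
    for i, (scaffold, strand, exons) in enumerate(raw):
        mean_cov = [
            float(cov.query(scaffold, a, b).mean()) if b > a else 0.0
            for a, b in exons
        ]
        out.append(
            Transcript(
                id=f"T{i + 1:06d}",
                scaffold=scaffold,
                strand=strand,
                exons=[(int(a), int(b)) for a, b in exons],
                mean_exon_coverage=mean_cov,
            )
        )
    return out


# --------------------------------------------------- model comparison


def _exonic_overlap(a_exons, b_exons) -> int:
    total = 0
    for s1, e1 in a_exons:
        for s2, e2 in b_exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _strand_ok(t: Transcript, m: GeneModel) -> bool:
    return t.strand == "." or t.strand == m.strand


def _contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and outer[1] >= inner[1]


def _has_zero_run(cov: CoverageTrack, scaffold: str, gap: Interval, min_len: int) -> bool:
    """True if the gap contains a run of >= min_len zero-depth bases (an
    unrelated transcribed region inside the gap does not hide the
    discontinuity between the flanking transcripts)."""
    v = cov.query(scaffold, *gap)
    if not len(v):
        return False
    zero = (v == 0).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], zero, [0]))))
    runs = edges[1::2] - edges[0::2]
    return bool(len(runs) and runs.max() >= min_len)


def compare_to_annotation(
    transcripts: list[Transcript],
    ann: Annotation,
    zero_gap: int = 50,
    cov: CoverageTrack | None = None,
    genome: dict[str, str] | None = None,
    min_orf_codons: int = 50,
) -> tuple[dict[str, ModelStatus], Annotation]:
    """Classify every annotated model against the assembly and build the
    corrected annotation.

    Statuses, in decision order per model: ``complete_match`` (a transcript's
    intron chain equals the model's and covers its span), ``fused`` (one
    transcript contains this model and >=1 neighbour end-to-end), ``split``
    (>=2 transcript clusters inside the model span separated by a
    zero-coverage gap >= ``zero_gap``), ``boundary_mismatch`` /
    ``missing_or_extra_intron`` (same / different intron count in the best
    overlapping transcript), else ``undetected``.
    """
    by_scaffold: dict[str, list[Transcript]] = defaultdict(list)
    for t in transcripts:
        by_scaffold[t.scaffold].append(t)
    models = ann.sorted_models()
    models_by_scaffold: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        models_by_scaffold[m.scaffold].append(m)

    statuses: dict[str, ModelStatus] = {}
    fusion_groups: dict[str, list[GeneModel]] = defaultdict(list)  # transcript id -> models
    split_parts: dict[str, list[Transcript]] = {}
    best_fix: dict[str, Transcript] = {}

    for m in models:
        cands = [
            t
            for t in by_scaffold.get(m.scaffold, [])
            if _strand_ok(t, m) and _exonic_overlap(t.exons, m.exons) > 0
        ]
        if not cands:
            statuses[m.id] = ModelStatus(m.id, "undetected")
            continue
        exact = [
            t
            for t in cands
            if t.introns == m.introns and _contains(t.span, m.span)
        ]
        if exact:
            statuses[m.id] = ModelStatus(m.id, "complete_match", [exact[0].id])
            continue
        fused_via = None
        for t in sorted(cands, key=lambda t: (t.span[0], t.id)):
            contained = [
                m2
                for m2 in models_by_scaffold[m.scaffold]
                if _contains(t.span, m2.span) and _strand_ok(t, m2)
            ]
            if len(contained) >= 2 and any(m2.id == m.id for m2 in contained):
                fused_via = t
                break
        if fused_via is not None:
            statuses[m.id] = ModelStatus(m.id, "fused", [fused_via.id])
            fusion_groups[fused_via.id].append(m)
            continue
        # transcripts assigned to the model (annotated spans lack UTRs, so
        # real transcripts overhang them; exonic overlap, not containment,
        # defines assignment)
        inside = sorted(cands, key=lambda t: t.span)
        clusters: list[list[Transcript]] = []
        for t in inside:
            if clusters and t.span[0] < max(x.span[1] for x in clusters[-1]):
                clusters[-1].append(t)
            else:
                clusters.append([t])
        if len(clusters) >= 2:
            ok = True
            for left, right in zip(clusters[:-1], clusters[1:]):
                gap = (max(x.span[1] for x in left), min(x.span[0] for x in right))
                if gap[1] - gap[0] < zero_gap:
                    ok = False
                    break
                if cov is not None and not _has_zero_run(
                    cov, m.scaffold, gap, zero_gap
                ):
                    ok = False
                    break
            if ok:
                reps = [
                    max(c, key=lambda t: (t.length, t.id)) for c in clusters
                ]
                statuses[m.id] = ModelStatus(m.id, "split", [t.id for t in reps])
                split_parts[m.id] = reps
                continue
        best = max(
            cands,
            key=lambda t: (_exonic_overlap(t.exons, m.exons), -t.span[0], t.id),
        )
        best_fix[m.id] = best
        if len(best.introns) == len(m.introns):
            statuses[m.id] = ModelStatus(m.id, "boundary_mismatch", [best.id])
        else:
            statuses[m.id] = ModelStatus(m.id, "missing_or_extra_intron", [best.id])

    tlookup = {t.id: t for t in transcripts}
    corrected = _build_corrected(
        ann, statuses, fusion_groups, split_parts, best_fix, tlookup,
        genome, min_orf_codons,
    )
    return statuses, corrected


def _orf_cds(genome, scaffold, exons, strand, min_orf_codons) -> Interval | None:
    if genome is None:
        return None
    seq = spliced_sequence(genome, scaffold, exons, strand)
    orf = longest_orf(seq, min_codons=min_orf_codons)
    if orf is None:
        return None
    # map transcript ORF bounds back to a genomic span
    total = sum(b - a for a, b in exons)
    if strand == "-":
        t0, t1 = total - orf[1], total - orf[0]
    else:
        t0, t1 = orf
    walked = 0
    g0 = g1 = None
    for a, b in sorted(exons):
        if g0 is None and walked + (b - a) > t0:
            g0 = a + (t0 - walked)
        if walked + (b - a) >= t1:
            g1 = a + (t1 - walked)
            break
        walked += b - a
    if g0 is None or g1 is None:
        return None
    return (g0, g1)


def _build_corrected(
    ann, statuses, fusion_groups, split_parts, best_fix, tlookup,
    genome, min_orf_codons,
) -> Annotation:
    corrected: dict[str, GeneModel] = {}
    done: set[str] = set()
    tmap = {}
    for tid, group in fusion_groups.items():
        group = sorted(group, key=lambda m: m.span)
        tmap[tid] = group

    for m in ann.sorted_models():
        st = statuses[m.id].status
        if m.id in done:
            continue
        if st in ("complete_match", "undetected"):
            corrected[m.id] = GeneModel(
                m.id, m.scaffold, m.strand, list(m.exons), m.cds
            )
        elif st == "fused":
            tid = statuses[m.id].transcript_ids[0]
            group = tmap[tid]
            gid = "--".join(g.id for g in group)
            if gid not in corrected:
                t = tlookup[tid]
                strand = t.strand if t.strand in "+-" else group[0].strand
                corrected[gid] = GeneModel(
                    gid,
                    m.scaffold,
                    strand,
                    list(t.exons),
                    _orf_cds(genome, m.scaffold, t.exons, strand, min_orf_codons),
                )
            done.update(g.id for g in group)
        elif st == "split":
            for i, t in enumerate(split_parts[m.id], start=1):
                gid = f"{m.id}.s{i}"
                strand = t.strand if t.strand in "+-" else m.strand
                corrected[gid] = GeneModel(
                    gid,
                    m.scaffold,
                    strand,
                    list(t.exons),
                    _orf_cds(genome, m.scaffold, t.exons, strand, min_orf_codons),
                )
        else:  # boundary_mismatch / missing_or_extra_intron
            t = best_fix[m.id]
            corrected[m.id] = GeneModel(
                m.id,
                m.scaffold,
                m.strand,
                list(t.exons),
                _orf_cds(genome, m.scaffold, t.exons, m.strand, min_orf_codons),
            )
    out = Annotation(
        models=corrected,
        scaffold_lengths=dict(ann.scaffold_lengths),
        provenance="corrected",
    )
    return out


# ----------------------------------------------------- novel regions


def detect_novel_regions(
    transcripts: list[Transcript],
    ann: Annotation,
    min_len: int = 300,
    genome: dict[str, str] | None = None,
    min_orf_codons: int = 50,
) -> list[NovelRegion]:
    """Transcripts lying entirely in intergenic space with span >= min_len.

    Each region is tagged coding/non-coding by a ciliate-code ORF scan of
    its spliced sequence (either strand when the transcript is unstranded).
    """
    spans: dict[str, list[Interval]] = defaultdict(list)
    for m in ann.sorted_models():
        lo, hi = m.span
        if m.utr5:
            lo, hi = min(lo, m.utr5[0]), max(hi, m.utr5[1])
        if m.utr3:
            lo, hi = min(lo, m.utr3[0]), max(hi, m.utr3[1])
        spans[m.scaffold].append((lo, hi))
    novel = []
    for t in sorted(transcripts, key=lambda t: (t.scaffold, t.span)):
        if t.length < min_len:
            continue
        s, e = t.span
        if any(s < hi and e > lo for lo, hi in spans.get(t.scaffold, [])):
            continue
        coding, orf = False, None
        if genome is not None:
            seq = spliced_sequence(genome, t.scaffold, t.exons, t.strand if t.strand in "+-" else "+")
            if t.strand in "+-":
                o = longest_orf(seq, min_codons=min_orf_codons)
                orf = o
            else:
                both = longest_orf_either_strand(seq, min_codons=min_orf_codons)
                orf = both[0] if both else None
            coding = orf is not None
        novel.append(
            NovelRegion(
                id=f"NOV{len(novel) + 1:04d}",
                scaffold=t.scaffold,
                start=s,
                end=e,
                coding=coding,
                orf=orf,
                transcript_id=t.id,
            )
        )
    return novel


# ------------------------------------------------------------- UTRs


def infer_utrs(
    cov: CoverageTrack,
    ann: Annotation,
    statuses: dict[str, ModelStatus] | None = None,
) -> Annotation:
    """Attach 5'/3' UTRs to confirmed models.

    The UTR extends from each CDS end through contiguous positions with
    depth >= 1, stopping at the first zero-depth base or the nearest
    neighbouring gene boundary, whichever comes first.  Only models with
    status ``complete_match`` are inspected (the most credible ORFs); with
    no status table every model is inspected.
    """
    by_scaffold: dict[str, list[GeneModel]] = defaultdict(list)
    for m in ann.sorted_models():
        by_scaffold[m.scaffold].append(m)
    for scaffold, ms in by_scaffold.items():
        depth = cov.depth.get(scaffold)
        if depth is None:
            continue
        for i, m in enumerate(ms):
            if statuses is not None and statuses.get(m.id, ModelStatus(m.id, "")).status != "complete_match":
                continue
            left_limit = ms[i - 1].span[1] if i > 0 else 0
            right_limit = ms[i + 1].span[0] if i + 1 < len(ms) else len(depth)
            s, e = m.span
            pos = s - 1
            while pos >= left_limit and pos >= 0 and depth[pos] >= 1:
                pos -= 1
            left = (pos + 1, s) if pos + 1 < s else None
            pos = e
            while pos < right_limit and pos < len(depth) and depth[pos] >= 1:
                pos += 1
            right = (e, pos) if pos > e else None
            if m.strand == "+":
                m.utr5, m.utr3 = left, right
            else:
                m.utr5, m.utr3 = right, left
    return ann
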