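"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
Internal coordinates are 0-based half-open everywhere.  GFF3/GTF are
1-based inclusive on disk and converted at this boundary; BED12 and
bedGraph are already 0-based half-open.  All writers emit deterministic
ordering (scaffold, start, id) so identical inputs give byte-identical
files.

Readers reject structurally invalid input rather than silently repairing
it; the single exception is exon sort order, which is repaired with a
logged warning (see :meth:`GeneModel.validate`).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from .models import (
    Annotation,
    CoverageTrack,
    GeneModel,
    Junction,
    ValidationError,
)

log = logging.getLogger(__name__)

# ---------------------------------------------------------------- FASTA


def read_genome(path) -> dict[str, str]:
    """Load a genome FASTA into a dict of upper-case sequences."""
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_genome(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ------------------------------------------------------------- GFF3/GTF

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _detect_dialect(path) -> str:
    """'gff3' or 'gtf' by attribute syntax; mixed files are rejected."""
    kinds = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValidationError(f"{path}: malformed feature line")
            attr = fields[8].strip()
            first = attr.split(";")[0].strip()
            if _GTF_ATTR.match(first):
                kinds.add("gtf")
            elif "=" in first:
                kinds.add("gff3")
            else:
                raise ValidationError(
                    f"{path}: unrecognised attribute syntax: {first!r}"
                )
    if not kinds:
        raise ValidationError(f"{path}: no features found")
    if len(kinds) > 1:
        raise ValidationError(f"{path}: mixed GFF3/GTF attribute dialects")
    return kinds.pop()


def _sequence_regions(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, name, _start, end = line.split()[:4]
                out[name] = int(end)
            elif not line.startswith("#") and line.strip():
                break
    return out


def read_annotation(path, scaffold_lengths: dict[str, int] | None = None) -> Annotation:
    """Read a GFF3 or GTF annotation into the internal data model.

    The dialect is auto-detected from the attribute syntax.  1-based
    inclusive coordinates become 0-based half-open.  Exons outside the
    scaffold bounds raise :class:`ValidationError` naming the feature.
    """
    import gffutils

    dialect = _detect_dialect(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=(dialect == "gff3"),
        disable_infer_transcripts=(dialect == "gff3"),
    )
    lengths = dict(scaffold_lengths or {})
    lengths.update(_sequence_regions(path))

    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        if dialect == "gtf":
            gid = gene.attributes.get("gene_id", [gene.id])[0]
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(gene.id, featuretype="exon")
        )
        cds_parts = [
            (f.start - 1, f.end)
            for f in db.children(gene.id, featuretype="CDS")
        ]
        utr5 = [
            (f.start - 1, f.end)
            for f in db.children(gene.id, featuretype="five_prime_UTR")
        ]
        utr3 = [
            (f.start - 1, f.end)
            for f in db.children(gene.id, featuretype="three_prime_UTR")
        ]
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        cds = None
        if cds_parts:
            cds = (min(s for s, _ in cds_parts), max(e for _, e in cds_parts))
        model = GeneModel(
            id=gid,
            scaffold=gene.seqid,
            strand=gene.strand if gene.strand in "+-" else "+",
            exons=exons,
            cds=cds,
            utr5=utr5[0] if utr5 else None,
            utr3=utr3[0] if utr3 else None,
        )
        if gene.strand not in "+-":
            log.warning("%s: strand '.' treated as '+'", gid)
        model.validate(lengths.get(gene.seqid))
        models[gid] = model

    if not lengths:
        for m in models.values():
            lengths[m.scaffold] = max(lengths.get(m.scaffold, 0), m.span[1])
    ann = Annotation(models=models, scaffold_lengths=lengths, provenance=str(path))
    return ann


def write_annotation(ann: Annotation, path, source: str = "splicerefine") -> None:
    """Write the annotation as GFF3 (gene/mRNA/exon/CDS plus UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in sorted(ann.scaffold_lengths):
            fh.write(f"##sequence-region {name} 1 {ann.scaffold_lengths[name]}\n")
        for m in ann.sorted_models():
            lo, hi = m.span
            if m.utr5:
                lo = min(lo, m.utr5[0])
                hi = max(hi, m.utr5[1])
            if m.utr3:
                lo = min(lo, m.utr3[0])
                hi = max(hi, m.utr3[1])

            def row(ftype, s, e, attrs, phase="."):
                fh.write(
                    "\t".join(
                        [
                            m.scaffold,
                            source,
                            ftype,
                            str(s + 1),
                            str(e),
                            ".",
                            m.strand,
                            phase,
                            attrs,
                        ]
                    )
                    + "\n"
                )

            row("gene", lo, hi, f"ID={m.id}")
            tid = f"{m.id}.t1"
            row("mRNA", lo, hi, f"ID={tid};Parent={m.id}")
            if m.utr5:
                row("five_prime_UTR", m.utr5[0], m.utr5[1], f"Parent={tid}")
            for s, e in m.exons:
                row("exon", s, e, f"Parent={tid}")
            if m.cds:
                cds_parts = [
                    (max(s, m.cds[0]), min(e, m.cds[1]))
                    for s, e in m.exons
                    if e > m.cds[0] and s < m.cds[1]
                ]
                if m.strand == "-":
                    cds_parts = cds_parts[::-1]
                walked = 0
                rows = []
                for s, e in cds_parts:
                    phase = (3 - walked % 3) % 3
                    rows.append((s, e, phase))
                    walked += e - s
                for s, e, phase in sorted(rows):
                    row("CDS", s, e, f"Parent={tid}", phase=str(phase))
            if m.utr3:
                row("three_prime_UTR", m.utr3[0], m.utr3[1], f"Parent={tid}")


# ------------------------------------------------------------ junctions


def write_junctions(junctions: list[Junction], bed_path, support_path, samples) -> None:
    """Write junctions as BED12 (block sizes = anchors, gap = intron) plus a
    TSV of per-sample non-redundant support."""
    ordered = sorted(junctions, key=lambda j: (j.scaffold, j.start, j.end))
    rows = []
    with open(bed_path, "w") as fh:
        for i, j in enumerate(ordered):
            name = j.id or f"JUNC{i + 1:06d}"
            a = max(int(j.min_anchor), 1)
            cs, ce = j.start - a, j.end + a
            fh.write(
                "\t".join(
                    [
                        j.scaffold,
                        str(cs),
                        str(ce),
                        name,
                        str(min(j.total_support, 1000)),
                        j.strand,
                        str(cs),
                        str(ce),
                        "0,0,0",
                        "2",
                        f"{a},{a}",
                        f"0,{j.end - cs}",
                    ]
                )
                + "\n"
            )
            rows.append(
                {"junction_id": name, **{s: int(j.support.get(s, 0)) for s in samples}}
            )
    pd.DataFrame(rows, columns=["junction_id", *samples]).to_csv(
        support_path, sep="\t", index=False
    )


def read_junctions(bed_path, support_path) -> list[Junction]:
    """Read BED12 junction records and their per-sample support table."""
    support = {}
    samples: list[str] = []
    sup = pd.read_csv(support_path, sep="\t", dtype={"junction_id": str})
    samples = [c for c in sup.columns if c != "junction_id"]
    for _, r in sup.iterrows():
        support[r["junction_id"]] = {s: int(r[s]) for s in samples}

    junctions = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, cs, ce, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            if len(sizes) != 2:
                raise ValidationError(f"{name}: expected 2 blocks")
            left, right = sizes
            if left <= 0 or right <= 0:
                raise ValidationError(f"{name}: non-positive anchor")
            start, end = cs + left, ce - right
            if end - start <= 0:
                raise ValidationError(f"{name}: non-positive intron gap")
            junctions.append(
                Junction(
                    scaffold=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    support=support.get(name, {}),
                    min_anchor=min(left, right),
                    id=name,
                )
            )
    return junctions


# ------------------------------------------------------------- bedGraph


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length encode the track; zero-depth regions are omitted."""
    with open(path, "w") as fh:
        for name in sorted(track.depth):
            arr = track.depth[name]
            if not len(arr):
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                d = int(arr[s])
                if d > 0:
                    fh.write(f"{name}\t{s}\t{e}\t{d}\n")


def read_bedgraph(path, scaffold_lengths: dict[str, int]) -> CoverageTrack:
    """Read a bedGraph into a dense track; overlapping records are a
    format error, absent positions read as depth 0."""
    track = CoverageTrack(scaffold_lengths)
    occupied = {n: np.zeros(l, dtype=bool) for n, l in scaffold_lengths.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            name, s, e, d = line.split()
            s, e, d = int(s), int(e), int(d)
            if name not in track.depth:
                raise ValidationError(f"{path}:{ln}: unknown scaffold {name}")
            if e > scaffold_lengths[name] or s < 0 or e <= s:
                raise ValidationError(f"{path}:{ln}: interval out of bounds")
            if occupied[name][s:e].any():
                raise ValidationError(f"{path}:{ln}: overlapping intervals")
            occupied[name][s:e] = True
            track.depth[name][s:e] = d
    return track


# ------------------------------------------------------------- TSV tables


def write_counts(counts: pd.DataFrame, totals: pd.Series, counts_path, totals_path) -> None:
    counts.sort_index().to_csv(counts_path, sep="\t", index_label="gene_id")
    totals.rename("total_mapped_reads").to_csv(
        totals_path, sep="\t", index_label="sample"
    )


def read_counts(counts_path, totals_path) -> tuple[pd.DataFrame, pd.Series]:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    totals = pd.read_csv(totals_path, sep="\t", index_col="sample")[
        "total_mapped_reads"
    ]
    return counts, totals


def write_probes(probes: pd.DataFrame, path) -> None:
    probes.sort_values(["scaffold", "start", "probe_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_probes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
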