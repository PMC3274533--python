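"""Core in-memory containers shared across the pipeline.

All coordinates are 0-based half-open in transcript-agnostic genomic space;
conversion to/from the 1-based inclusive GFF convention happens only at the
I/O boundary (see :mod:`splicerefine.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

Interval = tuple[int, int]

#: The five profiled samples, in life-cycle order: mid-log growth, 3 h and
#: 15 h starvation, 2 h and 8 h conjugation.
SAMPLES = ("G-m", "S-3", "S-15", "C-2", "C-8")

#: Life-cycle stage grouping of the samples.
STAGE_GROUPS = {
    "growth": ("G-m",),
    "starvation": ("S-3", "S-15"),
    "conjugation": ("C-2", "C-8"),
}

#: Two-way grouping used for the intron-retention specificity table.
IR_GROUPS = {
    "growth_starvation": ("G-m", "S-3", "S-15"),
    "conjugation": ("C-2", "C-8"),
}


class ValidationError(ValueError):
    """Structurally invalid input that the pipeline refuses to repair."""


@dataclass
class GeneModel:
    """One annotated gene model: ordered exons plus the CDS span.

    The original Tetrahymena annotation carries no UTRs, so ``exons``
    normally coincides with the CDS region; inferred UTRs are attached
    separately.
    """

    id: str
    scaffold: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: Interval | None = None
    utr5: Interval | None = None
    utr3: Interval | None = None

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, left to right in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def validate(self, scaffold_length: int | None = None) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.id}: bad strand {self.strand!r}")
        exons = sorted(self.exons)
        if exons != self.exons:
            log.warning("%s: exons were unsorted; sorting", self.id)
            self.exons = exons
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"{self.id}: empty exon ({s},{e})")
        for i in range(len(self.exons) - 1):
            if self.exons[i][1] > self.exons[i + 1][0]:
                raise ValidationError(f"{self.id}: overlapping exons")
        for s, e in self.introns:
            if e - s < 1:
                raise ValidationError(f"{self.id}: intron of length < 1")
        if scaffold_length is not None:
            if self.exons[0][0] < 0 or self.exons[-1][1] > scaffold_length:
                raise ValidationError(
                    f"{self.id}: exon outside scaffold bounds"
                )
        if self.cds is not None:
            lo, hi = self.span
            if not (lo <= self.cds[0] < self.cds[1] <= hi):
                raise ValidationError(f"{self.id}: CDS outside exon union")


@dataclass
class Annotation:
    """A genome annotation: gene models plus scaffold sizes."""

    models: dict[str, GeneModel]
    scaffold_lengths: dict[str, int]
    provenance: str = ""

    def validate(self) -> None:
        for m in self.models.values():
            m.validate(self.scaffold_lengths.get(m.scaffold))

    def sorted_models(self) -> list[GeneModel]:
        return sorted(
            self.models.values(), key=lambda m: (m.scaffold, m.span[0], m.id)
        )

    def models_on(self, scaffold: str) -> list[GeneModel]:
        return [m for m in self.sorted_models() if m.scaffold == scaffold]


@dataclass
class Junction:
    """One splice junction (an intron supported by spliced reads).

    ``donor_dinuc``/``acceptor_dinuc`` are reported in transcript
    orientation, so a canonical junction reads GT..AG on either strand.
    ``support`` maps sample name to the non-redundant spliced-read count.
    """

    scaffold: str
    start: int
    end: int
    strand: str = "."
    support: dict[str, int] = field(default_factory=dict)
    min_anchor: int = 0
    donor_dinuc: str | None = None
    acceptor_dinuc: str | None = None
    canonical: bool | None = None
    id: str | None = None

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_support(self) -> int:
        return sum(self.support.values())

    def copy(self, **changes) -> "Junction":
        j = replace(self, **changes)
        j.support = dict(self.support)
        return j


class CoverageTrack:
    """Dense per-base read depth for one sample (or a pool of samples)."""

    def __init__(self, scaffold_lengths: dict[str, int], dtype=np.int64):
        self.scaffold_lengths = dict(scaffold_lengths)
        self.depth = {
            name: np.zeros(length, dtype=dtype)
            for name, length in scaffold_lengths.items()
        }

    def query(self, scaffold: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end); positions past the scaffold end
        (or before 0) read as depth 0."""
        if end <= start:
            return np.zeros(0, dtype=np.int64)
        arr = self.depth[scaffold]
        out = np.zeros(end - start, dtype=arr.dtype)
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def min_depth(self, scaffold: str, start: int, end: int) -> int:
        v = self.query(scaffold, start, end)
        return int(v.min()) if len(v) else 0

    def add(self, other: "CoverageTrack") -> "CoverageTrack":
        for name, arr in other.depth.items():
            self.depth[name][: len(arr)] += arr
        return self

    @classmethod
    def pooled(cls, tracks: list["CoverageTrack"]) -> "CoverageTrack":
        out = cls(tracks[0].scaffold_lengths)
        for t in tracks:
            out.add(t)
        return out


@dataclass
class Transcript:
    """An assembled transcript: an exon chain linked by accepted junctions.

    ``strand`` is '.' for intron-less transcripts, whose orientation cannot
    be inferred from junction dinucleotides.
    """

    id: str
    scaffold: str
    strand: str
    exons: list[Interval]
    mean_exon_coverage: list[float] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


MODEL_STATUSES = (
    "complete_match",
    "boundary_mismatch",
    "missing_or_extra_intron",
    "fused",
    "split",
    "undetected",
)


@dataclass
class ModelStatus:
    """Outcome of comparing one annotated model against the assembly.

    ``fused``: one transcript spans this model and at least one neighbour
    end-to-end (the models are merged in the corrected annotation).
    ``split``: at least two coverage-separated transcripts lie inside this
    model's span (the model is split in the corrected annotation).
    """

    gene_id: str
    status: str
    transcript_ids: list[str] = field(default_factory=list)


@dataclass
class ASEvent:
    """One classified alternative-splicing event.

    ``ref_introns`` are the annotated intron intervals involved;
    ``alt_interval`` is the alternative junction's intron (alt5/alt3), the
    skipping junction's intron (cassette) or the retained intron itself
    (IR).  ``stage_detected`` maps stage-group name to whether the full
    stringent evidence criteria were met in at least one of its samples.
    """

    gene_id: str
    event_type: str  # 'cassette' | 'alt5' | 'alt3' | 'IR'
    scaffold: str
    ref_introns: tuple[Interval, ...]
    alt_interval: Interval
    stage_detected: dict[str, bool] = field(default_factory=dict)
    ptc: bool | None = None
    mean_as_intron_length: float = 0.0

    @property
    def key(self) -> tuple:
        """Identity of the event (gene, type, coordinates)."""
        return (self.gene_id, self.event_type, self.ref_introns, self.alt_interval)


@dataclass
class IRGeneSummary:
    """Per-gene intron-retention evidence for the specificity table."""

    gene_id: str
    n_introns: int
    #: stage-group -> per-intron retention read counts (5'-most first in
    #: transcript orientation).
    retention_counts: dict[str, list[int]] = field(default_factory=dict)

    def most_retained_frequency(self, group: str) -> float | None:
        counts = self.retention_counts.get(group, [])
        total = sum(counts)
        if total <= 0:
            return None
        return max(counts) / total


@dataclass
class NovelRegion:
    """A transcribed region lying entirely in intergenic space."""

    id: str
    scaffold: str
    start: int
    end: int
    coding: bool
    orf: Interval | None = None
    transcript_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start
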