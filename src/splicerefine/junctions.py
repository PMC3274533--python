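"""Splice-junction validation and filtering.

Acceptance rules for junction evidence: only canonical GT-AG introns (in
transcript orientation) are kept, anchors of at least 8 bp are required on
both sides of the junction, intron lengths must lie within [10, 10000] bp,
and support is counted as non-redundant (distinct alignment span) spliced
reads.  The detection universe uses support >= 1; alternative-splicing
calling later re-filters at support >= 2 per sample.
"""

from __future__ import annotations

import logging

from .genetics import revcomp
from .models import Junction, ValidationError

log = logging.getLogger(__name__)

CANONICAL = ("GT", "AG")


def validate_junction(genome: dict[str, str], j: Junction) -> Junction:
    """Annotate a junction with transcript-orientation terminal
    dinucleotides and the canonical GT-AG flag.

    For a '-' strand junction the genomic CT..AC intron reads GT..AG in
    transcript orientation.  Unstranded junctions have their strand
    inferred from the dinucleotides (GT-AG => '+', CT-AC => '-');
    junctions canonical on neither strand stay unstranded and
    non-canonical.
    """
    try:
        seq = genome[j.scaffold]
    except KeyError:
        raise ValidationError(f"junction {j.id or j.interval}: unknown scaffold {j.scaffold}")
    if j.start < 0 or j.end > len(seq) or j.end <= j.start:
        raise ValidationError(
            f"junction {j.id or ''} {j.scaffold}:{j.start}-{j.end}: interval out of bounds"
        )
    left = seq[j.start : j.start + 2]
    right = seq[j.end - 2 : j.end]

    out = j.copy()
    if j.strand == ".":
        if (left, right) == CANONICAL:
            out.strand = "+"
        elif (revcomp(right), revcomp(left)) == CANONICAL:
            out.strand = "-"
        else:
            log.info(
                "junction %s %s:%d-%d is canonical on neither strand; left unstranded",
                j.id or "", j.scaffold, j.start, j.end,
            )
    if out.strand == "-":
        out.donor_dinuc, out.acceptor_dinuc = revcomp(right), revcomp(left)
    else:
        out.donor_dinuc, out.acceptor_dinuc = left, right
    out.canonical = (out.donor_dinuc, out.acceptor_dinuc) == CANONICAL
    return out


def count_nonredundant(spans) -> int:
    """Number of distinct (start, end) alignment spans over a junction.

    'Non-redundant' deduplicates by alignment span, which is robust to PCR
    duplicates and computable from alignment-level evidence.
    """
    return len({(int(s), int(e)) for s, e in spans})


def filter_junctions(
    junctions: list[Junction],
    min_anchor: int = 8,
    min_support: int = 1,
    min_intron: int = 10,
    max_intron: int = 10000,
) -> list[Junction]:
    """Keep only canonical junctions meeting all evidence thresholds.

    ``min_support`` applies to the summed non-redundant support across
    samples.  The operation is idempotent and monotone in every threshold.
    """
    kept = []
    for j in junctions:
        if j.canonical is not True:
            continue
        if j.min_anchor < min_anchor:
            continue
        if not (min_intron <= j.length <= max_intron):
            continue
        if j.total_support < min_support:
            continue
        kept.append(j)
    return kept


def validate_and_filter(
    genome: dict[str, str], junctions: list[Junction], **thresholds
) -> list[Junction]:
    """Convenience wrapper: validate then filter, logging the attrition."""
    validated = [validate_junction(genome, j) for j in junctions]
    kept = filter_junctions(validated, **thresholds)
    dropped = len(validated) - len(kept)
    if dropped:
        log.info("junction filtering dropped %d of %d records", dropped, len(validated))
    return kept
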