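"""Independent brute-force oracles used by the splicing tests.

These re-derive the event classification by exhaustive enumeration over
all junction pairs and triples, written independently of the library's
grouped/indexed implementation.
"""

from itertools import combinations


def brute_force_events(gene, junctions, covs_min_depth, min_spliced=2, min_depth=10):
    """Exhaustively enumerate AS events for one gene.

    ``junctions``: list of (interval, support) with support an int (single
    condition).  ``covs_min_depth``: dict interval -> minimum per-base depth
    over that intron.  Returns a set of (type, frozenset of intervals).
    """
    strand = gene.strand
    introns = [tuple(iv) for iv in gene.introns]
    internal_exons = {tuple(e) for e in gene.exons[1:-1]}
    js = [(tuple(iv), s) for iv, s in junctions if s >= min_spliced]
    jset = {iv for iv, _ in js}

    events = set()
    suppressed = set()
    # cassette triples
    for (j1, _), (j2, _) in combinations(sorted(js), 2):
        if j1[1] < j2[0] and (j1[1], j2[0]) in internal_exons:
            skip = (j1[0], j2[1])
            if skip in jset:
                events.add(("cassette", frozenset((j1, j2, skip))))
                suppressed.add(frozenset((j1, skip)))
                suppressed.add(frozenset((j2, skip)))
    # alt5 / alt3 pairs
    for (j1, _), (j2, _) in combinations(sorted(js), 2):
        if frozenset((j1, j2)) in suppressed:
            continue
        if strand == "+":
            five1, three1 = j1[0], j1[1]
            five2, three2 = j2[0], j2[1]
        else:
            five1, three1 = j1[1], j1[0]
            five2, three2 = j2[1], j2[0]
        if three1 == three2 and five1 != five2:
            events.add(("alt5", frozenset((j1, j2))))
        elif five1 == five2 and three1 != three2:
            events.add(("alt3", frozenset((j1, j2))))
    # intron retention
    for iv in introns:
        if iv in jset and covs_min_depth.get(iv, 0) >= min_depth:
            events.add(("IR", frozenset((iv,))))
    return events
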