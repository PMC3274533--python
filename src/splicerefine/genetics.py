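"""Ciliate genetic code and small sequence utilities.

Tetrahymena (like most ciliates) uses nuclear translation table 6: the
canonical stop codons TAA and TAG are reassigned to glutamine, leaving TGA
as the only stop codon.  All ORF and premature-termination-codon logic in
this package therefore treats TGA as the sole stop.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = "TCAG"
_STANDARD_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
STANDARD_CODE = dict(zip(CODONS, _STANDARD_AA))

#: NCBI translation table 6 (ciliate nuclear): TAA/TAG -> Gln, TGA = stop.
CILIATE_CODE = {**STANDARD_CODE, "TAA": "Q", "TAG": "Q"}
STOP_CODONS = frozenset(c for c, aa in CILIATE_CODE.items() if aa == "*")
START_CODON = "ATG"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, to_stop: bool = True) -> str:
    """Translate ``seq`` under the ciliate nuclear code.

    Incomplete trailing codons are dropped.  With ``to_stop`` the protein
    ends at (and excludes) the first TGA.
    """
    aas = []
    for i in range(0, len(seq) - 2, 3):
        aa = CILIATE_CODE.get(seq[i : i + 3].upper(), "X")
        if aa == "*" and to_stop:
            break
        aas.append(aa)
    return "".join(aas)


def first_inframe_stop(seq: str, start: int = 0) -> int | None:
    """Transcript position of the first in-frame TGA at or after ``start``.

    Returns the 0-based position of the stop codon's first base, or None.
    """
    s = seq.upper()
    for i in range(start, len(s) - 2, 3):
        if s[i : i + 3] in STOP_CODONS:
            return i
    return None


def find_orfs(seq: str, min_codons: int = 50) -> list[tuple[int, int]]:
    """All complete ORFs (ATG..TGA, ciliate code) on the forward strand.

    Returns ``(start, end)`` half-open intervals including the stop codon,
    for ORFs of at least ``min_codons`` codons (stop included), longest
    first; ties broken by leftmost start.
    """
    s = seq.upper()
    orfs = []
    for frame in range(3):
        start = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if start is None:
                if codon == START_CODON:
                    start = i
            elif codon in STOP_CODONS:
                if (i + 3 - start) // 3 >= min_codons:
                    orfs.append((start, i + 3))
                start = None
    orfs.sort(key=lambda o: (-(o[1] - o[0]), o[0]))
    return orfs


def longest_orf(seq: str, min_codons: int = 50) -> tuple[int, int] | None:
    """Longest complete forward-strand ORF, or None if none reaches
    ``min_codons``."""
    orfs = find_orfs(seq, min_codons=min_codons)
    return orfs[0] if orfs else None


def longest_orf_either_strand(
    seq: str, min_codons: int = 50
) -> tuple[tuple[int, int], str] | None:
    """Longest ORF on either strand; returns (interval on given seq, strand)."""
    fwd = longest_orf(seq, min_codons)
    rev = longest_orf(revcomp(seq), min_codons)
    best = None
    if fwd:
        best = (fwd, "+")
    if rev:
        n = len(seq)
        rev_on_fwd = (n - rev[1], n - rev[0])
        if best is None or (rev[1] - rev[0]) > (best[0][1] - best[0][0]):
            best = (rev_on_fwd, "-")
    return best
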