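"""Expression quantification and cross-platform analysis.

RPKM (reads per kilobase of exon model per million mapped reads) is the
expression unit throughout; stage-specific up-regulation uses a two-rule
call (max stage RPKM > 5 and >= 5-fold over every other stage).
Microarray probes are reassigned to corrected gene models and per-gene
values renormalized as the median over member probes.  GO term enrichment
is a hypergeometric upper tail with Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import Annotation, STAGE_GROUPS

log = logging.getLogger(__name__)


def compute_rpkm(count: float, exon_len: int, total: float) -> float:
    """RPKM = 1e9 * count / (exon_len * total mapped reads)."""
    if total <= 0:
        raise ValueError("total mapped reads must be positive")
    if exon_len <= 0:
        raise ValueError("exon length must be positive")
    return 1e9 * count / (exon_len * total)


def rpkm_matrix(counts: pd.DataFrame, exon_lengths: pd.Series, totals: pd.Series) -> pd.DataFrame:
    """Per-gene x per-sample RPKM from a count matrix."""
    lengths = exon_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"genes without exon length: {missing}")
    out = counts.astype(float).copy()
    for sample in counts.columns:
        out[sample] = 1e9 * counts[sample] / (lengths * float(totals[sample]))
    return out


def stage_rpkm(rpkm: pd.DataFrame, groups: dict[str, tuple[str, ...]] = STAGE_GROUPS) -> pd.DataFrame:
    """Stage-level RPKM as the arithmetic mean over a stage's samples."""
    return pd.DataFrame(
        {g: rpkm[list(members)].mean(axis=1) for g, members in groups.items()}
    )


def call_stage_upregulated(
    stage_vals: pd.DataFrame, min_rpkm: float = 5.0, min_fold: float = 5.0
) -> dict[str, list[str]]:
    """Genes specifically up-regulated in one stage.

    A gene is stage-X-specific iff its stage-X RPKM exceeds ``min_rpkm``
    and is at least ``min_fold`` times the RPKM of every other stage (zero
    denominators count as satisfied when the numerator is positive).  The
    resulting sets are pairwise disjoint by construction.
    """
    out: dict[str, list[str]] = {}
    vals = stage_vals.to_numpy(dtype=float)
    genes = stage_vals.index.to_numpy()
    for k, stage in enumerate(stage_vals.columns):
        x = vals[:, k]
        others = np.delete(vals, k, axis=1)
        with np.errstate(invalid="ignore"):
            dominant = np.all(x[:, None] >= min_fold * others, axis=1) & (x > 0)
        called = (x > min_rpkm) & dominant
        out[str(stage)] = sorted(genes[called].tolist())
    return out


# ----------------------------------------------------------- microarray


def reassign_and_renormalize(
    probes: pd.DataFrame,
    corrected: Annotation,
    samples: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each probe to the unique corrected gene whose exon union
    contains it, then renormalize per-gene expression as the median of the
    member probes' intensities, per sample.

    Returns ``(per-gene renormalized values, probe assignment table)``.
    Probes contained in no gene, or in two overlapping genes, are dropped
    with a log entry.
    """
    assignments = []
    models = corrected.sorted_models()
    by_scaffold: dict[str, list] = {}
    for m in models:
        by_scaffold.setdefault(m.scaffold, []).append(m)
    for _, p in probes.iterrows():
        hits = []
        for m in by_scaffold.get(p["scaffold"], []):
            if any(s <= p["start"] and p["end"] <= e for s, e in m.exons):
                hits.append(m.id)
        if len(hits) == 1:
            assignments.append({"probe_id": p["probe_id"], "gene_id": hits[0]})
        elif not hits:
            log.info("probe %s contained in no corrected gene; dropped", p["probe_id"])
        else:
            log.info("probe %s contained in %d genes; unassigned", p["probe_id"], len(hits))
    assign = pd.DataFrame(assignments, columns=["probe_id", "gene_id"])
    merged = probes.merge(assign, on="probe_id")
    values = merged.groupby("gene_id")[list(samples)].median()
    return values, assign


def correlate_platforms(rpkm: pd.Series, array_log2: pd.Series) -> float:
    """Pearson r between log2(RPKM + 1) and microarray log2 intensities over
    the genes shared by both platforms."""
    shared = rpkm.index.intersection(array_log2.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes for correlation")
    x = np.log2(rpkm.loc[shared].to_numpy(dtype=float) + 1.0)
    y = array_log2.loc[shared].to_numpy(dtype=float)
    r, _ = stats.pearsonr(x, y)
    return float(r)


# ----------------------------------------------------------- enrichment


@dataclass
class EnrichmentResult:
    term: str
    k: int  # test-set genes with the term
    K: int  # universe genes with the term
    n: int  # test-set size
    N: int  # universe size
    p_raw: float
    p_corrected: float
    significant: bool


def go_enrichment(
    test_set,
    universe: dict[str, set[str]],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of GO terms in a gene set.

    ``universe`` maps gene id -> set of term ids.  The raw p-value is the
    hypergeometric upper tail P(X >= k); Bonferroni multiplies by the
    number of terms with at least one test-set gene, and a term is
    significant when the corrected p is below ``alpha``.
    """
    if not universe:
        raise ValueError("empty universe")
    test = set(test_set)
    if not test <= set(universe):
        raise ValueError("test set must be a subset of the universe")
    N = len(universe)
    n = len(test)
    term_genes: dict[str, set[str]] = {}
    for g, terms in universe.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(g)
    tested = {
        t: genes for t, genes in term_genes.items() if genes & test
    }
    m = len(tested)
    out = []
    for term in sorted(tested):
        genes = term_genes[term]
        K, k = len(genes), len(genes & test)
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_corr = min(1.0, p_raw * m)
        out.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N,
                p_raw=p_raw, p_corrected=p_corr,
                significant=bool(p_corr < alpha),
            )
        )
    out.sort(key=lambda r: (r.p_corrected, r.term))
    return out
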