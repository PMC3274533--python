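"""Assembly, model comparison, novel regions and UTR inference."""

import numpy as np
import pytest

from splicerefine.models import (
    Annotation,
    CoverageTrack,
    GeneModel,
    Junction,
    Transcript,
)
from splicerefine.refine import (
    assemble_transcripts,
    compare_to_annotation,
    detect_novel_regions,
    infer_utrs,
)


def _track(length=2000, segments=()):
    t = CoverageTrack({"scf": length})
    for s, e, d in segments:
        t.depth["scf"][s:e] = d
    return t


def _junction(start, end, strand="+", support=5):
    return Junction(
        scaffold="scf", start=start, end=end, strand=strand,
        support={"G-m": support}, min_anchor=10, canonical=True,
    )


class TestAssembly:
    def test_junction_links_two_islands_into_one_transcript(self):
        cov = _track(segments=[(0, 50, 5), (100, 150, 5)])
        ts = assemble_transcripts(cov, [_junction(50, 100)])
        assert len(ts) == 1
        assert ts[0].exons == [(0, 50), (100, 150)]
        assert ts[0].strand == "+"

    def test_without_junction_two_single_exon_transcripts(self):
        cov = _track(segments=[(0, 50, 5), (100, 150, 5)])
        ts = assemble_transcripts(cov, [])
        assert [t.exons for t in ts] == [[(0, 50)], [(100, 150)]]
        assert all(t.strand == "." for t in ts)

    def test_short_gap_bridged_only_without_junction_evidence(self):
        cov = _track(segments=[(0, 50, 5), (60, 110, 5)])
        bridged = assemble_transcripts(cov, [])
        assert [t.exons for t in bridged] == [[(0, 110)]]
        spliced = assemble_transcripts(cov, [_junction(50, 60)])
        assert [t.exons for t in spliced] == [[(0, 50), (60, 110)]]

    def test_retained_intron_yields_both_isoform_paths(self):
        cov = _track(segments=[(0, 150, 20)])
        ts = assemble_transcripts(cov, [_junction(50, 100)])
        chains = sorted(tuple(t.exons) for t in ts)
        assert ((0, 150),) in chains
        assert ((0, 50), (100, 150)) in chains

    def test_planted_chains_recovered_exactly(self, sim_clean, result_clean):
        truth = sim_clean.truth
        chains = {
            (t.scaffold, tuple(t.introns)) for t in result_clean.transcripts
        }
        for tg in truth.genes.values():
            m = tg.model
            assert (m.scaffold, tuple(m.introns)) in chains


class TestModelComparison:
    def test_exact_intron_chain_is_complete_match(self):
        ann = Annotation(
            {"g": GeneModel("g", "scf", "+", [(10, 50), (100, 150)], (10, 150))},
            {"scf": 2000},
        )
        ts = [Transcript("T1", "scf", "+", [(0, 50), (100, 160)])]
        statuses, corrected = compare_to_annotation(ts, ann)
        assert statuses["g"].status == "complete_match"
        assert corrected.models["g"].exons == [(10, 50), (100, 150)]

    def test_one_transcript_spanning_two_models_fuses_them(self):
        ann = Annotation(
            {
                "a": GeneModel("a", "scf", "+", [(10, 50)], (10, 50)),
                "b": GeneModel("b", "scf", "+", [(100, 150)], (100, 150)),
            },
            {"scf": 2000},
        )
        ts = [Transcript("T1", "scf", "+", [(0, 50), (100, 160)])]
        statuses, corrected = compare_to_annotation(ts, ann)
        assert statuses["a"].status == statuses["b"].status == "fused"
        assert set(corrected.models) == {"a--b"}
        assert corrected.models["a--b"].exons == [(0, 50), (100, 160)]

    def test_two_coverage_separated_transcripts_split_the_model(self):
        ann = Annotation(
            {"g": GeneModel("g", "scf", "+", [(0, 400)], (0, 400))},
            {"scf": 2000},
        )
        cov = _track(segments=[(0, 150, 5), (230, 400, 5)])
        ts = [
            Transcript("T1", "scf", ".", [(0, 150)]),
            Transcript("T2", "scf", ".", [(230, 400)]),
        ]
        statuses, corrected = compare_to_annotation(ts, ann, zero_gap=50, cov=cov)
        assert statuses["g"].status == "split"
        assert set(corrected.models) == {"g.s1", "g.s2"}

    def test_gap_below_zero_gap_threshold_does_not_split(self):
        ann = Annotation(
            {"g": GeneModel("g", "scf", "+", [(0, 400)], (0, 400))},
            {"scf": 2000},
        )
        cov = _track(segments=[(0, 150, 5), (180, 400, 5)])
        ts = [
            Transcript("T1", "scf", ".", [(0, 150)]),
            Transcript("T2", "scf", ".", [(180, 400)]),
        ]
        statuses, _ = compare_to_annotation(ts, ann, zero_gap=50, cov=cov)
        assert statuses["g"].status != "split"

    def test_planted_defects_get_the_expected_statuses(self, sim_small, result_small):
        truth = sim_small.truth
        st = result_small.statuses
        for mid in truth.merged_defects:
            assert st[mid].status == "split"
        for gid, (a, b) in truth.split_defects.items():
            assert st[a].status == st[b].status == "fused"
        for gid in truth.boundary_defects:
            assert st[gid].status == "boundary_mismatch"
        for gid in truth.intron_defects:
            assert st[gid].status == "missing_or_extra_intron"

    def test_clean_high_coverage_run_confirms_every_model(self, result_clean):
        assert all(
            s.status == "complete_match" for s in result_clean.statuses.values()
        )


class TestNovelRegions:
    def _ann(self):
        return Annotation(
            {"g": GeneModel("g", "scf", "+", [(5000, 5500)], (5000, 5500))},
            {"scf": 20_000},
        )

    def test_long_intergenic_transcript_reported(self):
        ts = [Transcript("T1", "scf", ".", [(1000, 1918)])]
        novel = detect_novel_regions(ts, self._ann())
        assert len(novel) == 1 and novel[0].length == 918

    def test_short_intergenic_transcript_rejected(self):
        ts = [Transcript("T1", "scf", ".", [(1000, 1250)])]
        assert detect_novel_regions(ts, self._ann()) == []

    def test_one_bp_overlap_with_annotated_exon_rejected(self):
        ts = [Transcript("T1", "scf", ".", [(4601, 5001)])]
        assert detect_novel_regions(ts, self._ann()) == []

    def test_planted_novel_regions_recovered(self, sim_small, result_small):
        truth = sim_small.truth
        expected = {
            (n.scaffold, n.start, n.end)
            for n in truth.novels
            if n.length >= 300
        }
        found = {(n.scaffold, n.start, n.end) for n in result_small.novel}
        assert found == expected

    def test_coding_flag_matches_planted_orfs(self, sim_small, result_small):
        truth_by_span = {
            (n.scaffold, n.start, n.end): n.coding for n in sim_small.truth.novels
        }
        for n in result_small.novel:
            assert n.coding == truth_by_span[(n.scaffold, n.start, n.end)]


class TestUTRs:
    def test_coverage_past_stop_becomes_utr3(self):
        ann = Annotation(
            {"g": GeneModel("g", "scf", "+", [(500, 800)], (500, 800))},
            {"scf": 2000},
        )
        cov = _track(segments=[(500, 920, 6)])
        infer_utrs(cov, ann)
        m = ann.models["g"]
        assert m.utr3 == (800, 920)
        assert m.utr3[1] - m.utr3[0] == 120
        assert m.utr5 is None

    def test_zero_coverage_outside_cds_gives_no_utr(self):
        ann = Annotation(
            {"g": GeneModel("g", "scf", "+", [(500, 800)], (500, 800))},
            {"scf": 2000},
        )
        cov = _track(segments=[(500, 800, 6)])
        infer_utrs(cov, ann)
        assert ann.models["g"].utr5 is None and ann.models["g"].utr3 is None

    def test_simulated_utr_lengths_recovered_exactly(self, sim_clean, result_clean):
        truth = sim_clean.truth
        for gid, tg in truth.genes.items():
            m = result_clean.corrected.models[gid]
            assert m.utr5 == tg.utr5, gid
            assert m.utr3 == tg.utr3, gid
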