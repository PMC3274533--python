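"""AS event classification, PTC scanning and IR statistics."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from helpers_oracle import brute_force_events
from splicerefine.models import ASEvent, CoverageTrack, GeneModel, Junction
from splicerefine.splicing import (
    as_intron_mean_length,
    detect_intron_retention,
    enumerate_as_events,
    event_ptc,
    ir_specificity,
    ir_weighted_average,
    scan_ptc,
    stage_specific_as,
)

GROUPS = {"growth": ("G-m",), "conjugation": ("C-2",)}


def _gene(exons, strand="+", gid="g"):
    span = (exons[0][0], exons[-1][1])
    return GeneModel(gid, "scf", strand, exons, span)


def _j(start, end, support, strand="+"):
    if isinstance(support, int):
        support = {"G-m": support, "C-2": support}
    return Junction(scaffold="scf", start=start, end=end, strand=strand,
                    support=support, min_anchor=10, canonical=True)


def _cov(length=2000, segments=(), sample="G-m"):
    t = CoverageTrack({"scf": length})
    for s, e, d in segments:
        t.depth["scf"][s:e] = d
    return {sample: t, "C-2": CoverageTrack({"scf": length})}


class TestClassification:
    def test_shared_donor_differing_acceptors_is_alt3(self):
        gene = _gene([(50, 100), (200, 260), (320, 400)])
        js = [_j(100, 200, 5), _j(100, 230, 5)]
        events = enumerate_as_events(js, _cov(), gene, groups=GROUPS)
        assert [e.event_type for e in events] == ["alt3"]
        assert events[0].ref_introns == ((100, 200),)
        assert events[0].alt_interval == (100, 230)

    def test_shared_acceptor_differing_donors_is_alt5(self):
        gene = _gene([(50, 100), (200, 260), (320, 400)])
        js = [_j(100, 200, 5), _j(130, 200, 5)]
        events = enumerate_as_events(js, _cov(), gene, groups=GROUPS)
        assert [e.event_type for e in events] == ["alt5"]

    def test_strand_flips_the_alt5_alt3_labels(self):
        gene = _gene([(50, 100), (200, 260), (320, 400)], strand="-")
        js = [_j(100, 200, 5, "-"), _j(100, 230, 5, "-")]
        events = enumerate_as_events(js, _cov(), gene, groups=GROUPS)
        assert [e.event_type for e in events] == ["alt5"]

    def test_cassette_needs_all_three_junctions_and_the_annotated_exon(self):
        gene = _gene([(50, 100), (200, 250), (350, 400)])
        js = [_j(100, 200, 5), _j(250, 350, 5), _j(100, 350, 5)]
        events = enumerate_as_events(js, _cov(), gene, groups=GROUPS)
        assert [e.event_type for e in events] == ["cassette"]
        assert events[0].ref_introns == ((100, 200), (250, 350))
        assert events[0].alt_interval == (100, 350)

    def test_cassette_pairs_not_double_reported_as_alt_events(self):
        gene = _gene([(50, 100), (200, 250), (350, 400)])
        js = [_j(100, 200, 5), _j(250, 350, 5), _j(100, 350, 5)]
        events = enumerate_as_events(js, _cov(), gene, groups=GROUPS)
        assert len(events) == 1

    def test_junction_below_support_threshold_ignored(self):
        gene = _gene([(50, 100), (200, 260)])
        js = [_j(100, 200, 5), _j(100, 230, 1)]
        assert enumerate_as_events(js, _cov(), gene, groups=GROUPS) == []


class TestIntronRetention:
    def test_full_depth_with_spliced_support_is_ir(self):
        cov = CoverageTrack({"scf": 500})
        cov.depth["scf"][100:200] = 12
        assert detect_intron_retention((100, 200), cov, "scf", spliced_support=5)

    def test_single_shallow_base_defeats_ir(self):
        cov = CoverageTrack({"scf": 500})
        cov.depth["scf"][100:200] = 50
        cov.depth["scf"][150] = 9
        assert not detect_intron_retention((100, 200), cov, "scf", spliced_support=5)

    def test_unspliced_covered_intron_is_not_as(self):
        cov = CoverageTrack({"scf": 500})
        cov.depth["scf"][100:200] = 50
        assert not detect_intron_retention((100, 200), cov, "scf", spliced_support=0)


class TestOracleEquivalence:
    def test_classifier_matches_exhaustive_enumeration(self, rng):
        """Random toy genes with <=4 introns and <=6 candidate junctions."""
        for _ in range(300):
            n_introns = int(rng.integers(1, 5))
            exons = []
            pos = 50
            for _ in range(n_introns + 1):
                exons.append((pos, pos + int(rng.integers(40, 90))))
                pos = exons[-1][1] + int(rng.integers(40, 90))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _gene(exons, strand=strand)
            introns = gene.introns

            candidates = [tuple(iv) for iv in introns]
            for a, b in introns:
                candidates.append((a + int(rng.integers(4, 20)), b))
                candidates.append((a, b - int(rng.integers(4, 20))))
            for i in range(len(introns) - 1):
                candidates.append((introns[i][0], introns[i + 1][1]))
            k = int(rng.integers(0, 7))
            chosen_idx = rng.choice(len(candidates), size=min(k, len(candidates)), replace=False)
            chosen = [candidates[i] for i in chosen_idx]
            support = {iv: int(rng.integers(0, 6)) for iv in chosen}

            cov = CoverageTrack({"scf": exons[-1][1] + 100})
            depths = {}
            for iv in introns:
                d = int(rng.integers(0, 25))
                cov.depth["scf"][iv[0]:iv[1]] = d
                depths[tuple(iv)] = d

            js = [_j(a, b, {"G-m": s}, strand) for (a, b), s in support.items()]
            events = enumerate_as_events(
                js, {"G-m": cov}, gene, groups={"growth": ("G-m",)},
            )
            got = set()
            for e in events:
                if e.event_type == "cassette":
                    got.add(("cassette", frozenset((*e.ref_introns, e.alt_interval))))
                elif e.event_type == "IR":
                    got.add(("IR", frozenset((e.alt_interval,))))
                else:
                    got.add((e.event_type, frozenset((e.ref_introns[0], e.alt_interval))))
            expected = brute_force_events(
                gene, [(iv, s) for iv, s in support.items()], depths,
            )
            assert got == expected


class TestPTC:
    def test_early_inframe_tga_is_ptc(self):
        seq = "ATG" + "AAA" * 10 + "TGA" + "AAA" * 20 + "TGA"
        assert scan_ptc(seq, 0) is True

    def test_taa_is_glutamine_not_stop(self):
        seq = "ATG" + "TAA" * 10 + "TGA"
        assert scan_ptc(seq, 0) is False

    @given(st.integers(0, 2**31 - 1))
    def test_matches_ciliate_table_translation(self, seed):
        """scan_ptc agrees with full translation under NCBI table 6."""
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 60))
        codons = ["ATG"] + [
            "".join(r.choice(list("ACGT"), size=3)) for _ in range(n)
        ] + ["TGA"]
        seq = "".join(codons)
        protein = str(Seq(seq).translate(table=6, to_stop=True))
        # premature iff translation stops before the final codon
        expected = len(protein) < len(codons) - 1
        assert scan_ptc(seq, 0) == expected

    def test_detected_event_ptc_flags_match_planted_truth(self, sim_recovery, result_recovery):
        truth_ptc = {e.key: e.ptc for e in sim_recovery.truth.events}
        checked = 0
        for e in result_recovery.events:
            if e.key in truth_ptc and e.ptc is not None:
                assert e.ptc == truth_ptc[e.key], e.key
                checked += 1
        assert checked >= 10


class TestLengthsAndSpecificity:
    def test_ir_mean_length_is_the_intron_length(self):
        e = ASEvent("g", "IR", "scf", ((100, 180),), (100, 180))
        assert as_intron_mean_length(e) == 80

    def test_alt5_mean_of_two_introns(self):
        e = ASEvent("g", "alt5", "scf", ((0, 150),), (0, 226))
        assert as_intron_mean_length(e) == 188

    def test_cassette_mean_of_three_introns(self):
        e = ASEvent("g", "cassette", "scf", ((0, 100), (150, 270)), (0, 300))
        assert as_intron_mean_length(e) == pytest.approx(173.33, abs=0.01)

    def test_specificity_examples(self):
        assert ir_specificity([9, 1]) == 0.9
        assert ir_specificity([5]) == 1.0
        with pytest.raises(ValueError):
            ir_specificity([0, 0])

    @given(st.lists(st.integers(0, 100), min_size=1).filter(lambda c: sum(c) > 0))
    def test_specificity_equals_max_over_sum(self, counts):
        assert ir_specificity(counts) == max(counts) / sum(counts)

    def test_weighted_average_single_category(self):
        assert ir_weighted_average([7], [0.83]) == 0.83

    def test_weighted_average_length_mismatch(self):
        with pytest.raises(ValueError):
            ir_weighted_average([1, 2], [0.5])


class TestStageSpecific:
    def test_single_group_event_is_stage_specific(self):
        e = ASEvent("g", "IR", "scf", ((0, 50),), (0, 50),
                    stage_detected={"growth": False, "starvation": False,
                                    "conjugation": True})
        assert stage_specific_as([e]) == [e]

    def test_two_group_event_is_not(self):
        e = ASEvent("g", "IR", "scf", ((0, 50),), (0, 50),
                    stage_detected={"growth": True, "starvation": False,
                                    "conjugation": True})
        assert stage_specific_as([e]) == []

    def test_planted_stage_restricted_events_recovered(self, sim_recovery, result_recovery):
        truth = sim_recovery.truth
        expected = truth.stage_specific_event_keys()
        got = {e.key for e in result_recovery.stage_specific_events}
        assert got == expected
        # and the detected group matches the planted one
        planted_group = {
            e.key: e.stage_group for e in truth.events if e.stage_group
        }
        for e in result_recovery.stage_specific_events:
            (group,) = [g for g, v in e.stage_detected.items() if v]
            assert group == planted_group[e.key]
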