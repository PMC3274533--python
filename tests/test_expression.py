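"""RPKM, stage-specific calls, probe renormalization, correlation, GO."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicerefine.expression import (
    call_stage_upregulated,
    compute_rpkm,
    correlate_platforms,
    go_enrichment,
    reassign_and_renormalize,
)
from splicerefine.models import Annotation, GeneModel


class TestRPKM:
    def test_closed_form_example(self):
        assert compute_rpkm(100, 2000, 5_000_000) == 10.0

    def test_zero_count_is_zero(self):
        assert compute_rpkm(0, 2000, 5_000_000) == 0.0

    @given(
        st.integers(0, 10**6),
        st.integers(1, 10**5),
        st.integers(1, 10**9),
    )
    def test_matches_independent_closed_form(self, count, length, total):
        expected = (count / total * 1e6) / (length / 1e3)  # per-million, per-kb
        got = compute_rpkm(count, length, total)
        assert got == pytest.approx(expected, rel=1e-9)

    @given(st.integers(1, 10**5), st.integers(1, 10**4), st.integers(1, 10**7),
           st.integers(2, 50))
    def test_invariant_under_joint_scaling(self, count, length, total, lam):
        a = compute_rpkm(count, length, total)
        b = compute_rpkm(lam * count, length, lam * total)
        assert b == pytest.approx(a, rel=1e-9)

    def test_zero_total_or_length_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(10, 100, 0)
        with pytest.raises(ValueError):
            compute_rpkm(10, 0, 100)


class TestStageCalls:
    def _vals(self, g, s, c):
        return pd.DataFrame(
            {"growth": [g], "starvation": [s], "conjugation": [c]}, index=["gene"]
        )

    def test_sixfold_dominant_gene_called(self):
        up = call_stage_upregulated(self._vals(30, 5, 5))
        assert up["growth"] == ["gene"] and up["starvation"] == []

    def test_max_rpkm_must_exceed_five(self):
        up = call_stage_upregulated(self._vals(4.9, 0.1, 0.1))
        assert all(v == [] for v in up.values())

    def test_fold_below_five_not_called(self):
        up = call_stage_upregulated(self._vals(25, 6, 1))
        assert all(v == [] for v in up.values())

    def test_zero_denominator_counts_as_infinite_fold(self):
        up = call_stage_upregulated(self._vals(30, 0, 0))
        assert up["growth"] == ["gene"]

    def test_stage_sets_are_pairwise_disjoint(self, result_recovery):
        sets = [set(v) for v in result_recovery.stage_up.values()]
        for a, b in combinations(sets, 2):
            assert not (a & b)

    def test_raising_min_fold_shrinks_the_sets(self, result_recovery):
        vals = result_recovery.stage_vals
        prev = None
        for fold in (2, 5, 10, 25):
            up = call_stage_upregulated(vals, min_fold=fold)
            flat = {g for v in up.values() for g in v}
            if prev is not None:
                assert flat <= prev
            prev = flat


class TestRenormalization:
    def test_probes_sorted_to_split_genes_get_separate_medians(self):
        ann = Annotation(
            {
                "A": GeneModel("A", "scf", "+", [(0, 200)], (0, 200)),
                "B": GeneModel("B", "scf", "+", [(500, 700)], (500, 700)),
            },
            {"scf": 1000},
        )
        rows = []
        for i in range(3):
            rows.append({"probe_id": f"p{i}", "scaffold": "scf",
                         "start": 10 + 50 * i, "end": 40 + 50 * i, "G-m": 2.0 + i})
        for i in range(3):
            rows.append({"probe_id": f"q{i}", "scaffold": "scf",
                         "start": 510 + 50 * i, "end": 540 + 50 * i, "G-m": 7.0 + i})
        probes = pd.DataFrame(rows)
        values, assign = reassign_and_renormalize(probes, ann, ["G-m"])
        assert values.loc["A", "G-m"] == 3.0  # median(2,3,4)
        assert values.loc["B", "G-m"] == 8.0  # median(7,8,9)

    def test_single_probe_gene_median_is_that_probe(self):
        ann = Annotation(
            {"A": GeneModel("A", "scf", "+", [(0, 200)], (0, 200))}, {"scf": 1000}
        )
        probes = pd.DataFrame(
            [{"probe_id": "p", "scaffold": "scf", "start": 10, "end": 40, "G-m": 5.5}]
        )
        values, _ = reassign_and_renormalize(probes, ann, ["G-m"])
        assert values.loc["A", "G-m"] == 5.5

    def test_unplaceable_probe_dropped(self):
        ann = Annotation(
            {"A": GeneModel("A", "scf", "+", [(0, 200)], (0, 200))}, {"scf": 1000}
        )
        probes = pd.DataFrame(
            [{"probe_id": "p", "scaffold": "scf", "start": 400, "end": 440, "G-m": 5.5}]
        )
        values, assign = reassign_and_renormalize(probes, ann, ["G-m"])
        assert len(values) == 0 and len(assign) == 0


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = pd.Series([1.0, 3.0, 7.0, 15.0], index=list("abcd"))
        y = pd.Series(np.log2(x + 1) * 2, index=list("abcd"))
        assert correlate_platforms(x, y) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = pd.Series([1.0, 3.0, 7.0, 15.0], index=list("abcd"))
        y = pd.Series(-np.log2(x + 1), index=list("abcd"))
        assert correlate_platforms(x, y) == pytest.approx(-1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_covariance_formula(self, seed):
        r = np.random.default_rng(seed)
        x = pd.Series(r.uniform(0, 100, size=20), index=range(20))
        y = pd.Series(r.normal(size=20), index=range(20))
        lx = np.log2(x.to_numpy() + 1)
        ly = y.to_numpy()
        expected = (
            ((lx - lx.mean()) * (ly - ly.mean())).sum()
            / np.sqrt(((lx - lx.mean()) ** 2).sum() * ((ly - ly.mean()) ** 2).sum())
        )
        assert correlate_platforms(x, y) == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_three_shared_genes_rejected(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            correlate_platforms(x, x)


class TestEnrichment:
    UNIVERSE = {
        **{f"g{i}": {"T"} for i in range(5)},
        **{f"g{i}": set() for i in range(5, 10)},
    }

    def test_raw_p_matches_exhaustive_enumeration(self):
        (res,) = go_enrichment(["g0", "g1"], self.UNIVERSE)
        # oracle: fraction of all 2-subsets of the 10-gene universe with
        # both members carrying the term
        hits = sum(
            1
            for pair in combinations(sorted(self.UNIVERSE), 2)
            if all("T" in self.UNIVERSE[g] for g in pair)
        )
        total = len(list(combinations(range(10), 2)))
        assert res.p_raw == pytest.approx(hits / total)
        assert res.p_raw == pytest.approx(0.2222, abs=1e-4)

    def test_absent_term_upper_tail_is_one(self):
        universe = {**self.UNIVERSE, "g10": {"U"}}
        res = go_enrichment(["g10"], universe)
        by_term = {r.term: r for r in res}
        assert "T" not in by_term  # no test-set gene carries T
        assert by_term["U"].p_raw <= 1.0

    def test_bonferroni_with_one_term_is_identity(self):
        (res,) = go_enrichment(["g0", "g1"], self.UNIVERSE)
        assert res.p_corrected == res.p_raw

    def test_corrected_p_never_below_raw(self, sim_recovery, result_recovery):
        for res in result_recovery.enrichment.values():
            for r in res:
                assert r.p_corrected >= r.p_raw

    def test_significance_set_shrinks_with_alpha(self):
        universe = {f"g{i}": ({"T"} if i < 8 else {"U"}) for i in range(40)}
        test = [f"g{i}" for i in range(8)]
        strict = {r.term for r in go_enrichment(test, universe, alpha=1e-6) if r.significant}
        loose = {r.term for r in go_enrichment(test, universe, alpha=0.05) if r.significant}
        assert strict <= loose

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment([], {})
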