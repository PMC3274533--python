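"""Synthetic-data generator: statistical targets, invariants, determinism."""

import numpy as np
import pytest

from splicerefine.junctions import validate_and_filter
from splicerefine.simulate import (
    SimConfig,
    SimSizeError,
    generate_truth,
    simulate_dataset,
    simulate_microarray,
    simulate_observables,
    write_dataset,
)


def test_no_planting_when_rates_zero():
    cfg = SimConfig(
        seed=2, n_genes=40, n_scaffolds=1, scaffold_length=150_000,
        as_rates={"cassette": 0.0, "alt5": 0.0, "alt3": 0.0, "IR": 0.0},
    )
    _, _, truth = generate_truth(cfg)
    assert truth.events == []


def test_intergenic_at_fraction_near_target():
    cfg = SimConfig(seed=4, n_genes=20, n_scaffolds=1, scaffold_length=150_000,
                    novel_count=0, short_novel_count=0,
                    at_fraction_noncoding=0.87)
    genome, _, truth = generate_truth(cfg)
    mask = np.ones(cfg.scaffold_length, dtype=bool)
    for tg in truth.genes.values():
        lo, hi = tg.footprint
        mask[lo:hi] = False
    seq = np.frombuffer(genome["scf_1"].encode(), dtype="S1")[mask]
    assert mask.sum() > 100_000
    at = np.isin(seq, [b"A", b"T"]).mean()
    assert abs(at - 0.87) < 0.02


def test_intron_length_mean_near_target():
    cfg = SimConfig(seed=6, n_genes=250, n_scaffolds=8, scaffold_length=250_000,
                    exons_per_gene=(4, 8), novel_count=0, short_novel_count=0)
    _, _, truth = generate_truth(cfg)
    lengths = [e - s for tg in truth.genes.values() for s, e in tg.model.introns]
    assert len(lengths) >= 1000
    assert all(cfg.intron_min <= L <= cfg.intron_max for L in lengths)
    assert abs(np.mean(lengths) - 135) < 10


def test_zero_depth_gives_empty_evidence():
    cfg = SimConfig(seed=2, n_genes=20, n_scaffolds=1, scaffold_length=100_000,
                    depth=0.0, count_depth=0.0)
    _, _, truth = generate_truth(cfg)
    junctions, covs, counts, totals = simulate_observables(truth, cfg)
    assert junctions == []
    assert all(int(arr.sum()) == 0 for t in covs.values() for arr in t.depth.values())
    assert int(counts.to_numpy().sum()) == 0


def test_silent_stage_has_zero_counts():
    profiles = {"G-m": 0.0, "S-3": 1.0, "S-15": 1.0, "C-2": 1.0, "C-8": 1.0}
    cfg = SimConfig(seed=2, n_genes=20, n_scaffolds=1, scaffold_length=100_000,
                    stage_profiles=profiles)
    _, _, truth = generate_truth(cfg)
    _, _, counts, _ = simulate_observables(truth, cfg)
    assert int(counts["G-m"].sum()) == 0
    assert int(counts["C-2"].sum()) > 0


def test_planted_ir_intron_fully_covered_at_10x(sim_recovery):
    """At >=40x gene depth and minor fraction 0.5, every base of a planted
    retained intron reaches the 10x retention threshold in active samples."""
    ds = sim_recovery
    from splicerefine.models import STAGE_GROUPS
    checked = 0
    for e in ds.truth.events:
        if e.event_type != "IR" or e.retention_fraction < 0.5:
            continue
        samples = (
            STAGE_GROUPS[e.stage_group] if e.stage_group else ds.config.samples
        )
        for s in samples:
            iv = e.ref_introns[0]
            scaffold = ds.truth.genes[e.gene_id].model.scaffold
            assert ds.coverage[s].min_depth(scaffold, *iv) >= 10
            checked += 1
    assert checked > 0


def test_emitted_junctions_pass_the_acceptance_filter(sim_small):
    ds = sim_small
    kept = validate_and_filter(ds.genome, ds.junctions)
    assert len(kept) == len(ds.junctions)
    assert all(j.min_anchor >= 8 for j in ds.junctions)
    assert all(10 <= j.length <= 10000 for j in ds.junctions)


def test_counts_sum_to_rpkm_denominator(sim_small):
    ds = sim_small
    assert (ds.counts.sum(axis=0) == ds.totals).all()


def test_same_seed_means_byte_identical_outputs(tmp_path):
    cfg = SimConfig(seed=9, n_genes=15, n_scaffolds=1, scaffold_length=80_000,
                    novel_count=3, short_novel_count=1)
    write_dataset(simulate_dataset(cfg), tmp_path / "a")
    write_dataset(simulate_dataset(cfg), tmp_path / "b")
    files = sorted(
        p.relative_to(tmp_path / "a")
        for p in (tmp_path / "a").rglob("*")
        if p.is_file()
    )
    assert files
    for f in files:
        assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes(), f


def test_infeasible_packing_raises_sizing_error():
    cfg = SimConfig(seed=2, n_genes=200, n_scaffolds=1, scaffold_length=30_000)
    with pytest.raises(SimSizeError):
        generate_truth(cfg)


def test_noiseless_probes_equal_log2_truth():
    cfg = SimConfig(seed=8, n_genes=25, n_scaffolds=1, scaffold_length=120_000,
                    probe_noise_sd=0.0)
    _, _, truth = generate_truth(cfg)
    probes, probe_map = simulate_microarray(truth, cfg)
    for _, row in probes.iterrows():
        gid = probe_map[row["probe_id"]]
        for s in cfg.samples:
            assert row[s] == np.log2(truth.expression.loc[gid, s])


def test_probe_longer_than_every_exon_raises():
    cfg = SimConfig(seed=8, n_genes=10, n_scaffolds=1, scaffold_length=80_000,
                    probe_length=500)
    _, _, truth = generate_truth(cfg)
    with pytest.raises(ValueError, match="probe length"):
        simulate_microarray(truth, cfg)


def test_planted_events_reference_existing_introns(sim_recovery):
    truth = sim_recovery.truth
    assert truth.events
    for e in truth.events:
        introns = set(map(tuple, truth.genes[e.gene_id].model.introns))
        if e.event_type in ("IR", "alt5", "alt3"):
            assert set(e.ref_introns) <= introns
        else:
            assert set(e.ref_introns) <= introns
            j1, j2 = e.ref_introns
            assert e.alt_interval == (min(j1[0], j2[0]), max(j1[1], j2[1]))
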