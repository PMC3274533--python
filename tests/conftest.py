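import numpy as np
import pytest
from hypothesis import settings

from splicerefine.pipeline import run_analysis
from splicerefine.simulate import SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_small():
    """A small mixed study: planted AS, defects, novel regions, stage-up."""
    cfg = SimConfig(seed=1, n_genes=60, n_scaffolds=2, scaffold_length=120_000)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def result_small(sim_small):
    ds = sim_small
    return run_analysis(
        ds.genome, ds.annotation, ds.junctions, ds.coverage,
        ds.counts, ds.totals, probes=ds.probes, go_map=ds.go_map,
    )


@pytest.fixture(scope="session")
def sim_recovery():
    """The planted-event recovery study: every gene at >=20x pooled
    coverage (the recovery conditions), minor isoform fraction 0.5,
    fixed seed."""
    cfg = SimConfig(
        seed=3, n_genes=600, n_scaffolds=6, scaffold_length=250_000,
        expr_log10_range=(0.7, 3.5),
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def result_recovery(sim_recovery):
    ds = sim_recovery
    return run_analysis(
        ds.genome, ds.annotation, ds.junctions, ds.coverage,
        ds.counts, ds.totals, probes=ds.probes, go_map=ds.go_map,
    )


@pytest.fixture(scope="session")
def sim_clean():
    """No planted AS/defects/novel regions and a high expression floor:
    every model should be completely confirmed."""
    cfg = SimConfig(
        seed=5, n_genes=50, n_scaffolds=2, scaffold_length=120_000,
        expr_log10_range=(1.0, 3.0),
        as_rates={"cassette": 0.0, "alt5": 0.0, "alt3": 0.0, "IR": 0.0},
        boundary_defect_fraction=0.0, intron_defect_fraction=0.0,
        merged_annotation_fraction=0.0, split_annotation_fraction=0.0,
        novel_count=0, short_novel_count=0, stage_up_fraction=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def result_clean(sim_clean):
    ds = sim_clean
    return run_analysis(
        ds.genome, ds.annotation, ds.junctions, ds.coverage,
        ds.counts, ds.totals, probes=ds.probes, go_map=ds.go_map,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
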