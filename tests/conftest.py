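"""Shared fixtures: a small synthetic panel generated once per session."""

import pytest

from tubervar.synthetic_data import (
    SampleSpec,
    SimConfig,
    generate_all,
    plant_cnv_profiles,
    simulate_layout,
    simulate_sequences,
)


def small_config(**overrides) -> SimConfig:
    """A 2 x 400-kb genome with 60 genes and 2 planted 10-gene clusters."""
    kwargs = dict(
        n_chroms=2,
        chrom_length=400_000,
        n_genes=60,
        n_planted_clusters=2,
        cluster_gene_count=10,
        cluster_span=120_000,
        samples=[
            SampleSpec("A", 2, "g1"),
            SampleSpec("B", 2, "g1"),
            SampleSpec("C", 4, "g2"),
            SampleSpec("D", 5, "g2"),
        ],
        decoy_fraction=0.25,
        snp_violation_fraction=0.2,
        seed=11,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def cfg():
    return small_config()


@pytest.fixture(scope="session")
def layout(cfg):
    return simulate_layout(cfg)


@pytest.fixture(scope="session")
def sequences(cfg, layout):
    return simulate_sequences(cfg, layout)


@pytest.fixture(scope="session")
def cnv_profiles(cfg, layout):
    return plant_cnv_profiles(cfg, layout)


@pytest.fixture(scope="session")
def fixture_dir(cfg, tmp_path_factory):
    """The full emitted file tree for the small panel."""
    outdir = tmp_path_factory.mktemp("panel")
    generate_all(cfg, outdir)
    return outdir
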