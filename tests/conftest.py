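"""Shared fixtures: small simulated datasets and a full toy pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from epiplexkit.pipeline import RunConfig, run_pipeline
from epiplexkit.sim import (SimConfig, build_spikein_reference, build_transcriptome,
                            plant_modifications)


def toy_config(seed: int = 1) -> RunConfig:
    """The 50-kb toy study: 20 planted m6A and 10 inosine sites, two replicates."""
    cfg = RunConfig()
    cfg.sim.seed = seed
    cfg.sim.n_m6a_sites = 20
    cfg.sim.n_inosine_sites = 10
    return cfg


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """A fast configuration for unit tests (few genes, few reads)."""
    cfg = SimConfig(seed=seed, n_genes=6, gene_length_range=(900, 1400),
                    n_reads_enrich=4000, n_reads_control=4000)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """Full pipeline run on the toy study; returns (config, run directory)."""
    outdir = tmp_path_factory.mktemp("toy_run")
    cfg = toy_config()
    run_pipeline(cfg, str(outdir))
    return cfg, str(outdir)


@pytest.fixture(scope="session")
def no_inosine_run(tmp_path_factory):
    """Toy study with every inosine site removed (decoupling control)."""
    outdir = tmp_path_factory.mktemp("no_inosine_run")
    cfg = toy_config()
    cfg.n_replicates = 1
    cfg.sim.n_inosine_sites = 0
    run_pipeline(cfg, str(outdir), until="callpeaks")
    return cfg, str(outdir)


@pytest.fixture(scope="session")
def small_world():
    """(config, model, seqs, sites, spikein) for a small simulated genome."""
    cfg = small_config()
    model, seqs = build_transcriptome(cfg)
    sites = plant_modifications(model, seqs, cfg)
    spike = build_spikein_reference(cfg)
    return cfg, model, seqs, sites, spike


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
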