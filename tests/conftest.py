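"""Shared fixtures: one simulated study (three species sharing isoform
ancestors) and one completed pipeline run, both session-scoped because
the spliced-alignment kernel compiles on first use."""

from __future__ import annotations

import numpy as np
import pytest

import mtminer as mt
from mtminer.simulate import ancestral_genes, reference_records


@pytest.fixture(scope="session")
def study_config() -> mt.SimulationConfig:
    return mt.SimulationConfig(seed=11, species_count=3)


@pytest.fixture(scope="session")
def study(study_config):
    return mt.simulate_species(study_config)


@pytest.fixture(scope="session")
def study_refs(study_config):
    return reference_records(study_config)


@pytest.fixture(scope="session")
def study_ancestors(study_config):
    return ancestral_genes(study_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, study_config, study, study_refs):
    """Pipeline output over the simulated study (noise-free)."""
    base = tmp_path_factory.mktemp("pipeline")
    fasta = base / "genomes.fasta"
    refs_fasta = base / "refs.fasta"
    mt.write_fasta([t.contig for t in study], fasta)
    mt.write_fasta([r for lst in study_refs.values() for r in lst], refs_fasta)
    config = mt.RunConfig(
        inputs=(str(fasta),),
        refs_path=str(refs_fasta),
        outdir=str(base / "out"),
        seed=7,
        replicates=100,
    )
    report = mt.run_pipeline(config)
    return {"report": report, "outdir": base / "out", "config": config, "base": base}


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
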