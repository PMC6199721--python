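"""Shared fixtures: a session-scoped synthetic study and its pipeline run."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from tadcomp.pipeline import RunConfig, run_full_analysis
from tadcomp.synthetic_data import (
    SimConfig,
    default_samples,
    generate_chip_tracks,
    generate_expression,
    generate_genome,
    write_fixture_bundle,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: One seed drives the whole synthetic study used across the suite.
STUDY_SEED = 1234


def build_bundle(config: SimConfig, directory, seed: int = STUDY_SEED):
    """Generate genome + expression + ChIP tracks and write them as a bundle."""
    genome = generate_genome(config, seed=seed)
    table, aux = generate_expression(genome, default_samples(config), seed=seed + 1)
    tracks = {}
    offset = 2
    for target in ("MOF", "H4K16ac"):
        for sex in ("F", "M"):
            tracks[(target, sex, "control")] = generate_chip_tracks(
                genome, sex=sex, target=target, seed=seed + offset
            )
            offset += 1
    write_fixture_bundle(genome, directory, expression=table, aux=aux, tracks=tracks)
    return genome


@pytest.fixture(scope="session")
def study_genome(tmp_path_factory):
    directory = tmp_path_factory.mktemp("study_bundle")
    genome = build_bundle(SimConfig.default_study(), directory)
    return genome, directory


@pytest.fixture(scope="session")
def study_run(study_genome, tmp_path_factory):
    _, bundle_dir = study_genome
    out_dir = tmp_path_factory.mktemp("study_run")
    config = RunConfig(
        bundle_dir=str(bundle_dir), out_dir=str(out_dir), seed=STUDY_SEED
    )
    out, manifest = run_full_analysis(config)
    return out, manifest
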