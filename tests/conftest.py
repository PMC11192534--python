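"""Shared fixtures: small peptides, synthetic scenarios, and one cached
end-to-end build reused by the integration and acceptance tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import mcbuild as mc


@pytest.fixture(scope="session")
def library():
    return mc.default_library()


@pytest.fixture(scope="session")
def tripeptide():
    """Single-conformer ALA-SER-ALA with ideal geometry."""
    return mc.build_ideal_peptide(["ALA", "SER", "ALA"])


@pytest.fixture(scope="session")
def ser_scenario():
    """Two-conformer Ser (p/m at 0.6/0.4) in a tripeptide at 1.0 A."""
    spec = mc.ScenarioSpec(
        sequence=["ALA", "SER", "ALA"],
        sites={2: mc.SiteSpec(["p", "m"], [0.6, 0.4])},
        resolution=1.0,
        seed=3,
    )
    return (spec,) + mc.make_scenario(spec)


@pytest.fixture(scope="session")
def ser_build(ser_scenario):
    """Full pipeline output on the Ser scenario (built once per session)."""
    _, ground_truth, single, dmap = ser_scenario
    config = mc.RunConfig(resolution=1.0, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final, report = mc.build_multiconformer_model(single, dmap, config)
    return ground_truth, final, report, dmap


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def build_scenario_and_fit(resolution: float, seed: int, rotamers=("p", "m"),
                           occupancies=(0.6, 0.4)):
    """Helper: run the full pipeline on a one-site Ser tripeptide."""
    spec = mc.ScenarioSpec(
        sequence=["ALA", "SER", "ALA"],
        sites={2: mc.SiteSpec(list(rotamers), list(occupancies))},
        resolution=resolution,
        seed=seed,
    )
    ground_truth, single, dmap = mc.make_scenario(spec)
    config = mc.RunConfig(resolution=resolution, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final, _ = mc.build_multiconformer_model(single, dmap, config)
    return ground_truth, final
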