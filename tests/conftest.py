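"""Shared fixtures: simulated scenarios reused across the suite.

The expensive simulations (default 2x1 Mb planted scenario, 1 Mb
exchangeable null, 200 kb small scenario) are session-scoped so every test
sees the same deterministic data without re-simulating.
"""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from methdiff import dmr as dmrmod
from methdiff import profiles
from methdiff.simulate import SimulationConfig, simulate_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """The standard planted scenario: 2 x 1 Mb, 200 CHH DMRs, 12x coverage."""
    return simulate_scenario(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_pair(default_bundle):
    return profiles.pair_samples(
        default_bundle.sample_a, default_bundle.sample_b, min_total_reads=3
    )


@pytest.fixture(scope="session")
def default_windows_chh(default_bundle, default_pair):
    return dmrmod.test_windows(
        default_pair, default_bundle.config.chrom_lengths, "CHH"
    )


@pytest.fixture(scope="session")
def default_dmrs(default_windows_chh, default_pair):
    premerge = dmrmod.call_dmrs(default_windows_chh)
    return dmrmod.merge_adjacent(premerge, default_pair)


@pytest.fixture(scope="session")
def null_windows():
    """CHH windows from a 1-Mb null: no planted DMRs, both samples drawn
    independently from the same per-site level distribution."""
    cfg = dataclasses.replace(
        SimulationConfig(seed=1, chrom_lengths={"chr1": 1_000_000}).null(),
        paired_true_levels=False,
    )
    bundle = simulate_scenario(cfg)
    pair = profiles.pair_samples(bundle.sample_a, bundle.sample_b, 3)
    return dmrmod.test_windows(pair, cfg.chrom_lengths, "CHH")


@pytest.fixture(scope="session")
def small_bundle():
    """A 200-kb scenario with 30 planted CHH DMRs (fast end-to-end runs)."""
    cfg = SimulationConfig(seed=7, chrom_lengths={"chr1": 200_000})
    cfg = dataclasses.replace(cfg, n_planted_dmrs={"CG": 0, "CHG": 0, "CHH": 30})
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def small_pair(small_bundle):
    return profiles.pair_samples(small_bundle.sample_a, small_bundle.sample_b, 3)


@pytest.fixture(scope="session")
def small_dmrs(small_bundle, small_pair):
    windows = dmrmod.test_windows(
        small_pair, small_bundle.config.chrom_lengths, "CHH"
    )
    return dmrmod.merge_adjacent(dmrmod.call_dmrs(windows), small_pair)
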