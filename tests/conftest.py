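"""Shared fixtures: small hand-built inputs and one session-scoped
synthetic digestion experiment at generator defaults."""

from __future__ import annotations

import pytest

import proteospec as ps


@pytest.fixture(scope="session")
def lib228() -> ps.PeptideLibrary:
    """Canonical-scale synthetic library: 228 random 14-mers."""
    return ps.make_library(228, 14, seed=0)


@pytest.fixture(scope="session")
def truth_ip() -> ps.GroundTruthSpecificity:
    return ps.GroundTruthSpecificity.ip_preset()


@pytest.fixture(scope="session")
def truth_cp() -> ps.GroundTruthSpecificity:
    return ps.GroundTruthSpecificity.cp_preset()


@pytest.fixture(scope="session")
def default_config() -> ps.DigestSimConfig:
    return ps.DigestSimConfig(seed=0)


@pytest.fixture(scope="session")
def digest_records(lib228, truth_ip, truth_cp, default_config):
    """One simulated two-enzyme experiment (iP, cP, shared NEC)."""
    return ps.simulate_experiment(lib228, truth_ip, truth_cp, default_config)


@pytest.fixture(scope="session")
def called_ip(digest_records, lib228):
    return ps.call_sites(digest_records, lib228, "iP")


@pytest.fixture(scope="session")
def called_cp(digest_records, lib228):
    return ps.call_sites(digest_records, lib228, "cP")


@pytest.fixture(scope="session")
def background_matrix(lib228):
    return ps.build_matrix(ps.all_windows(lib228))


@pytest.fixture(scope="session")
def enrichment_pair(called_ip, called_cp, lib228, background_matrix):
    """(iP, cP) enrichment results against the common library background."""
    out = []
    for calls in (called_ip, called_cp):
        windows = [ps.window(s, lib228) for s in sorted(calls[-1].sites)]
        out.append(ps.icelogo_enrichment(ps.build_matrix(windows), background_matrix))
    return tuple(out)
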