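"""Shared fixtures: the default synthetic study, computed once per session."""

import numpy as np
import pytest

import regclust as rc


@pytest.fixture(scope="session")
def truth():
    return rc.make_truth()


@pytest.fixture(scope="session")
def matrix(truth):
    return rc.simulate_expression(truth)


@pytest.fixture(scope="session")
def degs(matrix):
    return rc.filter_degs(matrix, 1.5)


@pytest.fixture(scope="session")
def scaled(matrix, degs):
    return rc.scale_profiles(matrix, degs)


@pytest.fixture(scope="session")
def network(truth):
    interactions, go_map = rc.simulate_network(truth)
    return interactions, go_map


@pytest.fixture(scope="session")
def signatures(network, matrix):
    interactions, _ = network
    return rc.build_signatures(interactions, matrix.gene_ids)


@pytest.fixture(scope="session")
def constraints(signatures, degs):
    return rc.derive_mustlinks(signatures, degs.gene_ids)


@pytest.fixture(scope="session")
def recovery_config():
    """Study conditions for the planted-recovery experiments."""
    return rc.Config(k_range=(2, 12), repeats_per_k=5, seed=1)


@pytest.fixture(scope="session")
def cluster_result(scaled, constraints, recovery_config):
    return rc.select_k(scaled, constraints, recovery_config)


@pytest.fixture(scope="session")
def truth_labels(truth, scaled):
    return [truth.gene_cluster[g] for g in scaled.gene_ids]
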