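"""Shared fixtures: random positive-definite quadratic problems and small
simulated genomic datasets, all generated at test time."""

import numpy as np
import pytest

import sparsegp as sg


def random_pd_problem(rng, p, m=1, scale=1.0):
    """Random PD Sigma (via A'A/n + ridge) and non-degenerate Gamma."""
    A = rng.standard_normal((3 * p, p))
    Sigma = A.T @ A / (3 * p) + 0.05 * np.eye(p)
    Gamma = scale * rng.standard_normal((p, m))
    return sg.SufficientStatistics(Sigma, Gamma)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def st_sim():
    """Single-trait genomic simulation: 150 genotypes, 400 markers, h2=0.4."""
    return sg.simulate_multitrait(
        sg.SimConfig(n=150, p_or_m=400, q=1, seed=42))


@pytest.fixture(scope="session")
def mt_sim():
    """Three-trait genomic simulation with correlated genetic values."""
    Omega = np.array([[0.5, 0.25, 0.1],
                      [0.25, 0.4, 0.2],
                      [0.1, 0.2, 0.6]])
    R = np.diag([0.5, 0.6, 0.4])
    return sg.simulate_multitrait(
        sg.SimConfig(n=60, p_or_m=250, q=3, Omega=Omega, R=R, seed=7))
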