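"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately re-derive expected quantities by
brute-force enumeration (never by calling the code paths they are used to
check), so tests compare two independent routes to the same number.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from pairkin import CategoryCounts, KCoefficients

# fully reproducible property tests, no example database on disk
settings.register_profile("pairkin", derandomize=True, database=None)
settings.load_profile("pairkin")


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


def hw(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


def oracle_ibd_cells(p: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brute-force conditional genotype-pair probabilities per IBD state,
    by enumerating Bernoulli(p) allele draws.

    IBD 0: four free alleles; IBD 1: one shared allele plus one free allele
    per individual; IBD 2: two alleles shared by both.
    """
    def bern(x):  # P(allele = x)
        return p if x == 1 else 1.0 - p

    m0 = np.zeros((3, 3))
    for a, b, c, d in itertools.product((0, 1), repeat=4):
        m0[a + b, c + d] += bern(a) * bern(b) * bern(c) * bern(d)
    m1 = np.zeros((3, 3))
    for s, x, y in itertools.product((0, 1), repeat=3):
        m1[s + x, s + y] += bern(s) * bern(x) * bern(y)
    m2 = np.zeros((3, 3))
    for a, b in itertools.product((0, 1), repeat=2):
        m2[a + b, a + b] += bern(a) * bern(b)
    return m0, m1, m2


def oracle_expected_cells(k: tuple[float, float, float],
                          p_values, weights=None) -> CategoryCounts:
    """Mixture of the brute-force IBD matrices over a discrete spectrum."""
    p_values = np.atleast_1d(np.asarray(p_values, dtype=float))
    if weights is None:
        weights = np.full(p_values.size, 1.0 / p_values.size)
    cells = np.zeros((3, 3))
    for p, w in zip(p_values, weights):
        m0, m1, m2 = oracle_ibd_cells(p)
        cells += w * (k[0] * m0 + k[1] * m1 + k[2] * m2)
    return CategoryCounts(cells)


def oracle_tally(g1, g2) -> CategoryCounts:
    """Per-site loop tally of the 3x3 matrix, skipping missing genotypes."""
    m = np.zeros((3, 3))
    for x, y in zip(g1, g2):
        if 0 <= x <= 2 and 0 <= y <= 2:
            m[x, y] += 1
    return CategoryCounts(m)


@pytest.fixture(scope="session")
def constant_spectrum():
    from pairkin import SpectrumModel
    return SpectrumModel.neutral_constant(40)
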