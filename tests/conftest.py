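"""Shared fixtures and the exact-rational oracle for the two-library test."""

from fractions import Fraction
from math import comb

import pytest

from digseg import SimulationConfig, generate_dataset


def exact_conditional_pmf(k: int, x: int, n1: int, n2: int) -> Fraction:
    """P(k | x) for integer library sizes, in exact rational arithmetic."""
    return Fraction(
        comb(x + k, k) * n2**k * n1 ** (x + 1), (n1 + n2) ** (x + k + 1)
    )


def exact_two_sided_p(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided p-value by direct exact summation: 2*min(lower, 1-lower)."""
    lower = sum(exact_conditional_pmf(k, x, n1, n2) for k in range(y + 1))
    return min(Fraction(1), 2 * min(lower, 1 - lower))


@pytest.fixture(scope="session")
def small_dataset():
    """400-gene default-mix dataset shared by read/classify smoke tests."""
    config = SimulationConfig(n_genes=400, seed=11)
    return config, generate_dataset(config)
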