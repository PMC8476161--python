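"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gcrobust.genetic_code import (
    CODONS,
    CODON_INDEX,
    NUCLEOTIDES,
    SGC_STOP_CODONS,
)
from gcrobust.pipeline import POLAR_REQUIREMENT_TSV
from gcrobust.properties_io import PropertyTable, load_property_table
from gcrobust.synthetic_data import FakePropertySpec, generate_fake_properties


@pytest.fixture(scope="session")
def polar_table() -> PropertyTable:
    return load_property_table(POLAR_REQUIREMENT_TSV)


@pytest.fixture(scope="session")
def polar_values(polar_table) -> np.ndarray:
    return polar_table.vector("polar_requirement")


@pytest.fixture(scope="session")
def small_fake_table() -> PropertyTable:
    """Five fake properties for cheap cross-checks."""
    return generate_fake_properties(FakePropertySpec(count=5, seed=42))


def minus_one_frameshift_matrix() -> np.ndarray:
    """Independent -1 frameshift enumerator (test oracle only).

    A -1 shift of codon n1n2n3 preceded by nucleotide n0 yields n0n1n2.
    Returns the 64x64 event-count matrix over sense codon pairs.
    """
    w = np.zeros((64, 64))
    for source in CODONS:
        if source in SGC_STOP_CODONS:
            continue
        for n0 in NUCLEOTIDES:
            outcome = n0 + source[:2]
            if outcome in SGC_STOP_CODONS:
                continue
            w[CODON_INDEX[source], CODON_INDEX[outcome]] += 1.0
    return w


def bh_stepup_reference(p: np.ndarray, alpha: float) -> np.ndarray:
    """Hand-rolled Benjamini–Hochberg step-up flags (test oracle only).

    Rejects hypotheses 1..k where k is the largest index (1-based, in
    ascending P order) with p_(k) <= k * alpha / m.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_max = rank
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_max]] = True
    return flags


def naive_ms(values20: np.ndarray, perm: np.ndarray, weights64: np.ndarray) -> float:
    """Brute-force MS over all 64x64 codon pairs (test oracle only).

    ``perm[a]`` is the amino-acid index assigned to SGC codon set ``a``.
    """
    from gcrobust.genetic_code import SET_OF_CODON

    p = np.zeros(64)
    for i in range(64):
        a = SET_OF_CODON[i]
        if a >= 0:
            p[i] = values20[perm[a]]
    num = 0.0
    for i in range(64):
        for j in range(64):
            num += weights64[i, j] * (p[i] - p[j]) ** 2
    return num / weights64.sum()
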