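"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (full-matrix
Smith-Waterman, PMF summation, step-up FDR) kept independent of the package
internals so they can vouch for them.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np
import pytest

from biss.kmer import ConversionMode


def full_sw_oracle(
    query: str,
    ref: str,
    mode: ConversionMode,
    match: int = 4,
    mismatch: int = -2,
    gap: int = -10,
) -> int:
    """Textbook full-matrix local-alignment score with the asymmetric rule."""
    n, m = len(query), len(ref)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    rb, qb = mode.ref_base, mode.read_base
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            q, r = query[i - 1], ref[j - 1]
            s = match if (q == r and q in "ACGT") or (r == rb and q == qb) else mismatch
            h = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            H[i][j] = h
            best = max(best, h)
    return best


def binom_upper_tail_oracle(m: int, n: int, p: float) -> float:
    """P(X >= m) by explicit PMF summation."""
    total = 0.0
    for k in range(m, n + 1):
        total += math.comb(n, k) * p ** k * (1 - p) ** (n - k)
    return total


def bh_oracle(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up by the definition: sort, scale by N/rank,
    enforce monotonicity from the largest p down, cap at 1."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        value = p[idx] * n / rank_from_top
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def convert_read(seq: str, rng: np.random.Generator, rate: float = 1.0) -> str:
    """Bisulfite-convert a Watson-strand fragment: each C to T with ``rate``."""
    return "".join(
        "T" if b == "C" and rng.random() < rate else b for b in seq
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome() -> dict:
    # one contig with every context represented and a G-rich stretch
    return {"chrT": "ACGTCAGCATTGGCCATCGA"}
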