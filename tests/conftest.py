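"""Shared fixtures and independent brute-force oracles.

The oracles implement the influence definitions as literal nested loops
over node triplets, independent of the vectorized package code, and are
the reference every aggregate is checked against.
"""

from __future__ import annotations

import numpy as np
import pytest

from depna.core import CorrelationMatrix
from depna.roi import RoiSet


# ---------------------------------------------------------------------------
# literal-loop oracles


def oracle_pc(C: np.ndarray, i: int, k: int, j: int) -> float:
    return (C[i, k] - C[i, j] * C[k, j]) / np.sqrt(
        (1 - C[i, j] ** 2) * (1 - C[k, j] ** 2)
    )


def oracle_d(C: np.ndarray, i: int, k: int, j: int) -> float:
    return max(0.0, C[i, k] - oracle_pc(C, i, k, j))


def oracle_dependency(C: np.ndarray) -> np.ndarray:
    """D(i,j) = 1/(N-1) * sum_{k != j} d(i,k|j); the k = i term is 0."""
    n = C.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total = 0.0
            for k in range(n):
                if k == j or k == i:
                    continue
                total += oracle_d(C, i, k, j)
            D[i, j] = total / (n - 1)
    return D


def oracle_degree(C: np.ndarray) -> np.ndarray:
    D = oracle_dependency(C)
    return D.sum(axis=0)


def oracle_intra(C: np.ndarray, idx: list[int]) -> np.ndarray:
    """Influencing degree computed on the sub-matrix alone."""
    return oracle_degree(C[np.ix_(idx, idx)])


def oracle_inter_within(C: np.ndarray, src: list[int], tgt: list[int]) -> np.ndarray:
    out = []
    for j in src:
        vals = [
            oracle_d(C, tgt[a], tgt[b], j)
            for a in range(len(tgt))
            for b in range(a + 1, len(tgt))
        ]
        out.append(np.mean(vals))
    return np.array(out)


def oracle_inter_between(C: np.ndarray, src: list[int], tgt: list[int]) -> np.ndarray:
    out = []
    for j in src:
        vals = [oracle_d(C, i, k, j) for i in tgt for k in src if k != j]
        out.append(np.mean(vals))
    return np.array(out)


def random_corr(rng: np.random.Generator, n: int, t: int = 40) -> CorrelationMatrix:
    """Well-conditioned random correlation matrix from a Gaussian sample."""
    x = rng.standard_normal((t, n))
    c = np.corrcoef(x, rowvar=False)
    c = np.clip((c + c.T) / 2, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(c)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_roiset() -> RoiSet:
    """Six nodes: three per network, compact enough for hand checks."""
    labels = ("a1", "a2", "a3", "b1", "b2", "b3")
    nets = {l: ("reactivity" if l.startswith("a") else "regulation") for l in labels}
    return RoiSet(labels, nets)
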