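"""Shared test utilities: an independent literal MPCI oracle and matrix fuzz."""

from __future__ import annotations

import math

import numpy as np


def literal_orientation_scaled(X: np.ndarray) -> tuple[int, list[int], int]:
    """Literal ordered-pair enumeration over the rows of a COMPLETE binary
    matrix, in exact integer arithmetic scaled by the column count.

    Returns (fixed, tie_similarities, n_pairs): ``fixed`` is the sum of
    W*S*m over pairs whose majority is decided, ``tie_similarities`` holds
    S*m for pairs whose pooled methylation fraction is exactly 1/2 (weight
    is a coin), and ``n_pairs`` counts all ordered pairs including self.
    """
    n, m = X.shape
    fixed = 0
    ties: list[int] = []
    for i in range(n):
        for j in range(n):
            d = int(np.abs(X[i] - X[j]).sum())
            s_scaled = m - d  # similarity * m, since every position is observed
            ones = int(X[i].sum() + X[j].sum())
            if ones > m:
                fixed += s_scaled
            elif ones < m:
                fixed -= s_scaled
            else:
                ties.append(s_scaled)
    return fixed, ties, n * n


def achievable_signed_sum(residual: int, ties: list[int]) -> bool:
    """Is ``residual`` == sum(eps_t * ties[t]) for some eps in {-1, +1}^T?"""
    sums = {0}
    for s in ties:
        sums = {x + s for x in sums} | {x - s for x in sums}
    return residual in sums


def oracle_mpci_tiefree(X: np.ndarray) -> float:
    """Scalar literal oracle for matrices (missing allowed) w/o tie pairs.

    Raises AssertionError if a tie pair is encountered; test code must
    pre-filter with has_tie_pairs.
    """

    def orient(signals: np.ndarray) -> float:
        total = 0.0
        n_valid = 0
        for a in signals:
            for b in signals:
                joint = [
                    (x, y)
                    for x, y in zip(a, b)
                    if not (math.isnan(x) or math.isnan(y))
                ]
                obs = [v for v in list(a) + list(b) if not math.isnan(v)]
                if not joint or not obs:
                    continue
                sim = 1.0 - sum(abs(x - y) for x, y in joint) / len(joint)
                ones = sum(obs)
                assert 2 * ones != len(obs), "tie pair in supposedly tie-free matrix"
                w = 1.0 if 2 * ones > len(obs) else -1.0
                total += w * sim
                n_valid += 1
        return total / n_valid if n_valid else math.nan

    ms_r = orient(X)
    ms_c = orient(X.T)
    vals = [v for v in (ms_r, ms_c) if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def has_tie_pairs(X: np.ndarray) -> bool:
    """Any ordered pair (rows or columns, incl. self) with pooled th == 1/2?"""
    for A in (X, X.T):
        obs = (~np.isnan(A)).sum(axis=1)
        ones = np.nansum(A, axis=1)
        ones2 = ones[:, None] + ones[None, :]
        obs2 = obs[:, None] + obs[None, :]
        if np.any((2 * ones2 == obs2) & (obs2 > 0)):
            return True
    return False


def random_matrix(
    rng: np.random.Generator,
    max_reads: int = 20,
    max_cpgs: int = 12,
    max_missing: float = 0.3,
) -> np.ndarray:
    """A random binary matrix with up to ``max_missing`` missing calls."""
    n = int(rng.integers(1, max_reads + 1))
    m = int(rng.integers(1, max_cpgs + 1))
    p = rng.random()
    X = (rng.random((n, m)) < p).astype(float)
    miss = rng.random((n, m)) < rng.random() * max_missing
    X[miss] = np.nan
    return X
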