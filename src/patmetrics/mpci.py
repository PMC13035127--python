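"""Methylation Pattern Consistency Index (MPCI).

MPCI scores how *consistent* the methylation patterns in a region are,
jointly across sequencing reads and across CpG sites.  Reads are rows of a
binary matrix R (1 = methylated, 0 = unmethylated, NaN = unknown).  For
every ordered pair of row signals (and, transposed, column signals) a
Manhattan similarity

    S_ij = 1 - ManhattanDistance(signal_i, signal_j) / D

is computed over jointly observed positions, and signed by the pooled
methylation majority of the pair:

    W_ij = +1 if th > 1/2,  -1 if th < 1/2,  fair coin if th = 1/2

with th the fraction of 1s among all observed calls of the two signals.
The orientation score is the weighted mean MS = sum(W*S) / (#valid pairs),
and MPCI is the mean of the row-wise and column-wise orientation scores.
The result lies in [-1, +1]: +1 for perfectly consistent methylation, -1
for perfectly consistent unmethylation, ~0 for random patterns.

Missing-data rules: a pair with no jointly observed position has no
similarity; a pair with no observed call has no majority; such pairs are
excluded.  An orientation with no valid pair is missing, and MPCI averages
the remaining orientation (or is missing if both are).

Tie coins are drawn from a seeded generator, one independent fair coin per
tie pair, in row-major pair order.  Each orientation uses a fresh generator
built from the same seed, which makes compute_mpci(R) == compute_mpci(R.T)
exact even when both orientations contain ties.

Cost is quadratic: n^2 + m^2 pair evaluations for an n-read, m-CpG region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .pat_io import ReadMatrix

__all__ = [
    "MpciConfig",
    "PairScore",
    "OrientationScore",
    "manhattan_similarity",
    "pair_weight",
    "pair_score",
    "orientation_score",
    "compute_mpci",
    "mpci_replicates",
    "MpciReplicateSummary",
]


@dataclass(frozen=True)
class MpciConfig:
    """Switches for the two formulation details the metric leaves open.

    similarity_denominator
        "joint" (default): divide the Manhattan distance by the number of
        jointly observed positions of the pair.  "ncols": divide by the
        total number of positions, which counts unobserved positions as
        zero distance and inflates similarity for sparse overlaps.
    include_self_pairs
        Default True: the double sum runs over all ordered pairs (i, j),
        i, j = 1..n, including i = j.  False restricts to unordered
        distinct pairs i < j.
    """

    similarity_denominator: Literal["joint", "ncols"] = "joint"
    include_self_pairs: bool = True


DEFAULT_CONFIG = MpciConfig()


@dataclass(frozen=True)
class PairScore:
    similarity: float  # in [0, 1], or NaN
    weight: float  # +1.0 / -1.0, or NaN
    majority_fraction: float  # th in [0, 1], or NaN


@dataclass(frozen=True)
class OrientationScore:
    value: float  # in [-1, 1], or NaN when no valid pair
    n_valid_pairs: int
    n_tie_pairs: int = 0


def _as_array(sig) -> np.ndarray:
    a = np.asarray(sig, dtype=float)
    if a.ndim != 1 or a.size < 1:
        raise ValueError("a signal is a non-empty 1-D vector")
    return a


def manhattan_similarity(a, b, config: MpciConfig = DEFAULT_CONFIG) -> float:
    """Similarity of two signals; NaN if they share no observed position."""
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    joint = ~np.isnan(a) & ~np.isnan(b)
    n_joint = int(joint.sum())
    if n_joint == 0:
        return math.nan
    dist = float(np.abs(a[joint] - b[joint]).sum())
    denom = n_joint if config.similarity_denominator == "joint" else a.size
    return 1.0 - dist / denom


def _majority_fraction(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """(number of 1s, number of observed calls) pooled over both signals."""
    ones = 0
    obs = 0
    for s in (a, b):
        o = ~np.isnan(s)
        obs += int(o.sum())
        ones += int(np.nansum(s))
    return ones, obs


def pair_weight(a, b, rng: np.random.Generator) -> float:
    """Majority sign of the pooled pair: +1, -1, or a seeded coin on a tie."""
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    ones, obs = _majority_fraction(a, b)
    if obs == 0:
        return math.nan
    if 2 * ones > obs:
        return 1.0
    if 2 * ones < obs:
        return -1.0
    return float(rng.integers(0, 2) * 2 - 1)


def pair_score(a, b, rng: np.random.Generator, config: MpciConfig = DEFAULT_CONFIG) -> PairScore:
    a, b = _as_array(a), _as_array(b)
    sim = manhattan_similarity(a, b, config)
    ones, obs = _majority_fraction(a, b)
    th = ones / obs if obs else math.nan
    w = math.nan if (math.isnan(sim) or obs == 0) else pair_weight(a, b, rng)
    return PairScore(similarity=sim, weight=w, majority_fraction=th)


def _orientation_score_cells(
    X: np.ndarray, rng: np.random.Generator, config: MpciConfig
) -> OrientationScore:
    """Vectorised score over the rows of X (pass X.T for columns)."""
    n, m = X.shape
    if n == 0 or m == 0:
        return OrientationScore(math.nan, 0, 0)
    obs_mask = ~np.isnan(X)
    Xz = np.where(obs_mask, X, 0.0)
    Of = obs_mask.astype(float)
    joint = Of @ Of.T
    # |a-b| = a + b - 2ab for binary calls, restricted to joint positions
    dist = Xz @ Of.T + Of @ Xz.T - 2.0 * (Xz @ Xz.T)
    if config.similarity_denominator == "joint":
        with np.errstate(invalid="ignore", divide="ignore"):
            S = 1.0 - dist / joint
    else:
        S = 1.0 - dist / m
    S[joint == 0] = np.nan

    ones = Xz.sum(axis=1)
    obs = Of.sum(axis=1)
    ones2 = ones[:, None] + ones[None, :]
    obs2 = obs[:, None] + obs[None, :]
    W = np.where(2.0 * ones2 > obs2, 1.0, -1.0)

    if config.include_self_pairs:
        pair_set = np.ones((n, n), dtype=bool)
    else:
        pair_set = np.triu(np.ones((n, n), dtype=bool), k=1)
    valid = pair_set & ~np.isnan(S) & (obs2 > 0)
    ties = valid & (2.0 * ones2 == obs2)
    n_ties = int(ties.sum())
    if n_ties:
        # boolean assignment flattens in row-major order, matching draw order
        W[ties] = rng.integers(0, 2, size=n_ties) * 2.0 - 1.0

    n_valid = int(valid.sum())
    if n_valid == 0:
        return OrientationScore(math.nan, 0, n_ties)
    value = float(np.sum(W[valid] * S[valid]) / n_valid)
    return OrientationScore(value, n_valid, n_ties)


def _cells(R) -> np.ndarray:
    if isinstance(R, ReadMatrix):
        return R.cells
    a = np.asarray(R, dtype=float)
    if a.ndim != 2:
        raise ValueError("read matrix must be 2-D")
    return a


def orientation_score(
    R, rng: np.random.Generator | int | None = 0, config: MpciConfig = DEFAULT_CONFIG
) -> OrientationScore:
    """Weighted-mean similarity over row signals of R (transpose for columns)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _orientation_score_cells(_cells(R), rng, config)


def compute_mpci(R, seed: int = 0, config: MpciConfig = DEFAULT_CONFIG) -> float:
    """MPCI of a read matrix: mean of row-wise and column-wise scores.

    Returns NaN for an empty matrix or when neither orientation has a valid
    pair.  Identical seed implies bit-identical output.
    """
    X = _cells(R)
    ms_rows = _orientation_score_cells(X, np.random.default_rng(seed), config)
    ms_cols = _orientation_score_cells(X.T, np.random.default_rng(seed), config)
    vals = [v.value for v in (ms_rows, ms_cols) if not math.isnan(v.value)]
    if not vals:
        return math.nan
    return float(np.mean(vals))


@dataclass(frozen=True)
class MpciReplicateSummary:
    mean: float
    sd: float  # sample SD across replicates; 0.0 when n_reps == 1
    values: tuple[float, ...]
    tie_fraction_rows: float  # tie pairs / valid pairs, row orientation
    tie_fraction_cols: float


def mpci_replicates(
    R, n_reps: int = 100, seed: int = 0, config: MpciConfig = DEFAULT_CONFIG
) -> MpciReplicateSummary:
    """Replicate MPCI under independent tie-coin draws.

    Replicates differ only through the +/-1 coins assigned to tie pairs
    (th = 1/2); a tie-free matrix therefore has SD exactly 0.  Also reports
    the fraction of valid pairs that hit a tie, per orientation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = _cells(R)
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    values = tuple(compute_mpci(X, seed=int(s), config=config) for s in rep_seeds)
    ms_rows = _orientation_score_cells(X, np.random.default_rng(seed), config)
    ms_cols = _orientation_score_cells(X.T, np.random.default_rng(seed), config)
    arr = np.array(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    mean = float(np.mean(finite)) if finite.size else math.nan
    if n_reps == 1 or np.unique(finite).size <= 1:
        sd = 0.0  # identical replicates (e.g. tie-free matrix): exactly zero
    else:
        sd = float(np.nanstd(arr, ddof=1))
    return MpciReplicateSummary(
        mean=mean,
        sd=sd,
        values=values,
        tie_fraction_rows=ms_rows.n_tie_pairs / ms_rows.n_valid_pairs
        if ms_rows.n_valid_pairs
        else 0.0,
        tie_fraction_cols=ms_cols.n_tie_pairs / ms_cols.n_valid_pairs
        if ms_cols.n_valid_pairs
        else 0.0,
    )
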