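"""Read-level methylation heterogeneity panel: ME, EP, PDR, FDRP, qFDRP.

These metrics quantify epiallele diversity rather than consistency:

* **ME** (methylation entropy): Shannon entropy (bits) of the complete
  epiallele distribution in sliding windows of ``b`` consecutive CpGs,
  normalised by b; region value = mean over qualifying windows.
* **EP** (epi-polymorphism): Gini-style 1 - sum(p_i^2) over the same
  windows; bounded by 1 - 2^-b.
* **PDR** (proportion of discordant reads): a read with >= ``min_cpgs``
  observed calls is discordant iff it shows both methylated and
  unmethylated calls; per-CpG discordant fraction averaged over CpGs.
* **FDRP** / **qFDRP**: per CpG, pairs of reads covering it are scored as
  discordant (any jointly observed call differs) or by normalised Hamming
  distance; up to ``max_pairs`` pairs per CpG are sampled with a seeded
  generator; per-CpG means averaged over CpGs.

All five are invariant under the global methylated/unmethylated swap,
unlike MHL/uMHL.  Windows and pairs live in region CpG-index space (PAT
patterns carry no base-pair distances), a deliberate adaptation of the
original base-pair-window definitions.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from .mpci import _cells

__all__ = ["compute_me", "compute_ep", "compute_pdr", "compute_fdrp", "compute_qfdrp"]


def _window_epiallele_probs(X: np.ndarray, b: int, min_window_reads: int):
    """Yield, per window with enough fully-observing reads, epiallele probs."""
    n, m = X.shape
    for s in range(0, m - b + 1):
        win = X[:, s : s + b]
        complete = ~np.isnan(win).any(axis=1)
        k = int(complete.sum())
        if k < min_window_reads:
            continue
        pats = win[complete].astype(int)
        codes = pats @ (1 << np.arange(b))
        _, counts = np.unique(codes, return_counts=True)
        yield counts / k


def compute_me(R, b: int = 4, min_window_reads: int = 1) -> float:
    """Mean normalised methylation entropy over b-CpG windows, in [0, 1]."""
    if b < 1:
        raise ValueError("b must be >= 1")
    vals = [
        float(-(p * np.log2(p)).sum()) / b
        for p in _window_epiallele_probs(_cells(R), b, min_window_reads)
    ]
    return float(np.mean(vals)) if vals else math.nan


def compute_ep(R, b: int = 4, min_window_reads: int = 1) -> float:
    """Mean epi-polymorphism 1 - sum(p^2) over b-CpG windows."""
    if b < 1:
        raise ValueError("b must be >= 1")
    vals = [float(1.0 - (p**2).sum()) for p in _window_epiallele_probs(_cells(R), b, min_window_reads)]
    return float(np.mean(vals)) if vals else math.nan


def compute_pdr(R, min_cpgs_per_read: int = 4) -> float:
    """Proportion of discordant reads, averaged per CpG then over CpGs."""
    X = _cells(R)
    n, m = X.shape
    if n == 0 or m == 0:
        return math.nan
    obs = ~np.isnan(X)
    qualifying = obs.sum(axis=1) >= min_cpgs_per_read
    has1 = np.nansum(X, axis=1) > 0
    has0 = np.nansum(1.0 - X, axis=1) > 0
    discordant = has1 & has0
    per_cpg = []
    for j in range(m):
        cov = qualifying & obs[:, j]
        total = int(cov.sum())
        if total == 0:
            continue
        per_cpg.append(int((cov & discordant).sum()) / total)
    return float(np.mean(per_cpg)) if per_cpg else math.nan


def _pairwise_read_scores(
    X: np.ndarray, quantitative: bool, max_pairs: int, min_joint: int, seed: int
) -> float:
    n, m = X.shape
    if n == 0 or m == 0:
        return math.nan
    obs = ~np.isnan(X)
    rng = np.random.default_rng(seed)
    per_cpg = []
    for j in range(m):
        readers = np.flatnonzero(obs[:, j])
        if readers.size < 2:
            continue
        pairs = list(combinations(readers.tolist(), 2))
        if len(pairs) > max_pairs:
            pick = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[i] for i in sorted(pick)]
        scores = []
        for a, b in pairs:
            joint = obs[a] & obs[b]
            nj = int(joint.sum())
            if nj < min_joint:
                continue
            diff = int(np.abs(X[a, joint] - X[b, joint]).sum())
            scores.append(diff / nj if quantitative else float(diff > 0))
        if scores:
            per_cpg.append(float(np.mean(scores)))
    return float(np.mean(per_cpg)) if per_cpg else math.nan


def compute_fdrp(R, max_pairs: int = 40, min_joint: int = 1, seed: int = 0) -> float:
    """Fraction of discordant read pairs, per CpG, averaged over CpGs."""
    return _pairwise_read_scores(_cells(R), False, max_pairs, min_joint, seed)


def compute_qfdrp(R, max_pairs: int = 40, min_joint: int = 1, seed: int = 0) -> float:
    """Quantitative FDRP: mean normalised Hamming distance of read pairs."""
    return _pairwise_read_scores(_cells(R), True, max_pairs, min_joint, seed)
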