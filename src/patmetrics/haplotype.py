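"""Methylation haplotype load (MHL), its unmethylated mirror and difference.

MHL summarises co-methylation along reads: for substring lengths
l = 1..L (L = number of region CpGs) let f_l be the fraction of observed
length-l substrings that are *fully methylated*; MHL is the weighted mean
sum(w_l * f_l) / sum(w_l) with w_l = l by default, over lengths with at
least one observed substring.  uMHL uses fully *unmethylated* substrings
instead, and dMHL = MHL - uMHL is the symmetric differential form.

Missing calls ('.') break a read into independent runs by default: a
substring never spans an unknown call.  Set ``split_on_missing=False`` to
instead skip missing calls and compress each read's observed calls into a
single run.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .pat_io import ReadMatrix
from .mpci import _cells

__all__ = ["compute_mhl", "compute_umhl", "compute_dmhl"]


def _observed_runs(row: np.ndarray, split_on_missing: bool) -> list[np.ndarray]:
    obs = ~np.isnan(row)
    if not obs.any():
        return []
    if not split_on_missing:
        return [row[obs]]
    runs = []
    start = None
    for k, o in enumerate(obs):
        if o and start is None:
            start = k
        elif not o and start is not None:
            runs.append(row[start:k])
            start = None
    if start is not None:
        runs.append(row[start:])
    return runs


def _haplotype_load(
    X: np.ndarray,
    target: float,
    weights: Sequence[float] | Callable[[int], float] | None,
    split_on_missing: bool,
) -> float:
    n, m = X.shape
    if n == 0 or m == 0:
        return math.nan
    # counts[l] = (#length-l substrings fully equal to target, #observed)
    full = np.zeros(m + 1)
    total = np.zeros(m + 1)
    for row in X:
        for run in _observed_runs(row, split_on_missing):
            r = len(run)
            is_target = run == target
            for l in range(1, r + 1):
                total[l] += r - l + 1
                # windows of length l that are entirely `target`
                if l == 1:
                    full[l] += int(is_target.sum())
                else:
                    conv = np.convolve(is_target.astype(int), np.ones(l, dtype=int), "valid")
                    full[l] += int((conv == l).sum())
    lengths = [l for l in range(1, m + 1) if total[l] > 0]
    if not lengths:
        return math.nan
    if weights is None:
        w = {l: float(l) for l in lengths}
    elif callable(weights):
        w = {l: float(weights(l)) for l in lengths}
    else:
        w = {l: float(weights[l - 1]) for l in lengths}
    num = sum(w[l] * full[l] / total[l] for l in lengths)
    den = sum(w[l] for l in lengths)
    return num / den


def compute_mhl(
    R,
    weights: Sequence[float] | Callable[[int], float] | None = None,
    split_on_missing: bool = True,
) -> float:
    """Methylation haplotype load in [0, 1]; NaN on an empty matrix."""
    return _haplotype_load(_cells(R), 1.0, weights, split_on_missing)


def compute_umhl(
    R,
    weights: Sequence[float] | Callable[[int], float] | None = None,
    split_on_missing: bool = True,
) -> float:
    """Unmethylated haplotype load: MHL of the complemented matrix."""
    return _haplotype_load(_cells(R), 0.0, weights, split_on_missing)


def compute_dmhl(
    R,
    weights: Sequence[float] | Callable[[int], float] | None = None,
    split_on_missing: bool = True,
) -> float:
    """Differential haplotype load dMHL = MHL - uMHL, in [-1, 1]."""
    mhl = compute_mhl(R, weights, split_on_missing)
    umhl = compute_umhl(R, weights, split_on_missing)
    if math.isnan(mhl) or math.isnan(umhl):
        return math.nan
    return mhl - umhl
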