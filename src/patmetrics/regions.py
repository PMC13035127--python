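"""Region selection: random CpG-count bins, overlap/coverage filters, and
greedy discovery of high-coverage runs.

Benchmark regions are drawn at random in CpG-index space with controlled
CpG counts (the default bins give 100 regions each of 3-7, 8-12, 13-17 and
18-22 CpGs), then pruned so no two retained regions share a CpG and, when
sample data is supplied, so every sample covers each region at more than a
minimum mean depth.  For datasets without predefined regions, a greedy
scan emits maximal runs of consecutive CpGs that each clear a per-CpG read
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .pat_io import CpGMap, PatRecord, RegionSpec
from .simulate import mean_coverage

__all__ = [
    "RegionBinSpec",
    "DEFAULT_BINS",
    "sample_random_regions",
    "filter_overlapping",
    "filter_by_coverage",
    "find_high_coverage_regions",
]


@dataclass(frozen=True)
class RegionBinSpec:
    """(min_cpgs, max_cpgs, n_regions) bins; counts drawn uniformly."""

    bins: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        for lo, hi, n in self.bins:
            if lo < 1 or hi < lo or n < 0:
                raise ValueError(f"bad bin ({lo}, {hi}, {n})")
        spans = sorted((lo, hi) for lo, hi, _ in self.bins)
        for (l1, h1), (l2, _) in zip(spans, spans[1:]):
            if l2 <= h1:
                raise ValueError("bins overlap in CpG count")


DEFAULT_BINS = RegionBinSpec(bins=((3, 7, 100), (8, 12, 100), (13, 17, 100), (18, 22, 100)))


def sample_random_regions(
    cpg_map: CpGMap, bins: RegionBinSpec = DEFAULT_BINS, seed: int = 0
) -> list[RegionSpec]:
    """Draw the binned random regions, each within a single chromosome."""
    table = cpg_map.table
    n_total = len(table)
    max_count = max(hi for _, hi, _ in bins.bins)
    if n_total < max_count:
        raise ValueError(f"CpG map has {n_total} CpGs, need >= {max_count}")
    chroms = table["chrom"].to_numpy()
    idx = table["index"].to_numpy()
    rng = np.random.default_rng(seed)
    regions: list[RegionSpec] = []
    for lo, hi, n_regions in bins.bins:
        made = 0
        attempts = 0
        while made < n_regions:
            attempts += 1
            if attempts > 1000 * max(1, n_regions):
                raise ValueError(f"cannot place {n_regions} regions of {lo}-{hi} CpGs")
            count = int(rng.integers(lo, hi + 1))
            pos = int(rng.integers(0, n_total - count + 1))
            if chroms[pos] != chroms[pos + count - 1]:
                continue  # region must not straddle a chromosome boundary
            regions.append(
                RegionSpec(
                    chrom=str(chroms[pos]),
                    first=int(idx[pos]),
                    last=int(idx[pos + count - 1]),
                )
            )
            made += 1
    return regions


def filter_overlapping(regions: Sequence[RegionSpec]) -> list[RegionSpec]:
    """Greedy keep-first in (chrom, first) order; output pairwise disjoint."""
    kept: list[RegionSpec] = []
    last_kept: dict[str, int] = {}
    for region in sorted(regions, key=lambda r: (r.chrom, r.first, r.last)):
        if region.chrom in last_kept and region.first <= last_kept[region.chrom]:
            continue
        kept.append(region)
        last_kept[region.chrom] = region.last
    return kept


def filter_by_coverage(
    regions: Sequence[RegionSpec],
    samples: Mapping[str, Sequence[PatRecord]],
    min_cov: float = 10.0,
) -> list[RegionSpec]:
    """Keep regions whose mean reads-per-CpG exceeds min_cov in every sample."""
    kept = []
    for region in regions:
        if all(mean_coverage(recs, region) > min_cov for recs in samples.values()):
            kept.append(region)
    return kept


def find_high_coverage_regions(
    records: Sequence[PatRecord],
    min_reads: int = 50,
    min_cpgs: int = 5,
    top_k: int | None = None,
    chrom: str | None = None,
) -> list[RegionSpec]:
    """Greedy scan for maximal runs of consecutive CpGs with deep coverage.

    Every CpG of an emitted region has >= min_reads observed calls and the
    run spans >= min_cpgs consecutive CpG indices.  Regions are ranked by
    mean coverage (descending, ties broken by genomic order); ``top_k``
    truncates the ranking.  ``chrom`` restricts the scan to one chromosome.
    """
    cov: dict[tuple[str, int], int] = {}
    for rec in records:
        if chrom is not None and rec.chrom != chrom:
            continue
        for k, call in enumerate(rec.pattern):
            if call != ".":
                key = (rec.chrom, rec.start_index + k)
                cov[key] = cov.get(key, 0) + rec.count
    runs: list[tuple[RegionSpec, float]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for (c, i), depth in cov.items():
        if depth >= min_reads:
            by_chrom.setdefault(c, []).append((i, depth))
    for c, entries in by_chrom.items():
        entries.sort()
        start = None
        prev = None
        depths: list[int] = []
        for i, depth in entries + [(None, None)]:  # sentinel flushes last run
            if start is not None and i == prev + 1:
                depths.append(depth)
                prev = i
                continue
            if start is not None and prev - start + 1 >= min_cpgs:
                runs.append(
                    (RegionSpec(chrom=c, first=start, last=prev), float(np.mean(depths)))
                )
            if i is None:
                break
            start, prev, depths = i, i, [depth]
    runs.sort(key=lambda t: (-t[1], t[0].chrom, t[0].first))
    out = [r for r, _ in runs]
    return out[:top_k] if top_k is not None else out
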