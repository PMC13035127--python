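"""Synthetic PAT generation and in-silico cfDNA spike-in.

The generator emulates the read structure the metrics consume: reads of a
few consecutive CpG calls drawn from an epiallele mixture of three
haplotype classes — fully methylated, fully unmethylated, and per-CpG
Bernoulli(theta) "random" haplotypes — with an independent per-call
dropout to '.'.  It makes no attempt to model fragment lengths in base
pairs, GC bias or bisulfite conversion errors.

The spike-in mimics a liquid-biopsy disease sample: a healthy cfDNA
background is downsampled to a target coverage (default 100 reads per
CpG), then a fraction f of its reads is *replaced* by reads from the
target tissue, conserving total read count.  Cohort simulation produces
n labelled healthy/disease samples per class with per-sample seeds derived
deterministically from one master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pat_io import PatRecord, RegionSpec, write_pat

__all__ = [
    "EpialleleMixtureConfig",
    "SpikeInConfig",
    "generate_region_reads",
    "downsample_to_coverage",
    "spike_in",
    "simulate_cohort",
    "mean_coverage",
]


@dataclass(frozen=True)
class EpialleleMixtureConfig:
    """Parameters of the synthetic epiallele mixture for one region.

    coverage is the expected mean number of reads per CpG; pi_* are the
    mixture weights of the fully methylated / fully unmethylated /
    Bernoulli(theta) haplotype classes and must sum to 1; dropout is the
    per-call probability of an unknown ('.') call; read_len_cpgs is an
    inclusive (min, max) range of read lengths in CpG units, drawn
    uniformly (cfDNA-scale fragments typically span a handful of CpGs).
    """

    region: RegionSpec
    coverage: float = 100.0
    pi_meth: float = 0.5
    pi_unmeth: float = 0.5
    pi_random: float = 0.0
    theta: float = 0.5
    dropout: float = 0.0
    read_len_cpgs: tuple[int, int] = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        pis = (self.pi_meth, self.pi_unmeth, self.pi_random)
        if any(p < 0 or p > 1 for p in pis) or abs(sum(pis) - 1.0) > 1e-9:
            raise ValueError("mixture weights must be in [0,1] and sum to 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.dropout <= 1 and 0 <= self.theta <= 1):
            raise ValueError("dropout and theta must be probabilities")
        lo, hi = self.read_len_cpgs
        if lo < 1 or hi < lo:
            raise ValueError("read_len_cpgs must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class SpikeInConfig:
    """Spike-in fraction and background target coverage (reads per CpG)."""

    fraction: float
    target_coverage: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


def _expand(records: Sequence[PatRecord]) -> list[PatRecord]:
    out = []
    for rec in records:
        if rec.count == 1:
            out.append(rec)
        else:
            single = PatRecord(rec.chrom, rec.start_index, rec.pattern, 1, rec.extra)
            out.extend([single] * rec.count)
    return out


def mean_coverage(records: Sequence[PatRecord], region: RegionSpec) -> float:
    """Mean reads-per-CpG over the region's CpGs (observed calls only)."""
    cov = np.zeros(region.n_cpgs)
    for rec in records:
        if rec.chrom != region.chrom:
            continue
        for k, call in enumerate(rec.pattern):
            gi = rec.start_index + k
            if region.first <= gi <= region.last and call != ".":
                cov[gi - region.first] += rec.count
    return float(cov.mean()) if region.n_cpgs else 0.0


def generate_region_reads(config: EpialleleMixtureConfig) -> list[PatRecord]:
    """Draw synthetic reads for one region; seeded and reproducible."""
    region = config.region
    m = region.n_cpgs
    if m < 1:
        raise ValueError("degenerate region with no CpGs")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.read_len_cpgs
    mean_len = min((lo + hi) / 2.0, m)
    n_reads = max(1, round(config.coverage * m / mean_len))
    records: list[PatRecord] = []
    for _ in range(n_reads):
        length = min(int(rng.integers(lo, hi + 1)), m)
        start = region.first + int(rng.integers(0, m - length + 1))
        comp = rng.choice(3, p=[config.pi_meth, config.pi_unmeth, config.pi_random])
        if comp == 0:
            calls = np.ones(length, dtype=int)
        elif comp == 1:
            calls = np.zeros(length, dtype=int)
        else:
            calls = (rng.random(length) < config.theta).astype(int)
        chars = ["C" if c else "T" for c in calls]
        if config.dropout > 0:
            drop = rng.random(length) < config.dropout
            chars = ["." if d else ch for ch, d in zip(chars, drop)]
        records.append(PatRecord(region.chrom, start, "".join(chars), 1))
    return records


def downsample_to_coverage(
    records: Sequence[PatRecord],
    region: RegionSpec,
    target_coverage: float,
    seed: int = 0,
) -> list[PatRecord]:
    """Seeded uniform read subsample bringing mean coverage near target.

    If the input is already at or below the target, it is returned
    unchanged with a warning.
    """
    reads = _expand(records)
    current = mean_coverage(reads, region)
    if current <= target_coverage:
        if current < target_coverage:
            warnings.warn(
                f"requested {target_coverage}x but only {current:.1f}x available; "
                "keeping all reads",
                stacklevel=2,
            )
        return reads
    k = max(1, round(len(reads) * target_coverage / current))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(reads), size=k, replace=False))
    return [reads[i] for i in keep]


def spike_in(
    background: Sequence[PatRecord],
    target: Sequence[PatRecord],
    region: RegionSpec,
    config: SpikeInConfig,
) -> list[PatRecord]:
    """Replace round(f*n) background reads with target-tissue reads.

    n is the expanded background read count; total read count is conserved
    exactly.  round() uses ties-to-even.  Raises if the target pool cannot
    supply the replacement reads.
    """
    bg = _expand(background)
    tg = _expand(target)
    n = len(bg)
    k = round(config.fraction * n)
    if k > len(tg):
        raise ValueError(
            f"spike-in needs {k} target reads but the pool has {len(tg)} "
            f"(shortfall {k - len(tg)})"
        )
    if k == 0:
        return list(bg)
    rng = np.random.default_rng(config.seed)
    remove = set(rng.choice(n, size=k, replace=False).tolist())
    kept = [r for i, r in enumerate(bg) if i not in remove]
    add_idx = np.sort(rng.choice(len(tg), size=k, replace=False))
    return kept + [tg[i] for i in add_idx]


def simulate_cohort(
    regions: Sequence[RegionSpec],
    healthy_config: EpialleleMixtureConfig,
    disease_target_config: EpialleleMixtureConfig,
    fraction: float,
    n_per_group: int = 100,
    target_coverage: float = 100.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[PatRecord]], pd.DataFrame]:
    """Simulate a labelled healthy/disease cohort over the given regions.

    Healthy samples are seeded downsamples of a per-region healthy
    background pool; disease samples additionally receive a fraction-f
    spike-in of reads generated from ``disease_target_config``.  The two
    mixture configs carry the per-region epiallele structure; their
    ``region`` and ``seed`` fields are overridden per region/sample.

    Returns (samples, truth) where samples maps sample id to PAT records
    over all regions and truth is a DataFrame (sample, label, fraction,
    seed).  With ``out_dir``, each sample is also written as
    ``<sample>.pat`` plus a ``truth.tsv`` sheet.
    """
    from dataclasses import replace

    ss = np.random.SeedSequence(seed)
    pool_seeds = ss.generate_state(2 * len(regions)) % (2**31)
    # generous pools so both downsampling and spike-in can draw freely
    backgrounds: list[list[PatRecord]] = []
    targets: list[list[PatRecord]] = []
    for i, region in enumerate(regions):
        bg_cfg = replace(
            healthy_config,
            region=region,
            coverage=max(healthy_config.coverage, 4 * target_coverage),
            seed=int(pool_seeds[2 * i]),
        )
        tg_cfg = replace(
            disease_target_config,
            region=region,
            coverage=max(disease_target_config.coverage, 2 * target_coverage),
            seed=int(pool_seeds[2 * i + 1]),
        )
        backgrounds.append(generate_region_reads(bg_cfg))
        targets.append(generate_region_reads(tg_cfg))

    sample_seeds = ss.spawn(1)[0].generate_state(2 * n_per_group * len(regions)) % (2**31)
    samples: dict[str, list[PatRecord]] = {}
    truth_rows = []
    si = 0
    for label, prefix in (("healthy", "H"), ("disease", "D")):
        for k in range(n_per_group):
            name = f"{prefix}{k:03d}"
            recs: list[PatRecord] = []
            first_seed = int(sample_seeds[si])
            for ri, region in enumerate(regions):
                s = int(sample_seeds[si])
                si += 1
                bg = downsample_to_coverage(
                    backgrounds[ri], region, target_coverage, seed=s
                )
                if label == "disease" and fraction > 0:
                    bg = spike_in(
                        bg,
                        targets[ri],
                        region,
                        SpikeInConfig(fraction=fraction, seed=s + 1),
                    )
                recs.extend(bg)
            samples[name] = recs
            truth_rows.append((name, label, fraction if label == "disease" else 0.0, first_seed))
    truth = pd.DataFrame(truth_rows, columns=["sample", "label", "fraction", "seed"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, recs in samples.items():
            write_pat(recs, out / f"{name}.pat")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return samples, truth
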