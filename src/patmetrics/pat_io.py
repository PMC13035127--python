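"""PAT file I/O, CpG coordinate maps and per-region read matrices.

The PAT format (as emitted by wgbstools) is a tab-separated, read-level
representation of bisulfite sequencing data.  Each row holds::

    chrom    start_cpg_index    pattern    count    [extra columns...]

where ``start_cpg_index`` is the 1-based *global CpG index* of the first
call of the pattern, the pattern is a string over ``{C, T, .}`` (``C`` =
methylated, ``T`` = unmethylated, ``.`` = unknown), and ``count`` is the
number of reads sharing that exact pattern at that position.

Genomic coordinates and CpG indices are linked through a :class:`CpGMap`,
which enumerates forward-strand CG dinucleotides of a reference genome in
genome order, starting at index 1.  Reverse-strand CpGs are not separately
indexed: PAT collapses each CpG/CpG unit to its forward-strand cytosine.

The central analysis object is the :class:`ReadMatrix`: a reads x CpGs
binary matrix with NaN for unobserved calls, materialised for one region.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_PATTERN_ALPHABET = frozenset("CT.")


class PatParseError(ValueError):
    """Raised when a PAT line cannot be parsed; message names the line."""


class EmptyRegionError(ValueError):
    """Raised when a genomic interval contains no mapped CpG."""


@dataclass(frozen=True)
class PatRecord:
    """One PAT row: a methylation pattern shared by ``count`` reads."""

    chrom: str
    start_index: int  # global CpG index of the first call, 1-based
    pattern: str
    count: int = 1
    extra: tuple[str, ...] = ()  # trailing columns, preserved opaquely

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if len(self.pattern) < 1:
            raise ValueError("pattern must be non-empty")
        bad = set(self.pattern) - _PATTERN_ALPHABET
        if bad:
            raise ValueError(f"illegal pattern characters: {sorted(bad)}")

    @property
    def end_index(self) -> int:
        """Global CpG index of the last call (inclusive)."""
        return self.start_index + len(self.pattern) - 1


@dataclass(frozen=True)
class RegionSpec:
    """A region expressed in CpG-index space (1-based, inclusive)."""

    chrom: str
    first: int
    last: int
    genomic_start: int | None = None  # 0-based, half-open, when known
    genomic_end: int | None = None

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(f"first ({self.first}) > last ({self.last})")
        if self.first < 1:
            raise ValueError("CpG indices are 1-based")

    @property
    def n_cpgs(self) -> int:
        return self.last - self.first + 1

    def overlaps(self, other: "RegionSpec") -> bool:
        return self.chrom == other.chrom and not (
            self.last < other.first or other.last < self.first
        )

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.first}-{self.last}"


class CpGMap:
    """Bidirectional map between genomic positions and global CpG indices.

    Backed by a DataFrame with columns ``chrom``, ``pos`` (1-based position
    of the C of a forward-strand CG) and ``index`` (1-based global CpG
    index, strictly increasing in genome order).
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"chrom", "pos", "index"}
        if not required.issubset(table.columns):
            raise ValueError(f"CpG map needs columns {sorted(required)}")
        # an empty map is legal (a sequence with no CG dinucleotides)
        idx = table["index"].to_numpy()
        if not np.all(np.diff(idx) > 0):
            raise ValueError("CpG indices must be strictly increasing")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_cpgs(self) -> int:
        return len(self.table)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CpGMap":
        """Scan a FASTA for forward-strand CG dinucleotides.

        Indices are assigned in the order sequences appear in the file.
        """
        return build_cpg_map(path)

    def position_of(self, index: int) -> tuple[str, int]:
        row = self.table[self.table["index"] == index]
        if row.empty:
            raise KeyError(f"no CpG with index {index}")
        r = row.iloc[0]
        return str(r["chrom"]), int(r["pos"])

    def region_from_genomic(self, chrom: str, start: int, end: int) -> RegionSpec:
        """CpG-index region covering positions in the half-open [start, end).

        ``start``/``end`` follow BED convention (0-based, half-open); a CpG
        at 1-based position p is inside iff start < p <= end, i.e.
        start <= p-1 < end.
        """
        sub = self.table[self.table["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        mask = (pos - 1 >= start) & (pos - 1 < end)
        if not mask.any():
            raise EmptyRegionError(f"no CpGs in {chrom}:[{start},{end})")
        hit = sub.loc[mask, "index"]
        return RegionSpec(
            chrom=chrom,
            first=int(hit.min()),
            last=int(hit.max()),
            genomic_start=start,
            genomic_end=end,
        )


def build_cpg_map(fasta_path: str | Path) -> CpGMap:
    """Build a :class:`CpGMap` from a FASTA file (see CpGMap.from_fasta)."""
    from Bio import SeqIO

    rows: list[tuple[str, int]] = []
    n_seq = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_seq += 1
        seq = str(rec.seq).upper()
        start = 0
        while True:
            hit = seq.find("CG", start)
            if hit < 0:
                break
            rows.append((rec.id, hit + 1))
            start = hit + 1
    if n_seq == 0:
        raise ValueError(f"no sequences in FASTA {fasta_path}")
    table = pd.DataFrame(rows, columns=["chrom", "pos"])
    table["index"] = np.arange(1, len(table) + 1, dtype=np.int64)
    return CpGMap(table)


def region_from_genomic(cpg_map: CpGMap, chrom: str, start: int, end: int) -> RegionSpec:
    """Module-level convenience wrapper around CpGMap.region_from_genomic."""
    return cpg_map.region_from_genomic(chrom, start, end)


# ---------------------------------------------------------------------------
# PAT reading / writing


def _open_text(path: str | Path, mode: str = "rt"):
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def read_pat(
    path: str | Path,
    region: RegionSpec | None = None,
) -> list[PatRecord]:
    """Parse a PAT file (plain or gzip) into records, in file order.

    With a ``region``, only records whose pattern overlaps the region's
    CpG-index range are returned.
    """
    records: list[PatRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PatParseError(
                    f"{path}: line {lineno}: expected >= 4 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, idx_s, pattern, count_s = fields[:4]
            try:
                start_index = int(idx_s)
                count = int(count_s)
            except ValueError as exc:
                raise PatParseError(
                    f"{path}: line {lineno}: non-integer index or count"
                ) from exc
            try:
                rec = PatRecord(
                    chrom=chrom,
                    start_index=start_index,
                    pattern=pattern,
                    count=count,
                    extra=tuple(fields[4:]),
                )
            except ValueError as exc:
                raise PatParseError(f"{path}: line {lineno}: {exc}") from exc
            if region is not None:
                if rec.chrom != region.chrom:
                    continue
                if rec.end_index < region.first or rec.start_index > region.last:
                    continue
            records.append(rec)
    return records


def write_pat(
    records: Iterable[PatRecord],
    path: str | Path,
    aggregate: bool = True,
) -> None:
    """Write records as a PAT file (gzip if the path ends in .gz).

    With ``aggregate`` (default), rows sharing (chrom, start_index, pattern)
    are merged by summing counts — the format's native semantics of "count
    of reads exhibiting that exact pattern".  Extra columns of the first
    occurrence are kept.  Output is sorted by (chrom, start_index, pattern)
    when aggregating, file order otherwise.
    """
    records = list(records)
    if aggregate:
        merged: dict[tuple[str, int, str], list] = {}
        for rec in records:
            key = (rec.chrom, rec.start_index, rec.pattern)
            if key in merged:
                merged[key][0] += rec.count
            else:
                merged[key] = [rec.count, rec.extra]
        rows = [
            PatRecord(chrom=k[0], start_index=k[1], pattern=k[2], count=v[0], extra=v[1])
            for k, v in sorted(merged.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
        ]
    else:
        rows = records
    with _open_text(path, "wt") as fh:
        for rec in rows:
            fields = [rec.chrom, str(rec.start_index), rec.pattern, str(rec.count)]
            fields.extend(rec.extra)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Read matrices


@dataclass
class ReadMatrix:
    """Binary reads x CpGs matrix for one region; NaN marks missing calls."""

    region: RegionSpec
    cells: np.ndarray  # float array, values in {0.0, 1.0, nan}

    @property
    def n_reads(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.cells.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.n_reads == 0

    def transposed(self) -> "ReadMatrix":
        # region metadata is nominal after transposition; kept for shape only
        t = RegionSpec(chrom=self.region.chrom, first=1, last=max(1, self.cells.shape[0]))
        return ReadMatrix(region=t, cells=self.cells.T.copy())

    def complemented(self) -> "ReadMatrix":
        return ReadMatrix(region=self.region, cells=1.0 - self.cells)


_CALL_VALUE = {"C": 1.0, "T": 0.0, ".": np.nan}


def build_read_matrix(
    records: Sequence[PatRecord],
    region: RegionSpec,
    min_overlap: int = 1,
    max_reads: int | None = None,
    seed: int | None = None,
) -> ReadMatrix:
    """Materialise the region's read matrix from PAT records.

    Each record is expanded to ``count`` identical rows.  Calls outside the
    region are dropped; region CpGs a read does not cover, and '.' calls,
    become NaN.  Rows with fewer than ``min_overlap`` observed cells are
    discarded.  If more than ``max_reads`` rows survive, a seeded uniform
    subsample of ``max_reads`` rows is kept (MPCI cost grows quadratically
    with read depth, so a cap can matter at high coverage).

    A region with no surviving reads yields an empty (0 x n_cpgs) matrix;
    metrics computed on it return missing.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    m = region.n_cpgs
    rows: list[np.ndarray] = []
    for rec in records:
        if rec.chrom != region.chrom:
            continue
        if rec.end_index < region.first or rec.start_index > region.last:
            continue
        row = np.full(m, np.nan)
        for k, call in enumerate(rec.pattern):
            gi = rec.start_index + k
            if region.first <= gi <= region.last:
                row[gi - region.first] = _CALL_VALUE[call]
        if np.count_nonzero(~np.isnan(row)) < min_overlap:
            continue
        rows.extend([row] * rec.count)
    if not rows:
        return ReadMatrix(region=region, cells=np.empty((0, m)))
    cells = np.array(rows)
    if max_reads is not None and cells.shape[0] > max_reads:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(cells.shape[0], size=max_reads, replace=False))
        cells = cells[keep]
    return ReadMatrix(region=region, cells=cells)


def read_regions_tsv(path: str | Path) -> list[RegionSpec]:
    """Read regions from a TSV with columns chrom, first_cpg_index, last_cpg_index."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    return [
        RegionSpec(chrom=str(r[cols[0]]), first=int(r[cols[1]]), last=int(r[cols[2]]))
        for _, r in df.iterrows()
    ]


def write_regions_tsv(regions: Sequence[RegionSpec], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "first_cpg_index": [r.first for r in regions],
            "last_cpg_index": [r.last for r in regions],
        }
    )
    df.to_csv(path, sep="\t", index=False)
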