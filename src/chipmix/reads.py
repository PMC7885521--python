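"""Mapped-read containers and I/O.

Reads are represented as 0-based half-open intervals with a strand. The
5' end of a read — the sequencing start, and the anchor for all window
counting and pileup extension downstream — is ``start`` for a ``+`` read
and the exclusive ``end`` coordinate for a ``-`` read.

Two on-disk formats are supported: BAM (via pysam) and "BED-reads", a
6-column BED file (chrom, start, end, name, score, strand) where name and
score are ignored on input and written as ``.`` / ``0``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeTable

log = logging.getLogger(__name__)

_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass
class MappedReadSet:
    """One sample's mapped reads, sorted by (chrom, start).

    ``reads`` is a DataFrame with columns chrom/start/end/strand; the
    chromosome order follows ``genome``. ``total_read_count`` always
    equals the number of retained reads.
    """

    sample_id: str
    reads: pd.DataFrame
    genome: GenomeTable
    dedup_applied: bool = False
    max_per_locus: int | None = None
    n_dropped_unknown_chrom: int = 0

    @property
    def total_read_count(self) -> int:
        return len(self.reads)

    def chrom_reads(self, chrom: str) -> pd.DataFrame:
        return self.reads[self.reads["chrom"] == chrom]

    def five_prime(self) -> np.ndarray:
        """5' coordinate per read: start for +, exclusive end for -."""
        fwd = self.reads["strand"].to_numpy() == "+"
        return np.where(fwd, self.reads["start"].to_numpy(), self.reads["end"].to_numpy())

    def is_sorted(self) -> bool:
        order = {c: i for i, c in enumerate(self.genome.names)}
        key = self.reads["chrom"].map(order).to_numpy()
        start = self.reads["start"].to_numpy()
        if len(key) < 2:
            return True
        d = np.diff(key)
        return bool(np.all((d > 0) | ((d == 0) & (np.diff(start) >= 0))))


def _finalize(sample_id: str, df: pd.DataFrame, genome: GenomeTable,
              n_dropped: int = 0, **meta) -> MappedReadSet:
    order = {c: i for i, c in enumerate(genome.names)}
    df = df.copy()
    df["_key"] = df["chrom"].map(order)
    df = df.sort_values(["_key", "start"], kind="stable").drop(columns="_key")
    df = df.reset_index(drop=True)
    return MappedReadSet(sample_id, df[_COLUMNS], genome,
                         n_dropped_unknown_chrom=n_dropped, **meta)


def from_arrays(sample_id: str, chrom, start, end, strand,
                genome: GenomeTable) -> MappedReadSet:
    """Build a MappedReadSet from parallel arrays (fixture generators, tests)."""
    df = pd.DataFrame({
        "chrom": np.asarray(chrom, dtype=object),
        "start": np.asarray(start, dtype=np.int64),
        "end": np.asarray(end, dtype=np.int64),
        "strand": np.asarray(strand, dtype=object),
    })
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise ValueError("read intervals must satisfy 0 <= start < end")
    return _finalize(sample_id, df, genome)


def load_reads(path, genome: GenomeTable, fmt: str | None = None,
               sample_id: str | None = None, min_mapq: int = 0) -> MappedReadSet:
    """Load mapped reads from BAM or BED-reads.

    Reads on chromosomes absent from ``genome`` are dropped with a warning
    (decoy/alt contigs are common); the drop count is recorded on the
    returned set. No deduplication or other filtering is applied here
    beyond the optional MAPQ threshold for BAM input.
    """
    path = str(path)
    if fmt is None:
        fmt = "BAM" if path.endswith((".bam", ".sam", ".cram")) else "BED-reads"
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].split(".")[0]

    if fmt.upper() == "BAM":
        df, n_dropped = _load_bam(path, genome, min_mapq)
    elif fmt.lower() in ("bed-reads", "bed"):
        df, n_dropped = _load_bed_reads(path, genome)
    else:
        raise ValueError(f"unknown read format {fmt!r}")

    if len(df) == 0:
        raise ValueError(f"no mapped reads in {path}")
    if n_dropped:
        warnings.warn(
            f"{sample_id}: dropped {n_dropped} reads on chromosomes absent "
            "from the genome table", stacklevel=2)
    return _finalize(sample_id, df, genome, n_dropped=n_dropped)


def _load_bed_reads(path, genome: GenomeTable):
    chroms, starts, ends, strands = [], [], [], []
    n_dropped = 0
    known = set(genome.names)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if parts[5] not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {parts[5]!r}")
            if not 0 <= start < end:
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if parts[0] not in known:
                n_dropped += 1
                continue
            chroms.append(parts[0]); starts.append(start)
            ends.append(end); strands.append(parts[5])
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "strand": strands})
    return df, n_dropped


def _load_bam(path, genome: GenomeTable, min_mapq: int):
    chroms, starts, ends, strands = [], [], [], []
    n_dropped = 0
    known = set(genome.names)
    with pysam.AlignmentFile(path, check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name is None:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.reference_name not in known:
                n_dropped += 1
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            end = rec.reference_end
            if end is None:  # no CIGAR: fall back to query length
                end = rec.reference_start + (rec.query_length or 1)
            ends.append(end)
            strands.append("-" if rec.is_reverse else "+")
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "strand": strands})
    return df, n_dropped


def write_bed_reads(rs: MappedReadSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, strand in rs.reads.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t{strand}\n")


def write_bam(rs: MappedReadSet, path) -> None:
    """Write reads as a minimal coordinate-sorted BAM (fixture twin of BED-reads)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in rs.genome.chroms],
    }
    tid = {name: i for i, (name, _) in enumerate(rs.genome.chroms)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (chrom, start, end, strand) in enumerate(rs.reads.itertuples(index=False)):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.reference_id = tid[chrom]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, end - start)]
            a.flag = 16 if strand == "-" else 0
            a.query_sequence = "N" * (end - start)
            bam.write(a)


def deduplicate(rs: MappedReadSet, max_per_locus: int = 1) -> MappedReadSet:
    """Retain at most ``max_per_locus`` reads per (chrom, 5' coordinate, strand).

    Deduplication is per sample, applied before any pooling, so duplicates
    are judged within one sequencing library only. Idempotent.
    """
    if max_per_locus < 1:
        raise ValueError("max_per_locus must be >= 1")
    df = rs.reads
    five = np.where(df["strand"].to_numpy() == "+",
                    df["start"].to_numpy(), df["end"].to_numpy())
    rank = df.groupby([df["chrom"], pd.Series(five, index=df.index),
                       df["strand"]], sort=False).cumcount()
    kept = df[rank < max_per_locus].reset_index(drop=True)
    return replace(rs, reads=kept, dedup_applied=True, max_per_locus=max_per_locus)
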