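"""Fragment-extension pileup and density statistics.

Single-end reads are extended to the average fragment length (150 bp) in
their read direction, and each extended fragment contributes
10^6/library_size to every base it covers, giving reads-per-million
density tracks.  Region means over these tracks drive between-sample
Pearson correlations; summit-aligned averaging gives meta-profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .regions import ChromSizes, Peak

DEFAULT_EXTENSION = 150
DEFAULT_READ_LENGTH = 50


@dataclass(frozen=True)
class ReadRecord:
    chrom: str
    five_prime: int
    strand: str
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")


@dataclass
class DensityTrack:
    data: dict[str, np.ndarray]
    extension_length: int
    library_size: int
    n_reads: int
    n_clipped: int = 0

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


@dataclass(frozen=True)
class RegionDensityVector:
    values: np.ndarray
    sample: str = ""


@dataclass(frozen=True)
class MetaProfile:
    offsets: np.ndarray
    mean_density: np.ndarray
    n_regions: int


def extend_and_pile(
    reads: Sequence[ReadRecord],
    sizes: ChromSizes,
    extension: int = DEFAULT_EXTENSION,
    library_size: int | None = None,
) -> DensityTrack:
    """Strand-aware fragment extension and per-base pileup.

    Plus-strand fragments cover [5', 5'+extension); minus-strand fragments
    run leftward and cover [5'-extension+1, 5'+1).  Fragments are clipped
    at chromosome ends (clip events counted), so total mass equals
    n_reads * extension * 1e6/library_size only in the absence of clipping.
    """
    if library_size is None:
        library_size = len(reads)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if reads and extension < max(r.read_length for r in reads):
        raise ValueError("extension must be at least the read length")
    weight = 1e6 / library_size
    deltas = {name: np.zeros(length + 1) for name, length in sizes.entries.items()}
    n_clipped = 0
    for r in reads:
        length = sizes[r.chrom]
        if r.strand == "+":
            start, end = r.five_prime, r.five_prime + extension
        else:
            start, end = r.five_prime - extension + 1, r.five_prime + 1
        if start < 0 or end > length:
            n_clipped += 1
            start, end = max(start, 0), min(end, length)
        if end > start:
            deltas[r.chrom][start] += weight
            deltas[r.chrom][end] -= weight
    data = {name: np.cumsum(d[:-1]) for name, d in deltas.items()}
    return DensityTrack(data, extension, library_size, n_reads=len(reads), n_clipped=n_clipped)


def region_mean_density(track: DensityTrack, regions: Sequence[Peak], sample: str = "") -> RegionDensityVector:
    """Arithmetic mean density over each region's bases."""
    values = np.empty(len(regions))
    for i, p in enumerate(regions):
        if p.chrom not in track.data:
            raise ValueError(f"region {p.peak_id}: chromosome {p.chrom} absent from track")
        values[i] = track.data[p.chrom][p.interval.start : p.interval.end].mean()
    return RegionDensityVector(values, sample=sample)


def sample_correlation(a: RegionDensityVector, b: RegionDensityVector) -> float:
    """Pearson correlation of two samples' per-region mean densities."""
    x, y = np.asarray(a.values, dtype=float), np.asarray(b.values, dtype=float)
    if len(x) != len(y):
        raise ValueError("density vectors cover different region sets")
    if len(x) < 3:
        raise ValueError("need at least 3 regions for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def metaprofile(track: DensityTrack, peaks: Sequence[Peak], flank: int = 1000) -> MetaProfile:
    """Mean density at each offset in -flank..+flank across all peaks
    aligned at their summits; out-of-bounds positions are excluded."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    width = 2 * flank + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=np.int64)
    for p in peaks:
        values = track.data.get(p.chrom)
        if values is None:
            continue
        lo = max(0, p.summit - flank)
        hi = min(len(values), p.summit + flank + 1)
        off = lo - (p.summit - flank)
        total[off : off + hi - lo] += values[lo:hi]
        count[off : off + hi - lo] += 1
    mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return MetaProfile(np.arange(-flank, flank + 1), mean, n_regions=len(peaks))


# ---------------------------------------------------------------------------
# read I/O
# ---------------------------------------------------------------------------


def read_bed_reads(path: str | Path) -> list[ReadRecord]:
    """BED6 read positions: the 5' end is `start` on + and `end - 1` on -."""
    reads = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{i}: BED6 needs 6 columns")
        start, end, strand = int(fields[1]), int(fields[2]), fields[5]
        reads.append(
            ReadRecord(
                chrom=fields[0],
                five_prime=start if strand == "+" else end - 1,
                strand=strand,
                read_length=end - start,
            )
        )
    return reads


def read_sam_reads(path: str | Path) -> list[ReadRecord]:
    """Mapped reads from a SAM/BAM file (unmapped records skipped)."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            five_prime = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            reads.append(
                ReadRecord(aln.reference_name, five_prime, strand, aln.query_length or DEFAULT_READ_LENGTH)
            )
    return reads


def write_bedgraph(track: DensityTrack, path: str | Path) -> None:
    """Run-length-compressed bedGraph of a density track (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom, values in track.data.items():
            if len(values) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
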