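"""Genomic-interval data model for summit-anchored ChIP-seq peaks.

Coordinates are 0-based, half-open throughout the package.  The peakzilla
dialect (1-based starts and summits) is converted on read and restored on
write, so files round-trip unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

FEATURE_CLASSES = ("promoter", "five_prime_utr", "exon", "intron")
#: classification priority when a summit falls in several annotated features
FEATURE_PRIORITY = FEATURE_CLASSES + ("intergenic",)


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome name -> length (bp)."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.entries.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, chrom: str) -> int:
        return self.entries[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromSizes":
        entries: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{i}: expected two tab-separated columns")
            name = fields[0]
            if name in entries:
                raise ValueError(f"{path}:{i}: duplicate chromosome {name!r}")
            entries[name] = int(fields[1])
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{length}\n" for name, length in self.entries.items())
        )


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval anchored at its maximal-signal summit."""

    interval: GenomicInterval
    summit: int
    score: float
    peak_id: str
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError(
                f"peak {self.peak_id}: summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.peak_id}: negative score {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class FeatureAnnotation:
    """Class-labelled intervals; labels are restricted to FEATURE_CLASSES."""

    records: Sequence[tuple[GenomicInterval, str]]

    def __post_init__(self) -> None:
        for _, label in self.records:
            if label not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {label!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureAnnotation":
        """Four-column TSV: chrom, start, end, class."""
        records = []
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{i}: expected 4 columns")
            records.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3])
            )
        return cls(records)


@dataclass(frozen=True)
class PeakGeneAssignment:
    """Peak linked to its nearest gene TSS.

    ``distance`` is summit minus TSS on the forward genome, negated for
    minus-strand genes, so negative always means upstream of the gene.
    """

    peak_id: str
    gene_id: str
    distance: int
    proximity_class: str
    proximal_threshold: int = 2000

    def __post_init__(self) -> None:
        expected = "proximal" if abs(self.distance) <= self.proximal_threshold else "distal"
        if self.proximity_class != expected:
            raise ValueError(
                f"{self.peak_id}->{self.gene_id}: proximity_class "
                f"{self.proximity_class!r} inconsistent with |distance|="
                f"{abs(self.distance)} at threshold {self.proximal_threshold}"
            )


@dataclass(frozen=True)
class SummitWindow:
    interval: GenomicInterval
    clipped: bool


@dataclass(frozen=True)
class NearestTssResult:
    assignments: list[PeakGeneAssignment]
    genes: list[str]
    unassigned_peak_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# peak I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("summit-table", "peakzilla", "bed")


def read_peaks(
    path: str | Path, dialect: str = "summit-table", sample: str | None = None
) -> list[Peak]:
    """Read a peak table.

    Dialects
    --------
    summit-table
        Tab-separated chrom, start, end, name, summit, score with 0-based
        half-open coordinates and an absolute 0-based summit.
    peakzilla
        Same columns but 1-based inclusive start and 1-based summit, as
        emitted by the peakzilla caller; converted on read.
    bed
        BED6 (chrom, start, end, name, score, strand); the summit is taken
        as the interval midpoint.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    peaks: list[Peak] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            if dialect == "bed":
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"peak_{i}"
                score = float(fields[4]) if len(fields) > 4 else 0.0
                summit = (start + end) // 2
            else:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                summit, score = int(fields[4]), float(fields[5])
                if dialect == "peakzilla":
                    start -= 1
                    summit -= 1
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{i}: malformed peak line: {exc}") from exc
        try:
            interval = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: {exc}") from exc
        if not start <= summit < end:
            raise ValueError(f"{path}:{i}: summit {summit} outside [{start}, {end})")
        peaks.append(
            Peak(interval, summit, score, peak_id=name, sample=sample or "")
        )
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path, dialect: str = "summit-table") -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    for p in peaks:
        if dialect == "bed":
            lines.append(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.peak_id}\t{p.score:g}\t.\n"
            )
        else:
            start = p.interval.start + 1 if dialect == "peakzilla" else p.interval.start
            summit = p.summit + 1 if dialect == "peakzilla" else p.summit
            lines.append(
                f"{p.chrom}\t{start}\t{p.interval.end}\t{p.peak_id}\t{summit}\t{p.score:g}\n"
            )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def summit_window(
    peak: Peak, width: int, sizes: ChromSizes | None = None
) -> SummitWindow:
    """A ``width``-bp interval centred on the peak summit.

    ``width`` must be odd so the window is symmetric.  Windows running off
    either end of the chromosome are clipped and flagged.
    """
    if width <= 0 or width % 2 == 0:
        raise ValueError(f"window width must be odd and positive, got {width}")
    half = width // 2
    start = peak.summit - half
    end = peak.summit + half + 1
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if sizes is not None:
        limit = sizes[peak.chrom]
        if end > limit:
            end, clipped = limit, True
    return SummitWindow(GenomicInterval(peak.chrom, start, end), clipped)


def overlap_fraction(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> tuple[float, np.ndarray]:
    """Fraction of query intervals intersecting >= ``min_overlap`` bp of any
    reference interval, plus the per-query hit vector."""
    if len(query) == 0:
        raise ValueError("overlap fraction undefined for an empty query set")
    trees: dict[str, IntervalTree] = {}
    for iv in reference:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    hits = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                hits[i] = True
                break
    return float(hits.mean()), hits


def shuffle_regions(peaks: Sequence[Peak], sizes: ChromSizes, seed: int) -> list[Peak]:
    """Width-preserving uniform relocation of each peak within its chromosome.

    The null model behind all enrichment statistics: placements are
    independent, may overlap each other or the original peak, and the
    summit moves to the new region's centre.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for p in peaks:
        if p.chrom not in sizes:
            raise ValueError(f"peak {p.peak_id}: chromosome {p.chrom} not in sizes")
        length = sizes[p.chrom]
        if p.width > length:
            raise ValueError(
                f"peak {p.peak_id}: width {p.width} exceeds chromosome length {length}"
            )
        start = int(rng.integers(0, length - p.width + 1))
        interval = GenomicInterval(p.chrom, start, start + p.width)
        shuffled.append(
            replace(p, interval=interval, summit=start + p.width // 2)
        )
    return shuffled


def nearest_tss_assign(
    peaks: Sequence[Peak],
    tss: Sequence[TssRecord],
    proximal_threshold: int = 2000,
) -> NearestTssResult:
    """Assign each peak to the gene with the nearest TSS on its chromosome.

    Ties (equidistant TSSs) resolve to the lexicographically smallest
    gene_id.  Peaks on chromosomes without any TSS are reported unassigned.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS list")
    by_chrom: dict[str, list[TssRecord]] = {}
    for rec in tss:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    positions = {
        chrom: np.array([r.tss for r in sorted(recs, key=lambda r: r.tss)])
        for chrom, recs in by_chrom.items()
    }
    sorted_recs = {
        chrom: sorted(recs, key=lambda r: r.tss) for chrom, recs in by_chrom.items()
    }

    assignments: list[PeakGeneAssignment] = []
    unassigned: list[str] = []
    genes: list[str] = []
    seen: set[str] = set()
    for p in peaks:
        if p.chrom not in positions:
            unassigned.append(p.peak_id)
            continue
        pos = positions[p.chrom]
        recs = sorted_recs[p.chrom]
        idx = int(np.searchsorted(pos, p.summit))
        best = min(
            abs(p.summit - pos[j]) for j in (idx - 1, idx) if 0 <= j < len(pos)
        )
        candidates = [r for r in recs if abs(p.summit - r.tss) == best]
        rec = min(candidates, key=lambda r: r.gene_id)
        distance = p.summit - rec.tss
        if rec.strand == "-":
            distance = -distance
        cls = "proximal" if abs(distance) <= proximal_threshold else "distal"
        assignments.append(
            PeakGeneAssignment(p.peak_id, rec.gene_id, distance, cls, proximal_threshold)
        )
        if rec.gene_id not in seen:
            seen.add(rec.gene_id)
            genes.append(rec.gene_id)
    return NearestTssResult(assignments, genes, unassigned)


def classify_feature(
    peaks: Sequence[Peak], annotation: FeatureAnnotation
) -> dict[str, float]:
    """Per-class peak fractions over promoter/5'UTR/exon/intron/intergenic.

    Each peak is classified by its summit position; when the summit lies in
    several annotated features the highest-priority class wins
    (promoter > five_prime_utr > exon > intron), and summits outside every
    feature are intergenic.  Fractions sum to 1.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks to classify")
    trees: dict[str, dict[str, IntervalTree]] = {c: {} for c in FEATURE_CLASSES}
    for iv, label in annotation.records:
        trees[label].setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    counts = dict.fromkeys(FEATURE_PRIORITY, 0)
    for p in peaks:
        assigned = "intergenic"
        for cls in FEATURE_CLASSES:
            tree = trees[cls].get(p.chrom)
            if tree is not None and tree.overlaps_point(p.summit):
                assigned = cls
                break
        counts[assigned] += 1
    n = len(peaks)
    return {cls: counts[cls] / n for cls in FEATURE_PRIORITY}
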