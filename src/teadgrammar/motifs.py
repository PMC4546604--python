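"""Mismatch-tolerant consensus motif scanning and homotypic pair detection.

The TEAD consensus CATTCC (reverse complement GGAATG) is the default
query.  Scanning slides the consensus and its reverse complement over the
sequence and reports every offset within the mismatch budget; ``N`` bases
never match.  Pair detection then looks for two same-orientation
occurrences separated by a short spacer — the homotypic "double motif"
configuration, of which the 3-bp spacer is the biologically enriched one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

from .regions import ChromSizes, Peak, summit_window

TEAD_CONSENSUS = "CATTCC"
DEFAULT_WINDOW = 151  # average genomic fragment length, centred on the summit

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# A..0 C..1 G..2 T..3 N..4; 4 compares unequal to every consensus code
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusQuery:
    consensus: str = TEAD_CONSENSUS
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise ValueError("consensus must be at least 4 bp")
        if any(b not in "ACGT" for b in self.consensus):
            raise ValueError(f"consensus {self.consensus!r} must be over ACGT")
        if not 0 <= self.max_mismatch < len(self.consensus):
            raise ValueError("max_mismatch must satisfy 0 <= k < consensus length")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifMatch:
    offset: int
    strand: str
    n_mismatch: int


@dataclass(frozen=True)
class MotifPair:
    first: MotifMatch
    second: MotifMatch
    spacer: int
    same_orientation: bool = True


@dataclass(frozen=True)
class SpacerSpectrum:
    """Per-spacer counts of regions containing >= 1 same-orientation pair."""

    counts: Mapping[int, int]
    n_regions: int
    max_spacer: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "max_spacer", max(self.counts, default=0))
        expected = set(range(self.max_spacer + 1))
        if set(self.counts) != expected:
            raise ValueError("spacer counts must cover 0..max_spacer contiguously")
        if any(c > self.n_regions or c < 0 for c in self.counts.values()):
            raise ValueError("per-spacer counts must lie in [0, n_regions]")

    def fraction(self, spacer: int) -> float:
        return self.counts[spacer] / self.n_regions


def _encode(sequence: str) -> np.ndarray:
    codes = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sequence[int(np.argmax(codes < 0))]
        raise ValueError(f"illegal character {bad!r} in sequence (expected ACGTN)")
    return codes


def _mismatch_counts(codes: np.ndarray, motif: str) -> np.ndarray:
    """Hamming distance of every window of len(motif) to the motif."""
    m = len(motif)
    n_win = len(codes) - m + 1
    mot = _ENCODE[np.frombuffer(motif.encode("ascii"), dtype=np.uint8)]
    counts = np.zeros(n_win, dtype=np.int16)
    for j in range(m):
        counts += codes[j : j + n_win] != mot[j]
    return counts


def scan_consensus(sequence: str, query: ConsensusQuery) -> list[MotifMatch]:
    """All occurrences of the consensus on either strand within the
    mismatch budget, sorted by offset then strand (+ before -).

    A minus-strand match at offset ``i`` means the reverse complement of
    the consensus occurs at ``sequence[i:i+m]``.  Sequences shorter than
    the consensus yield an empty list.
    """
    m = len(query)
    codes = _encode(sequence)
    if len(codes) < m:
        return []
    matches = []
    for strand, motif in (("+", query.consensus), ("-", reverse_complement(query.consensus))):
        mism = _mismatch_counts(codes, motif)
        for off in np.flatnonzero(mism <= query.max_mismatch):
            matches.append(MotifMatch(int(off), strand, int(mism[off])))
    matches.sort(key=lambda mm: (mm.offset, mm.strand))
    return matches


def find_pairs(
    matches: Sequence[MotifMatch], motif_len: int, max_spacer: int = 30
) -> list[MotifPair]:
    """All ordered same-strand pairs with spacer in [0, max_spacer].

    The spacer is measured between the occurrences in plus-strand
    coordinates (end of the first to start of the second) regardless of
    which strand the pair sits on, so a minus-strand double qualifies the
    same way as a plus-strand one.  Overlapping occurrences never pair.
    """
    pairs = []
    for i, first in enumerate(matches):
        for second in matches[i + 1 :]:
            if second.strand != first.strand:
                continue
            if second.offset <= first.offset:
                continue
            spacer = second.offset - (first.offset + motif_len)
            if 0 <= spacer <= max_spacer:
                pairs.append(MotifPair(first, second, spacer))
    return pairs


def spacer_spectrum(
    regions: Sequence[str], query: ConsensusQuery, max_spacer: int = 30
) -> SpacerSpectrum:
    """For each spacer length, the number of regions containing at least
    one same-orientation double motif at exactly that spacing.  A region
    with doubles at several spacings counts toward each of them."""
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    counts = {s: 0 for s in range(max_spacer + 1)}
    for seq in regions:
        matches = scan_consensus(seq, query)
        seen = {p.spacer for p in find_pairs(matches, len(query), max_spacer)}
        for s in seen:
            counts[s] += 1
    return SpacerSpectrum(counts, n_regions=len(regions))


# ---------------------------------------------------------------------------
# sequence extraction helpers
# ---------------------------------------------------------------------------


def load_genome(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {name: uppercase sequence}."""
    fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def extract_summit_windows(
    genome: Mapping[str, str],
    peaks: Sequence[Peak],
    width: int = DEFAULT_WINDOW,
) -> list[str]:
    """Summit-centred sequence windows for a peak set (clipped at
    chromosome ends)."""
    sizes = ChromSizes({name: len(seq) for name, seq in genome.items()})
    windows = []
    for p in peaks:
        if p.chrom not in genome:
            raise ValueError(f"peak {p.peak_id}: no sequence for chromosome {p.chrom}")
        win = summit_window(p, width, sizes).interval
        windows.append(genome[p.chrom][win.start : win.end])
    return windows
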