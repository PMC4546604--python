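"""Synthetic data with the statistical structure the pipeline assumes.

``gen_genome_with_peaks`` emits a random genome carrying non-overlapping
summit-anchored peaks whose windows contain planted consensus motifs:
singles at a controlled rate, same-orientation doubles with a controlled
spacer distribution, and a genome-wide background motif density that sets
the hit rate of random control windows.  The defaults reproduce the study
conditions of the TEAD-motif analysis: 151-bp windows, an 86% single-motif
region rate, an 18% spacer-3 double rate, and a ~37% rate on shuffled
controls (a ~2.3-fold enrichment).

Rates are targets for the *scanned* fraction: the generator computes the
probability that a random window already contains an incidental consensus
match (from base composition alone, treating window offsets as
independent) and calibrates its planting probabilities so the totals come
out at the requested rates.  A planting ledger records every planted
motif so tests can separate planted from incidental occurrences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import ReadRecord
from .motifs import reverse_complement, TEAD_CONSENSUS
from .regions import ChromSizes, GenomicInterval, Peak

_BASES = "ACGT"
_BYTE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MotifPlantingConfig:
    """Planting targets for a synthetic peak-sequence population.

    single_rate / double_rate / background_rate are target fractions of
    151-bp windows (peak windows for the first two, random windows for the
    last) containing >= 1 consensus match / >= 1 same-orientation pair,
    under scanning with ``consensus`` and ``max_mismatch``.
    """

    single_rate: float = 0.86
    double_rate: float = 0.18
    spacer_distribution: Mapping[int, float] = field(default_factory=lambda: {3: 1.0})
    strand_probability: float = 0.5
    background_gc: float = 0.5
    background_rate: float = 0.37
    consensus: str = TEAD_CONSENSUS
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        for name in ("single_rate", "double_rate", "background_rate", "strand_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must lie in (0,1)")
        total = sum(self.spacer_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spacer distribution sums to {total}, not 1")
        if any(s < 0 for s in self.spacer_distribution):
            raise ValueError("spacer lengths must be >= 0")
        if self.double_rate > self.single_rate:
            raise ValueError("double_rate cannot exceed single_rate (a pair contains singles)")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Two-class tumor-expression simulation.

    Defaults mirror the glioblastoma signature setting: 528 samples and a
    70-gene signature whose genes shift by ``effect_size`` standard
    deviations (of the per-gene log2 noise) between activity classes.
    """

    n_genes: int = 500
    n_samples: int = 528
    signature_size: int = 70
    effect_size: float = 1.0
    noise_sd: float = 1.0
    class_fraction: float = 0.5
    seed: int = 0
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.signature_size) <= 0:
            raise ValueError("n_genes, n_samples and signature_size must be positive")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size cannot exceed n_genes")
        if not 0 < self.class_fraction < 1:
            raise ValueError("class_fraction must lie in (0,1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass(frozen=True)
class PlantedMotif:
    chrom: str
    position: int  # genome coordinate of the occurrence start
    strand: str
    kind: str  # 'single' | 'pair_first' | 'pair_second' | 'background'


@dataclass(frozen=True)
class PeakPlanting:
    peak_id: str
    motifs: tuple[PlantedMotif, ...]
    pair_spacer: int | None  # set when the peak carries a planted double

    @property
    def has_planted(self) -> bool:
        return len(self.motifs) > 0


@dataclass(frozen=True)
class PlantingLedger:
    peaks: dict[str, PeakPlanting]
    background: list[PlantedMotif]
    p_incidental: float  # analytic incidental window hit rate

    def planted_single_fraction(self) -> float:
        return sum(p.has_planted for p in self.peaks.values()) / len(self.peaks)

    def planted_pair_fraction(self) -> float:
        return sum(p.pair_spacer is not None for p in self.peaks.values()) / len(self.peaks)


# ---------------------------------------------------------------------------
# analytic background calibration
# ---------------------------------------------------------------------------


def _base_probs(gc: float) -> dict[str, float]:
    return {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}


def _offset_match_prob(consensus: str, max_mismatch: int, gc: float) -> float:
    """P(a random window of len(consensus) matches either strand within the
    mismatch budget), treating the two strands as independent events."""
    probs = _base_probs(gc)

    def one_strand(motif: str) -> float:
        # distribution of mismatch count: Poisson-binomial DP
        dist = np.zeros(len(motif) + 1)
        dist[0] = 1.0
        for base in motif:
            p_mis = 1 - probs[base]
            nxt = np.zeros_like(dist)
            nxt[1:] = dist[:-1] * p_mis
            nxt += dist * (1 - p_mis)
            dist = nxt
        return float(dist[: max_mismatch + 1].sum())

    p_f = one_strand(consensus)
    p_r = one_strand(reverse_complement(consensus))
    return 1 - (1 - p_f) * (1 - p_r)


def incidental_window_rate(config: MotifPlantingConfig, window: int) -> float:
    """Analytic P(a random ``window``-bp sequence contains >= 1 consensus
    occurrence), under independence across offsets (adequate for a short
    non-repetitive consensus)."""
    n_offsets = window - len(config.consensus) + 1
    if n_offsets <= 0:
        return 0.0
    p_off = _offset_match_prob(config.consensus, config.max_mismatch, config.background_gc)
    return 1 - (1 - p_off) ** n_offsets


def _calibrate(config: MotifPlantingConfig, window: int) -> tuple[float, float, float]:
    """(p_single_plant, bg_start_prob, p_incidental) hitting the target rates."""
    m = len(config.consensus)
    p_inc = incidental_window_rate(config, window)
    # peaks without a planted pair must reach the residual single rate
    if config.double_rate >= 1.0 or config.single_rate == 0.0:
        # nothing (extra) to plant; with a zero target no singles are planted
        # even though incidental matches keep the scanned rate at p_inc
        p_single = 0.0
    else:
        residual = (1 - config.single_rate) / (1 - config.double_rate)
        p_single = 1 - residual / (1 - p_inc)
        if p_single < 0:
            raise ValueError(
                f"single_rate {config.single_rate} is below the incidental "
                f"background floor {1 - (1 - config.double_rate) * (1 - p_inc):.3f}"
            )
        p_single = min(p_single, 1.0)
    # background density so random windows hit at background_rate
    if config.background_rate <= p_inc:
        if config.background_rate > 0 and config.background_rate < p_inc:
            warnings.warn(
                f"background_rate {config.background_rate} below the incidental "
                f"rate {p_inc:.3f}; planting no background motifs",
                stacklevel=2,
            )
        q = 0.0
    else:
        n_offsets = window - m + 1
        keep = (1 - config.background_rate) / (1 - p_inc)
        q = 1 - keep ** (1 / n_offsets)
    return p_single, q, p_inc


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_genome_with_peaks(
    sizes: ChromSizes,
    n_peaks: int,
    peak_width: int = 151,
    config: MotifPlantingConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], list[Peak], PlantingLedger]:
    """Random genome + non-overlapping planted peaks + ground-truth ledger.

    Peak intervals coincide with their 151-bp summit windows (odd width,
    summit at the centre), placed uniformly without overlap within each
    chromosome.  Peak scores are drawn log-normal as a stand-in for caller
    scores.  Planted motif bases are written after the background, so they
    are never mutated; the background may still produce incidental matches,
    which the ledger lets callers separate out.
    """
    if config is None:
        config = MotifPlantingConfig()
    if peak_width % 2 == 0 or peak_width <= 0:
        raise ValueError("peak_width must be odd and positive")
    m = len(config.consensus)
    max_span = 2 * m + max(config.spacer_distribution, default=0)
    if max_span > peak_width:
        raise ValueError("peak_width too small for the widest planted double motif")
    rng = np.random.default_rng(seed)
    p_single, q_bg, p_inc = _calibrate(config, peak_width)
    probs = _base_probs(config.background_gc)
    p_vec = np.array([probs[b] for b in _BASES])

    # ---- allocate peaks to chromosomes proportionally to length
    chroms = list(sizes.entries)
    lengths = np.array([sizes[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(n_peaks, lengths / lengths.sum())
    for c, k in zip(chroms, alloc):
        if k * peak_width > sizes[c]:
            raise ValueError(f"cannot pack {k} peaks of {peak_width} bp into {c}")

    genome_bytes: dict[str, np.ndarray] = {}
    peaks: list[Peak] = []
    peak_plantings: dict[str, PeakPlanting] = {}
    background: list[PlantedMotif] = []
    fwd = np.frombuffer(config.consensus.encode(), dtype=np.uint8)
    rev = np.frombuffer(reverse_complement(config.consensus).encode(), dtype=np.uint8)
    peak_counter = 0

    for chrom, k in zip(chroms, alloc):
        length = sizes[chrom]
        if np.allclose(p_vec, 0.25):
            codes = rng.integers(0, 4, size=length)
        else:
            codes = rng.choice(4, size=length, p=p_vec)
        seq = _BYTE_LUT[codes.astype(np.intp)].copy()
        occupied = np.zeros(length, dtype=bool)

        # non-overlapping uniform placement: order statistics + spacing trick
        slack = length - k * peak_width
        starts = np.sort(rng.integers(0, slack + 1, size=k)) + np.arange(k) * peak_width

        for start in starts:
            start = int(start)
            peak_counter += 1
            peak_id = f"peak_{peak_counter:05d}"
            summit = start + peak_width // 2
            score = float(rng.lognormal(mean=3.0, sigma=0.5))
            peaks.append(
                Peak(GenomicInterval(chrom, start, start + peak_width), summit, score, peak_id)
            )
            occupied[start : start + peak_width] = True

            planted: list[PlantedMotif] = []
            pair_spacer: int | None = None
            strand = "-" if rng.random() < config.strand_probability else "+"
            motif_bytes = rev if strand == "-" else fwd
            if rng.random() < config.double_rate:
                spacers = sorted(config.spacer_distribution)
                weights = [config.spacer_distribution[s] for s in spacers]
                pair_spacer = int(rng.choice(spacers, p=weights))
                span = 2 * m + pair_spacer
                off = int(rng.integers(0, peak_width - span + 1))
                for j, kind in ((0, "pair_first"), (m + pair_spacer, "pair_second")):
                    pos = start + off + j
                    seq[pos : pos + m] = motif_bytes
                    planted.append(PlantedMotif(chrom, pos, strand, kind))
            elif rng.random() < p_single:
                off = int(rng.integers(0, peak_width - m + 1))
                pos = start + off
                seq[pos : pos + m] = motif_bytes
                planted.append(PlantedMotif(chrom, pos, strand, "single"))
            peak_plantings[peak_id] = PeakPlanting(peak_id, tuple(planted), pair_spacer)

        # genome-wide background motifs outside peak windows
        if q_bg > 0:
            n_bg = rng.binomial(length - m + 1, q_bg)
            planted_bg = 0
            attempts = 0
            while planted_bg < n_bg and attempts < 20 * n_bg + 100:
                batch = rng.integers(0, length - m + 1, size=max(n_bg - planted_bg, 16))
                for pos in batch:
                    attempts += 1
                    pos = int(pos)
                    if occupied[pos : pos + m].any():
                        continue
                    strand = "-" if rng.random() < config.strand_probability else "+"
                    seq[pos : pos + m] = rev if strand == "-" else fwd
                    occupied[pos : pos + m] = True
                    background.append(PlantedMotif(chrom, pos, strand, "background"))
                    planted_bg += 1
                    if planted_bg == n_bg:
                        break
        genome_bytes[chrom] = seq

    genome = {c: b.tobytes().decode("ascii") for c, b in genome_bytes.items()}
    ledger = PlantingLedger(peak_plantings, background, p_inc)
    return genome, peaks, ledger


def gen_reads(
    peaks: Sequence[Peak],
    enrichment: float,
    n_reads: int,
    fragment_length: int,
    sizes: ChromSizes,
    seed: int = 0,
    read_length: int = 50,
) -> list[ReadRecord]:
    """Strand-balanced reads from a uniform background plus summit-centred
    Gaussian components.

    ``enrichment`` is the expected fragment-centre density at an average
    summit relative to the background density; 1 means a purely uniform
    library.  Fragment centres in the peak component are Normal(summit,
    fragment length / 2), and reads are apportioned among peaks
    proportionally to peak score, so strong and weak peaks differ in
    occupancy the way replicate ChIP libraries agree on.
    """
    if n_reads < 0 or fragment_length <= 0 or enrichment < 1:
        raise ValueError("need n_reads >= 0, fragment_length > 0, enrichment >= 1")
    if n_reads == 0:
        return []
    rng = np.random.default_rng(seed)
    chroms = list(sizes.entries)
    lengths = np.array([sizes[c] for c in chroms], dtype=float)
    genome_size = lengths.sum()
    sigma = fragment_length / 2

    if enrichment > 1 and len(peaks) > 0:
        ratio = (enrichment - 1) * len(peaks) * sigma * np.sqrt(2 * np.pi) / genome_size
        w_peak = ratio / (1 + ratio)
    else:
        w_peak = 0.0

    records: list[ReadRecord] = []
    from_peak = rng.random(n_reads) < w_peak
    n_peak_reads = int(from_peak.sum())
    # peak component, apportioned by peak score (uniform if all scores zero)
    if n_peak_reads:
        scores = np.array([p.score for p in peaks], dtype=float)
        weights = scores / scores.sum() if scores.sum() > 0 else None
        which = rng.choice(len(peaks), size=n_peak_reads, p=weights)
        centers = rng.normal(
            [peaks[i].summit for i in which], sigma
        ).round().astype(int)
        for i, c in zip(which, centers):
            records.append(_read_at(peaks[i].chrom, int(c), fragment_length, sizes, rng, read_length))
    # background component
    n_bg = n_reads - n_peak_reads
    if n_bg:
        chrom_idx = rng.choice(len(chroms), size=n_bg, p=lengths / genome_size)
        for ci in chrom_idx:
            c = int(rng.integers(0, sizes[chroms[ci]]))
            records.append(_read_at(chroms[ci], c, fragment_length, sizes, rng, read_length))
    return records


def _read_at(
    chrom: str,
    center: int,
    fragment_length: int,
    sizes: ChromSizes,
    rng: np.random.Generator,
    read_length: int,
) -> ReadRecord:
    strand = "+" if rng.random() < 0.5 else "-"
    half = fragment_length // 2
    five_prime = center - half if strand == "+" else center + half - 1
    five_prime = int(np.clip(five_prime, 0, sizes[chrom] - 1))
    return ReadRecord(chrom, five_prime, strand, read_length)


def gen_expression(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Two-class expression matrix (genes x samples, FPKM-like linear
    units), true per-sample class labels, and the planted signature genes.

    Per-gene log2 expression is Gaussian around a gene baseline; signature
    genes gain ``effect_size * noise_sd`` log2 units in "high" samples.
    Pure function of the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    n_high = int(round(config.class_fraction * config.n_samples))
    if n_high == 0 or n_high == config.n_samples:
        raise ValueError("class_fraction yields a single class at this n_samples")
    label_values = np.array(["low"] * config.n_samples, dtype=object)
    label_values[rng.permutation(config.n_samples)[:n_high]] = "high"
    labels = pd.Series(label_values, index=samples, name="label")

    signature = sorted(rng.choice(genes, size=config.signature_size, replace=False))
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    log_expr = baselines[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_samples)
    )
    sig_mask = np.isin(genes, signature)
    high_mask = (labels == "high").to_numpy()
    log_expr[np.ix_(sig_mask, high_mask)] += config.effect_size * config.noise_sd
    matrix = pd.DataFrame(np.exp2(log_expr), index=genes, columns=samples)
    return matrix, labels, list(signature)


# ---------------------------------------------------------------------------
# FASTA output
# ---------------------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path: str | Path, line_width: int = 80) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    seqio_write(records, str(path), "fasta")
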