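"""Enrichment statistics against shuffled-region nulls.

All tests are one-sided exact hypergeometric upper tails: the pooled
observed + control regions form the population, hit regions the successes,
and the observed set the draw.  Tail sums are evaluated in log space
(stable out to populations of ~10^6 and p-values far below the smallest
normal float).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .motifs import ConsensusQuery, extract_summit_windows, spacer_spectrum, scan_consensus, SpacerSpectrum, DEFAULT_WINDOW
from .regions import ChromSizes, Peak, shuffle_regions, summit_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs control hit-region counts with fold and exact p."""

    n_obs: int
    x_obs: int
    n_ctrl: int
    x_ctrl: int
    fold: float  # NaN when the control rate is zero (fold undefined)
    p_value: float
    log10_p: float

    @classmethod
    def from_counts(cls, x_obs: int, n_obs: int, x_ctrl: int, n_ctrl: int) -> "EnrichmentResult":
        if not (0 <= x_obs <= n_obs and 0 <= x_ctrl <= n_ctrl):
            raise ValueError("hit counts must lie within their region counts")
        rate_obs = x_obs / n_obs
        rate_ctrl = x_ctrl / n_ctrl
        fold = rate_obs / rate_ctrl if x_ctrl > 0 else float("nan")
        log_p = hypergeom_upper_tail(
            x_obs, n_obs, x_obs + x_ctrl, n_obs + n_ctrl, log=True
        )
        return cls(
            n_obs, x_obs, n_ctrl, x_ctrl, fold,
            p_value=float(np.exp(log_p)),
            log10_p=float(log_p / np.log(10)),
        )


@dataclass(frozen=True)
class SpacerEnrichment:
    """Per-spacer enrichment of double motifs, tested two ways: against the
    shuffled control spectrum, and against the pooled hits at every other
    spacer length within the observed set."""

    vs_control: Mapping[int, EnrichmentResult]
    vs_other_spacers: Mapping[int, EnrichmentResult]


@dataclass(frozen=True)
class ConservationProfile:
    positions: np.ndarray
    mean_score: np.ndarray
    n_covered: np.ndarray
    n_regions: int


def hypergeom_upper_tail(x: int, n: int, X: int, N: int, log: bool = False) -> float:
    """P(K >= x) for K ~ Hypergeometric(N population, X successes, n drawn).

    Exact log-space tail; returns the probability, or its natural log when
    ``log`` is set (needed for the astronomically small p-values typical of
    motif enrichment).
    """
    if not (0 <= X <= N and 0 <= n <= N and 0 <= x <= n):
        raise ValueError(
            f"inconsistent hypergeometric parameters x={x}, n={n}, X={X}, N={N}"
        )
    log_p = float(hypergeom.logsf(x - 1, N, X, n))
    return log_p if log else float(np.exp(log_p))


def motif_enrichment(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    query: ConsensusQuery,
    sizes: ChromSizes,
    seed: int,
    n_shuffles: int = 1,
    window: int = DEFAULT_WINDOW,
) -> EnrichmentResult:
    """Fraction of summit windows containing >= 1 consensus occurrence,
    against the same statistic on chromosome-shuffled control regions.

    ``n_shuffles`` control sets are pooled; the default single set mirrors
    the one-control design of the original analysis.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    x_obs = count_hit_regions(extract_summit_windows(genome, peaks, window), query)
    rng = np.random.default_rng(seed)
    x_ctrl = n_ctrl = 0
    for _ in range(n_shuffles):
        shuffled = shuffle_regions(peaks, sizes, int(rng.integers(0, 2**31)))
        x_ctrl += count_hit_regions(extract_summit_windows(genome, shuffled, window), query)
        n_ctrl += len(shuffled)
    return EnrichmentResult.from_counts(x_obs, len(peaks), x_ctrl, n_ctrl)


def count_hit_regions(windows: Sequence[str], query: ConsensusQuery) -> int:
    """Number of sequences with at least one consensus occurrence (region-level
    presence is boolean, so palindromic double-strand hits cannot inflate it)."""
    return sum(1 for seq in windows if scan_consensus(seq, query))


def spacer_enrichment(obs: SpacerSpectrum, ctrl: SpacerSpectrum) -> SpacerEnrichment:
    if set(obs.counts) != set(ctrl.counts):
        raise ValueError("observed and control spectra cover different spacer domains")
    vs_control = {
        s: EnrichmentResult.from_counts(
            obs.counts[s], obs.n_regions, ctrl.counts[s], ctrl.n_regions
        )
        for s in obs.counts
    }
    n_spacers = len(obs.counts)
    vs_other = {}
    for s in obs.counts:
        pooled_hits = sum(c for s2, c in obs.counts.items() if s2 != s)
        pooled_n = (n_spacers - 1) * obs.n_regions
        vs_other[s] = EnrichmentResult.from_counts(
            obs.counts[s], obs.n_regions, pooled_hits, pooled_n
        )
    return SpacerEnrichment(vs_control, vs_other)


def geneset_enrichment(
    selected: Sequence[str],
    universe: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    fdr: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the selected
    genes, relative to the universe.  Term genes outside the universe are
    dropped (count logged).  Raw p-values by default; ``fdr`` adds a
    Benjamini-Hochberg column."""
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    selected_set = set(selected) & universe_set
    N, n = len(universe_set), len(selected_set)
    rows = []
    n_dropped = 0
    for term, genes in sets.items():
        term_genes = set(genes)
        n_dropped += len(term_genes - universe_set)
        term_genes &= universe_set
        K = len(term_genes)
        k = len(term_genes & selected_set)
        fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
        rows.append(
            {
                "term_id": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fold": fold,
                "p_value": hypergeom_upper_tail(k, n, K, N),
            }
        )
    if n_dropped:
        logger.info("geneset_enrichment: dropped %d term genes absent from universe", n_dropped)
    df = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def conservation_profile(
    regions: Sequence[Peak],
    track: Mapping[str, np.ndarray],
    flank: int,
) -> ConservationProfile:
    """Per-position mean of a per-base score track over all regions aligned
    at their summits (offsets -flank..+flank).  NaN scores and positions
    beyond chromosome ends are excluded from the means."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    width = 2 * flank + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=np.int64)
    for p in regions:
        values = track.get(p.chrom)
        if values is None:
            continue
        lo = max(0, p.summit - flank)
        hi = min(len(values), p.summit + flank + 1)
        if hi <= lo:
            continue
        segment = np.asarray(values[lo:hi], dtype=float)
        off = lo - (p.summit - flank)
        ok = np.isfinite(segment)
        total[off : off + len(segment)][ok] += segment[ok]
        count[off : off + len(segment)][ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ConservationProfile(
        positions=np.arange(-flank, flank + 1),
        mean_score=mean,
        n_covered=count,
        n_regions=len(regions),
    )


# ---------------------------------------------------------------------------
# track and gene-set I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: term, description, genes... (tab-separated)."""
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: GMT lines need term, description, >=1 gene")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def read_bedgraph(path: str | Path, sizes: ChromSizes) -> dict[str, np.ndarray]:
    """bedGraph -> per-chromosome float arrays (NaN where uncovered)."""
    track = {name: np.full(length, np.nan) for name, length in sizes.entries.items()}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "#", "browser")):
            continue
        chrom, start, end, value = line.split("\t")[:4]
        if chrom in track:
            track[chrom][int(start) : int(end)] = float(value)
    return track


def read_wiggle(path: str | Path, sizes: ChromSizes) -> dict[str, np.ndarray]:
    """fixedStep wiggle -> per-chromosome float arrays (NaN where uncovered)."""
    track = {name: np.full(length, np.nan) for name, length in sizes.entries.items()}
    chrom, pos, step, span = None, 0, 1, 1
    for line in Path(path).read_text().splitlines():
        if line.startswith("fixedStep"):
            attrs = dict(tok.split("=") for tok in line.split()[1:])
            chrom = attrs["chrom"]
            pos = int(attrs["start"]) - 1  # wiggle is 1-based
            step = int(attrs.get("step", 1))
            span = int(attrs.get("span", 1))
        elif line.strip() and chrom is not None:
            track[chrom][pos : pos + span] = float(line)
            pos += step
    return track
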