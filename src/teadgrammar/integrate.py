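"""Threshold rules linking binding to expression.

Differential expression after knockdown is judged across four pairwise
knockdown-vs-control comparisons: a gene qualifies when every comparison
is significant (adjusted p <= 1e-5), all four agree in direction, and the
fold change reaches 2-fold in at least one comparison and 1.2-fold in the
other three.  Differential binding uses adjusted p <= 1e-5, >= 2-fold
enrichment, and reference-sample density below 100 normalized reads per
kilobase.  Fold changes are linear magnitudes (>= 1) with an explicit
down/up direction; the statistics themselves (DESeq-style adjusted
p-values) are inputs, not recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .regions import PeakGeneAssignment

N_COMPARISONS = 4


@dataclass(frozen=True)
class ComparisonStat:
    gene_id: str
    folds: tuple[float, ...]  # linear fold magnitudes, all >= 0
    padj: tuple[float, ...]
    directions: tuple[str, ...]  # 'down' / 'up' per comparison

    def __post_init__(self) -> None:
        if not len(self.folds) == len(self.padj) == len(self.directions) == N_COMPARISONS:
            raise ValueError(f"gene {self.gene_id}: need exactly {N_COMPARISONS} comparisons")
        if any(f <= 0 for f in self.folds):
            raise ValueError(f"gene {self.gene_id}: fold changes must be positive")
        if any(not 0 <= p <= 1 for p in self.padj):
            raise ValueError(f"gene {self.gene_id}: adjusted p-values must lie in [0,1]")
        if any(d not in ("down", "up") for d in self.directions):
            raise ValueError(f"gene {self.gene_id}: directions must be 'down' or 'up'")

    @classmethod
    def from_ratios(cls, gene_id: str, ratios: Sequence[float], padj: Sequence[float]) -> "ComparisonStat":
        """Build from knockdown/control expression ratios: ratio < 1 is
        down-regulation, stored as the control/knockdown magnitude."""
        folds, directions = [], []
        for r in ratios:
            if r <= 0:
                raise ValueError(f"gene {gene_id}: expression ratio must be positive")
            if r < 1:
                folds.append(1.0 / r)
                directions.append("down")
            else:
                folds.append(r)
                directions.append("up")
        return cls(gene_id, tuple(folds), tuple(padj), tuple(directions))


@dataclass(frozen=True)
class DiffBindStat:
    region_id: str
    padj: float
    fold: float
    reference_density: float  # normalized reads per kilobase in the reference sample

    def __post_init__(self) -> None:
        if not 0 <= self.padj <= 1:
            raise ValueError(f"region {self.region_id}: adjusted p must lie in [0,1]")
        if self.fold <= 0:
            raise ValueError(f"region {self.region_id}: fold must be positive")
        if self.reference_density < 0:
            raise ValueError(f"region {self.region_id}: negative reference density")


def de_filter(
    stats: Sequence[ComparisonStat],
    p_threshold: float = 1e-5,
    major_fold: float = 2.0,
    minor_fold: float = 1.2,
) -> tuple[set[str], set[str]]:
    """(down-regulated, up-regulated) gene sets under the four-comparison rule.

    Selected iff all four adjusted p <= p_threshold, all four directions
    agree, the largest fold >= major_fold and the remaining three folds
    >= minor_fold (equivalently the smallest fold >= minor_fold).
    """
    down, up = set(), set()
    for s in stats:
        if any(p > p_threshold for p in s.padj):
            continue
        if len(set(s.directions)) != 1:
            continue
        if max(s.folds) < major_fold or min(s.folds) < minor_fold:
            continue
        (down if s.directions[0] == "down" else up).add(s.gene_id)
    return down, up


def diffbind_filter(
    stats: Sequence[DiffBindStat],
    p_threshold: float = 1e-5,
    fold_threshold: float = 2.0,
    max_reference_density: float = 100.0,
) -> set[str]:
    """Differentially bound regions: adjusted p <= threshold, fold >=
    threshold ('at least 2-fold'), reference density strictly below the cap."""
    return {
        s.region_id
        for s in stats
        if s.padj <= p_threshold
        and s.fold >= fold_threshold
        and s.reference_density < max_reference_density
    }


def intersect_targets(
    de: tuple[set[str], set[str]],
    assignments: Sequence[PeakGeneAssignment],
) -> tuple[pd.DataFrame, dict[str, float | int | None]]:
    """Cross the DE gene sets with peak-to-gene assignments.

    Returns a per-gene table (gene_id, has_peak, de_status) over the union
    of DE genes and peak-assigned genes, plus summary counts: the number of
    down-regulated genes with a peak and the corresponding fraction (None
    when the down set is empty).
    """
    down, up = de
    peak_genes = {a.gene_id for a in assignments}
    all_genes = sorted(down | up | peak_genes)
    table = pd.DataFrame(
        {
            "gene_id": all_genes,
            "has_peak": [g in peak_genes for g in all_genes],
            "de_status": [
                "down" if g in down else ("up" if g in up else "none") for g in all_genes
            ],
        }
    )
    n_down_with_peak = len(down & peak_genes)
    n_up_with_peak = len(up & peak_genes)
    counts: dict[str, float | int | None] = {
        "n_down": len(down),
        "n_up": len(up),
        "n_down_with_peak": n_down_with_peak,
        "n_up_with_peak": n_up_with_peak,
        "frac_down_with_peak": n_down_with_peak / len(down) if down else None,
        "frac_up_with_peak": n_up_with_peak / len(up) if up else None,
    }
    return table, counts


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_comparison_stats(path: str | Path) -> list[ComparisonStat]:
    """gene_id + 4 ratio columns + 4 adjusted-p columns (tab-separated,
    header optional).  Ratios are knockdown/control; <1 means down."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] != 9:
        raise ValueError(f"{path}: expected 9 columns (gene_id, 4 ratios, 4 padj)")
    return [
        ComparisonStat.from_ratios(
            str(row.iloc[0]), [float(v) for v in row.iloc[1:5]], [float(v) for v in row.iloc[5:9]]
        )
        for _, row in df.iterrows()
    ]


def read_diffbind_stats(path: str | Path) -> list[DiffBindStat]:
    """region_id, padj, fold, reference_density (tab-separated)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (region_id, padj, fold, reference_density)")
    return [
        DiffBindStat(str(r.iloc[0]), float(r.iloc[1]), float(r.iloc[2]), float(r.iloc[3]))
        for _, r in df.iterrows()
    ]
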