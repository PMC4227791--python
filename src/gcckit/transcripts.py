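"""Transcript-defined gene sets and their linear chromosomal distribution.

From a per-phase expression table we derive the gene sets used in the
colocalization analyses: the top and bottom 5% of transcript levels in
each cell-cycle phase, and the genes whose levels change at least 2-fold
across each transition of the cycle (G1->G2, G2->M, M->G1).  The module
also bins genes along chromosomes by their central position and tests set
positions for departure from a uniform linear distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionTable, GenomeAssembly, GenomicInterval
from .coloc import LocusSet

TRANSITIONS = ("G1->G2", "G2->M", "M->G1")


@dataclass(frozen=True)
class GeneSet:
    """Named gene set with a phase or transition label."""

    name: str
    label: str                      # phase or transition the set refers to
    genes: tuple[str, ...]
    intervals: tuple[GenomicInterval, ...]

    def __len__(self) -> int:
        return len(self.genes)

    def as_locus_set(self) -> LocusSet:
        return LocusSet(self.name, self.intervals)

    @property
    def centers(self) -> np.ndarray:
        return np.array([iv.center for iv in self.intervals], dtype=float)


@dataclass(frozen=True)
class KSResult:
    """One-sample Kolmogorov-Smirnov test of positional uniformity."""

    chrom: str
    n: int
    statistic: float
    p_value: float
    tested: bool


def _detected(table: ExpressionTable) -> pd.DataFrame:
    # genes without detectable transcript (level 0 in every phase) are excluded
    frame = table.frame
    return frame[(frame[list(table.phases)] > 0).any(axis=1)]


def _gene_set(name: str, label: str, rows: pd.DataFrame) -> GeneSet:
    ivs = tuple(GenomicInterval(r.chrom, int(r.start), int(r.end), r.gene)
                for r in rows.itertuples())
    return GeneSet(name, label, tuple(rows["gene"]), ivs)


def extreme_sets(table: ExpressionTable, phase: str,
                 quantile: float = 0.05) -> tuple[GeneSet, GeneSet]:
    """Genes in the top and bottom ``quantile`` of transcript levels.

    Genes with no detectable transcript in the given phase are removed
    before the quantiles are taken.  Boundaries are inclusive, so ties at
    the quantile all enter the set (a degenerate all-equal table returns
    every gene in both sets, with a warning).
    """
    if not (0 < quantile < 0.5):
        raise ValueError("quantile must lie in (0, 0.5)")
    frame = table.frame[table.frame[phase] > 0]
    levels = frame[phase].to_numpy()
    if len(levels) < round(1 / quantile):
        warnings.warn("fewer genes than 1/quantile; sets may exceed nominal size")
    lo = np.quantile(levels, quantile)
    hi = np.quantile(levels, 1 - quantile)
    if lo == hi:
        warnings.warn("degenerate level distribution; high and low sets overlap")
    high = _gene_set(f"high_{phase}", phase, frame[frame[phase] >= hi])
    low = _gene_set(f"low_{phase}", phase, frame[frame[phase] <= lo])
    return high, low


def differential_sets(table: ExpressionTable, transition: str,
                      fold: float = 2.0, pseudocount: float = 0.1
                      ) -> tuple[GeneSet, GeneSet]:
    """Genes changing at least ``fold``-fold across a cell-cycle transition.

    The fold change is ``(level_to + pseudocount) / (level_from +
    pseudocount)``; the pseudocount keeps zero levels finite without
    swamping the signal.  up(A->B) equals down(B->A) exactly.
    """
    if transition not in TRANSITIONS and transition not in (
            "G2->G1", "M->G2", "G1->M"):
        raise ValueError(f"unknown transition {transition!r}")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    src, dst = transition.split("->")
    frame = _detected(table)
    ratio = (frame[dst] + pseudocount) / (frame[src] + pseudocount)
    up = _gene_set(f"up_{transition}", transition, frame[ratio >= fold])
    down = _gene_set(f"down_{transition}", transition, frame[ratio <= 1.0 / fold])
    return up, down


def fold_changes(table: ExpressionTable, transition: str,
                 pseudocount: float = 0.1) -> pd.Series:
    """Per-gene fold change for one transition, indexed by gene id."""
    src, dst = transition.split("->")
    frame = _detected(table)
    ratio = (frame[dst] + pseudocount) / (frame[src] + pseudocount)
    return pd.Series(ratio.to_numpy(), index=frame["gene"])


def bin_genes(gene_set: GeneSet, genome: GenomeAssembly,
              bin_width: int = 50_000,
              values: pd.Series | None = None) -> pd.DataFrame:
    """Assign genes to 50-kb bins along each chromosome by central position.

    A gene's bin is ``floor(center / bin_width)`` with half-open bins, so a
    gene centered exactly on a boundary falls in the higher bin.  Returns
    per-(chrom, bin) gene counts, or the mean of ``values`` (e.g. fold
    changes) when given.
    """
    rows = []
    for iv in gene_set.intervals:
        rows.append({"chrom": iv.chrom, "bin_start": (iv.center // bin_width)
                     * bin_width, "gene": iv.name})
    if not rows:
        return pd.DataFrame(columns=["chrom", "bin_start", "value"])
    frame = pd.DataFrame(rows)
    if values is None:
        out = (frame.groupby(["chrom", "bin_start"]).size()
               .rename("value").reset_index())
    else:
        frame["value"] = values.loc[frame["gene"]].to_numpy()
        out = (frame.groupby(["chrom", "bin_start"])["value"].mean()
               .reset_index())
    return out.sort_values(["chrom", "bin_start"]).reset_index(drop=True)


def ks_uniformity(gene_set: GeneSet, genome: GenomeAssembly,
                  chrom: str, min_genes: int = 3) -> KSResult:
    """One-sample KS test of gene centers against Uniform(0, chrom length).

    With fewer than ``min_genes`` genes on the chromosome the test is not
    performed and the result carries ``tested=False``.
    """
    length = genome.lengths[chrom]
    centers = np.array([iv.center for iv in gene_set.intervals
                        if iv.chrom == chrom], dtype=float)
    if len(centers) < min_genes:
        return KSResult(chrom, len(centers), float("nan"), float("nan"), False)
    stat, p = stats.kstest(centers, "uniform", args=(0, length))
    return KSResult(chrom, len(centers), float(stat), float(p), True)
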