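"""Genomic-context annotation of circle calls.

Attributes each call to a genic-region class (exon > intron > 2 kb
upstream flank > 2 kb downstream flank > intergenic, any-overlap with
precedence), counts calls per gene, and computes per-chromosome circle
density against coding-gene density with a Pearson correlation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from eccatlas.io_formats import CircleCall, GeneModel, GenomeIndex

__all__ = [
    "GeneModel", "RegionClass", "AnnotationIndex", "ChromDensity",
    "CorrelationResult", "classify_region", "region_distribution",
    "count_per_gene", "build_gene_count_matrix", "density_per_chromosome",
    "windowed_density", "correlate_density",
]


class RegionClass(str, enum.Enum):
    EXON = "exon"
    INTRON = "intron"
    GENE_UP2K = "gene_up2k"
    GENE_DOWN2K = "gene_down2k"
    INTERGENIC = "intergenic"


#: Classification precedence: a call takes the first class it overlaps.
PRECEDENCE = (RegionClass.EXON, RegionClass.INTRON, RegionClass.GENE_UP2K,
              RegionClass.GENE_DOWN2K)


class AnnotationIndex:
    """Interval trees over exons, introns, strand-aware flanks and genes."""

    def __init__(self, genes: Sequence[GeneModel], flank_bp: int = 2000):
        self.flank_bp = flank_bp
        self.genes = list(genes)
        self.trees: dict[RegionClass, dict[str, IntervalTree]] = {
            rc: {} for rc in PRECEDENCE
        }
        self.gene_tree: dict[str, IntervalTree] = {}
        for gene in self.genes:
            self._add(self.gene_tree, gene.chrom, gene.start, gene.end, gene.gene_id)
            for s, e in gene.exons:
                self._add(self.trees[RegionClass.EXON], gene.chrom, s, e, gene.gene_id)
            for s, e in gene.introns:
                self._add(self.trees[RegionClass.INTRON], gene.chrom, s, e,
                          gene.gene_id)
            # upstream is 5' of the gene body, so it depends on strand
            if gene.strand == "+":
                up = (gene.start - flank_bp, gene.start)
                down = (gene.end, gene.end + flank_bp)
            else:
                up = (gene.end, gene.end + flank_bp)
                down = (gene.start - flank_bp, gene.start)
            self._add(self.trees[RegionClass.GENE_UP2K], gene.chrom,
                      max(0, up[0]), up[1], gene.gene_id)
            self._add(self.trees[RegionClass.GENE_DOWN2K], gene.chrom,
                      max(0, down[0]), down[1], gene.gene_id)

    @staticmethod
    def _add(trees: dict[str, IntervalTree], chrom: str, start: int, end: int,
             data) -> None:
        if end <= start:
            return
        trees.setdefault(chrom, IntervalTree()).addi(start, end, data)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self.gene_tree.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def classify_region(call: CircleCall, index: AnnotationIndex) -> RegionClass:
    """First overlapped class in precedence order; intergenic by default."""
    for region in PRECEDENCE:
        tree = index.trees[region].get(call.chrom)
        if tree is not None and tree.overlaps(call.start, call.end):
            return region
    return RegionClass.INTERGENIC


def region_distribution(calls: Iterable[CircleCall], index: AnnotationIndex,
                        ) -> dict[str, int]:
    counts = {rc.value: 0 for rc in RegionClass}
    for call in calls:
        counts[classify_region(call, index).value] += 1
    return counts


def count_per_gene(calls: Iterable[CircleCall], index: AnnotationIndex,
                   mode: str = "overlap") -> pd.Series:
    """Per-gene circle counts for one sample.

    ``overlap`` increments every gene the call touches by >= 1 bp;
    ``containment`` requires the call to lie entirely inside the gene body.
    """
    if mode not in ("overlap", "containment"):
        raise ValueError(f"unknown counting mode {mode!r}")
    counts = pd.Series(0, index=[g.gene_id for g in index.genes], dtype=int)
    by_id = {g.gene_id: g for g in index.genes}
    for call in calls:
        for gene_id in index.overlapping_genes(call.chrom, call.start, call.end):
            if mode == "containment":
                gene = by_id[gene_id]
                if not (call.start >= gene.start and call.end <= gene.end):
                    continue
            counts[gene_id] += 1
    return counts


def build_gene_count_matrix(calls_by_sample: dict[str, Iterable[CircleCall]],
                            index: AnnotationIndex, mode: str = "overlap",
                            ) -> pd.DataFrame:
    """Genes x samples matrix of circle counts."""
    return pd.DataFrame({
        sample: count_per_gene(calls, index, mode)
        for sample, calls in calls_by_sample.items()
    })


@dataclass
class ChromDensity:
    chrom: str
    length_bp: int
    n_circles: int
    circles_per_mb: float
    genes_per_mb: float


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def density_per_chromosome(calls: Iterable[CircleCall], genome: GenomeIndex,
                           genes: Sequence[GeneModel]) -> list[ChromDensity]:
    """Circles/Mb and coding genes/Mb per chromosome (zero rows included)."""
    circle_counts = {name: 0 for name in genome.names}
    for call in calls:
        if call.chrom not in circle_counts:
            raise ValueError(f"call on unknown chromosome {call.chrom!r}")
        circle_counts[call.chrom] += 1
    gene_counts = {name: 0 for name in genome.names}
    for gene in genes:
        if gene.chrom in gene_counts:
            gene_counts[gene.chrom] += 1
    out = []
    for name, length in genome.entries:
        mb = length / 1e6
        out.append(ChromDensity(
            chrom=name, length_bp=length, n_circles=circle_counts[name],
            circles_per_mb=circle_counts[name] / mb,
            genes_per_mb=gene_counts[name] / mb,
        ))
    return out


def windowed_density(calls: Iterable[CircleCall], genome: GenomeIndex,
                     window_bp: int = 50_000) -> pd.DataFrame:
    """Fixed-width genome scan: circle counts per window (for density tracks)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    counts: dict[tuple[str, int], int] = {}
    for name, length in genome.entries:
        for w in range(0, length, window_bp):
            counts[(name, w)] = 0
    for call in calls:
        if call.chrom not in genome:
            raise ValueError(f"call on unknown chromosome {call.chrom!r}")
        w = (call.start // window_bp) * window_bp
        counts[(call.chrom, w)] += 1
    rows = [
        {"chrom": chrom, "window_start": w,
         "window_end": min(w + window_bp, genome.length_of(chrom)),
         "n_circles": n}
        for (chrom, w), n in counts.items()
    ]
    return pd.DataFrame(rows).sort_values(["chrom", "window_start"],
                                          ignore_index=True)


def correlate_density(density: Sequence[ChromDensity]) -> CorrelationResult:
    """Pearson correlation of circles/Mb with genes/Mb across chromosomes.

    Two-sided p-value from the t transform with n - 2 degrees of freedom.
    """
    x = np.array([d.circles_per_mb for d in density], dtype=float)
    y = np.array([d.genes_per_mb for d in density], dtype=float)
    return correlate_vectors(x, y)


def correlate_vectors(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=int(x.size))
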