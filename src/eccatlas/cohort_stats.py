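"""Cohort-level statistics over circle calls.

Covers the 100 kb size-class partition (eccDNA vs ecDNA), length
histograms with kernel-smoothed peak detection, cross-sample locus
identity and the at-least-two-samples consistency filter, group-overlap
(Venn) counts, and between-group per-gene quantity correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from eccatlas.genomic_context import CorrelationResult, correlate_vectors
from eccatlas.io_formats import CircleCall, GroupLabel, SampleManifest

#: Length cutoff separating small circles (eccDNA) from large ecDNA.
SIZE_CUTOFF_BP = 100_000


@dataclass(frozen=True)
class ConsistencyConfig:
    """Locus identity/consistency settings.

    Two calls from different samples are the same locus when their
    chromosomes match and both boundary differences are within
    ``match_tolerance_bp`` (connected-component closure).  A locus is
    "consistent" in a group when present in >= ``min_samples`` samples.
    """

    min_samples: int = 2
    match_tolerance_bp: int = 0

    def __post_init__(self):
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.match_tolerance_bp < 0:
            raise ValueError("match_tolerance_bp must be >= 0")


def partition_by_size(calls: Iterable[CircleCall],
                      cutoff_bp: int = SIZE_CUTOFF_BP,
                      ) -> tuple[list[CircleCall], list[CircleCall]]:
    """Split calls into (eccDNA, ecDNA); strictly longer than cutoff = ecDNA."""
    ecc, ec = [], []
    for call in calls:
        (ec if call.length > cutoff_bp else ecc).append(call)
    return ecc, ec


@dataclass
class LengthHistogram:
    bin_width_bp: int
    edges: np.ndarray          # left edges of bins
    counts: np.ndarray
    smoothed: np.ndarray
    peak_bp: int
    smoothing_bandwidth: float


def length_histogram(calls: Sequence[CircleCall], bin_width_bp: int = 1,
                     smoothing_bandwidth_bp: float = 25.0) -> LengthHistogram:
    """Histogram circle lengths and locate the smoothed modal length.

    1 bp bins by default, Gaussian kernel smoothing; the peak is the left
    edge of the maximal smoothed bin, ties broken toward smaller lengths.
    """
    lengths = np.array([c.length for c in calls], dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("length_histogram needs at least one call")
    lo = 0
    hi = int(lengths.max()) + bin_width_bp
    edges = np.arange(lo, hi + bin_width_bp, bin_width_bp)
    counts, _ = np.histogram(lengths, bins=edges)
    sigma_bins = max(smoothing_bandwidth_bp / bin_width_bp, 1e-9)
    smoothed = gaussian_filter1d(counts.astype(float), sigma=sigma_bins,
                                 mode="constant")
    peak_idx = int(np.argmax(smoothed))  # argmax takes the first (smallest) bin
    return LengthHistogram(
        bin_width_bp=bin_width_bp, edges=edges[:-1], counts=counts,
        smoothed=smoothed, peak_bp=int(edges[peak_idx]),
        smoothing_bandwidth=smoothing_bandwidth_bp,
    )


@dataclass
class Locus:
    """A merged cross-sample locus: representative coordinates + presence."""

    chrom: str
    start: int
    end: int
    samples: frozenset[str]
    members: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, sample)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def merge_locus_identity(calls: Iterable[CircleCall],
                         cfg: ConsistencyConfig | None = None) -> list[Locus]:
    """Group calls into loci by coordinate identity across samples.

    Identity is chromosome equality plus both boundaries within
    ``match_tolerance_bp``; loci are connected components of this relation,
    each represented by its leftmost member's coordinates.
    """
    cfg = cfg or ConsistencyConfig()
    items = sorted(
        ((c.chrom, c.start, c.end, c.sample_id) for c in calls),
        key=lambda t: (t[0], t[1], t[2]),
    )
    loci: list[Locus] = []
    tol = cfg.match_tolerance_bp
    if tol == 0:
        # exact identity: simple grouping by coordinates
        groups: dict[tuple[str, int, int], list] = {}
        for it in items:
            groups.setdefault((it[0], it[1], it[2]), []).append(it)
        for (chrom, start, end), members in sorted(groups.items()):
            loci.append(Locus(chrom, start, end,
                              frozenset(m[3] for m in members), tuple(members)))
        return loci
    # tolerance > 0: union-find over start-sorted calls per chromosome
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i, a in enumerate(items):
        for j in range(i + 1, len(items)):
            b = items[j]
            if b[0] != a[0] or b[1] - a[1] > tol:
                break
            if abs(b[2] - a[2]) <= tol:
                union(i, j)
    components: dict[int, list] = {}
    for i, it in enumerate(items):
        components.setdefault(find(i), []).append(it)
    for root in sorted(components):
        members = components[root]
        chrom, start, end, _ = min(members, key=lambda t: (t[1], t[2]))
        loci.append(Locus(chrom, start, end,
                          frozenset(m[3] for m in members), tuple(members)))
    loci.sort(key=lambda l: l.key)
    return loci


def consistency_filter(loci: Sequence[Locus], manifest: SampleManifest,
                       group: GroupLabel, cfg: ConsistencyConfig | None = None,
                       ) -> list[Locus]:
    """Keep loci present in >= min_samples samples of the given group."""
    cfg = cfg or ConsistencyConfig()
    group_ids = set(manifest.ids_in_group(group))
    if not group_ids:
        raise ValueError(f"no samples in group {group.value!r}")
    return [l for l in loci if len(l.samples & group_ids) >= cfg.min_samples]


@dataclass
class VennResult:
    only_a: int
    only_b: int
    both: int

    @property
    def union_size(self) -> int:
        return self.only_a + self.only_b + self.both


def venn_counts(set_a: Iterable[Locus], set_b: Iterable[Locus],
                cfg: ConsistencyConfig | None = None) -> VennResult:
    """Two-set overlap partition by locus identity.

    Both inputs must have been built with the same identity rule; with a
    nonzero tolerance two loci match when their representative coordinates
    fall within it.
    """
    cfg = cfg or ConsistencyConfig()
    keys_a = {l.key for l in set_a}
    keys_b = {l.key for l in set_b}
    tol = cfg.match_tolerance_bp
    if tol == 0:
        both = len(keys_a & keys_b)
        return VennResult(only_a=len(keys_a - keys_b),
                          only_b=len(keys_b - keys_a), both=both)
    matched_b: set = set()
    both = 0
    for ka in sorted(keys_a):
        for kb in sorted(keys_b - matched_b):
            if (ka[0] == kb[0] and abs(ka[1] - kb[1]) <= tol
                    and abs(ka[2] - kb[2]) <= tol):
                matched_b.add(kb)
                both += 1
                break
    return VennResult(only_a=len(keys_a) - both, only_b=len(keys_b) - both,
                      both=both)


def per_gene_quantity_correlation(totals_a: pd.Series, totals_b: pd.Series,
                                  ) -> CorrelationResult:
    """Pearson correlation of per-gene circle totals between two groups."""
    if not totals_a.index.equals(totals_b.index):
        totals_b = totals_b.reindex(totals_a.index)
        if totals_b.isna().any():
            raise ValueError("gene universes differ between the two groups")
    return correlate_vectors(totals_a.to_numpy(float), totals_b.to_numpy(float))
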