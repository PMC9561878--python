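"""Junction-evidence circle caller.

Detection proceeds in three stages: outward-oriented discordant read pairs
coarsely localize a circle junction, soft-clipped (split) reads pin its
exact coordinates by matching the clipped sequence against the genome at
the opposite boundary, and coverage metrics quantify support inside the
interval and at its edges.  A call is emitted only when it carries at least
``min_structural_reads`` structural reads (split + discordant) and at least
``min_split`` split reads.

This is a deliberately simple single-fragment caller: no probabilistic
realignment, no multi-segment circles, no inter-chromosomal junctions.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO

from eccatlas.io_formats import CircleCall, CircleCallTable, GenomeIndex

logger = logging.getLogger(__name__)


@dataclass
class CallerParams:
    """Thresholds and windows for the caller.

    ``min_structural_reads`` is the two-independent-structural-variants
    rule (e.g. one split read plus one discordant pair); ``min_split``
    defaults to 1 because downstream confidence tiers all require split
    support.  ``cluster_gap_bp`` should be of the order of
    insert_mean + 3*insert_sd.
    """

    min_structural_reads: int = 2
    min_split: int = 1
    cluster_gap_bp: int = 350
    clip_match_min_bp: int = 10
    clip_mismatch_max: int = 1
    flank_bp: int = 100

    def __post_init__(self):
        if self.min_structural_reads < 1:
            raise ValueError("min_structural_reads must be >= 1")
        if self.min_split < 0:
            raise ValueError("min_split must be >= 0")


@dataclass
class CandidateInterval:
    chrom: str
    start: int
    end: int
    n_discordant: int


@dataclass
class _ClipEvent:
    # kind "end": aligned part ends at pos (candidate circle end);
    # kind "start": aligned part begins at pos (candidate circle start)
    kind: str
    pos: int
    clip_seq: str


class AlignmentSet:
    """All alignments of one coordinate-sorted SAM, indexed by chromosome."""

    def __init__(self, references: list[tuple[str, int]]):
        self.references = references
        self.by_chrom: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
        self._depth_cache: dict[str, np.ndarray] = {}

    @classmethod
    def from_sam(cls, path: str | Path) -> "AlignmentSet":
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            refs = list(zip(sam.references, sam.lengths))
            out = cls(refs)
            last = (-1, -1)
            for rec in sam:
                if rec.is_unmapped:
                    continue
                key = (rec.reference_id, rec.reference_start)
                if key < last:
                    raise ValueError(
                        "input SAM is not coordinate-sorted "
                        f"(at {rec.reference_name}:{rec.reference_start})"
                    )
                last = key
                out.by_chrom[rec.reference_name].append(rec)
        return out

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.references:
            if name == chrom:
                return length
        raise KeyError(f"chromosome {chrom!r} not in SAM header")

    def depth(self, chrom: str) -> np.ndarray:
        """Per-base depth over one chromosome (aligned reference blocks)."""
        if chrom not in self._depth_cache:
            length = self.chrom_length(chrom)
            diff = np.zeros(length + 1, dtype=np.int32)
            for rec in self.by_chrom.get(chrom, []):
                for bs, be in rec.get_blocks():
                    diff[bs] += 1
                    diff[min(be, length)] -= 1
            self._depth_cache[chrom] = np.cumsum(diff[:-1])
        return self._depth_cache[chrom]

    def genome_index(self) -> GenomeIndex:
        return GenomeIndex(entries=tuple(self.references))


def find_discordant_clusters(alignments: AlignmentSet,
                             params: CallerParams | None = None,
                             ) -> list[CandidateInterval]:
    """Cluster outward-oriented pairs into candidate circle intervals.

    A pair is outward-facing when its reverse-strand mate lies upstream of
    the forward-strand mate on the same chromosome — the signature of a
    fragment spanning a circle junction.  Pairs whose implied intervals lie
    within ``cluster_gap_bp`` of each other are merged; the candidate spans
    the outermost implied boundaries.
    """
    params = params or CallerParams()
    implied: dict[str, list[tuple[int, int]]] = defaultdict(list)
    any_paired = False
    for chrom, records in alignments.by_chrom.items():
        for rec in records:
            if not rec.is_paired:
                continue
            any_paired = True
            if rec.is_reverse or not rec.mate_is_reverse:
                continue  # consider each pair once, via its forward read
            if rec.next_reference_id != rec.reference_id:
                continue
            if rec.next_reference_start < rec.reference_start:
                # reverse mate upstream of the forward read: outward pair
                implied[chrom].append(
                    (rec.next_reference_start, rec.reference_end)
                )
    if not any_paired:
        logger.warning("no paired reads in stream; no discordant candidates")
        return []
    clusters: list[CandidateInterval] = []
    for chrom in sorted(implied):
        intervals = sorted(implied[chrom])
        current: list[tuple[int, int]] = []
        for iv in intervals:
            if current and (
                iv[0] - max(s for s, _ in current) <= params.cluster_gap_bp
                and abs(iv[1] - current[-1][1]) <= params.cluster_gap_bp
            ):
                current.append(iv)
            else:
                if current:
                    clusters.append(_to_candidate(chrom, current))
                current = [iv]
        if current:
            clusters.append(_to_candidate(chrom, current))
    return clusters


def _to_candidate(chrom: str, members: list[tuple[int, int]]) -> CandidateInterval:
    start = min(s for s, _ in members)
    end = max(e for _, e in members)
    return CandidateInterval(chrom, start, end, n_discordant=len(members))


def _clip_events(alignments: AlignmentSet, chrom: str, lo: int, hi: int,
                 min_clip: int) -> list[_ClipEvent]:
    events = []
    for rec in alignments.by_chrom.get(chrom, []):
        cig = rec.cigartuples
        if not cig or rec.query_sequence is None:
            continue
        if rec.reference_end < lo or rec.reference_start > hi:
            continue
        # soft-clipped suffix: aligned part ends at a putative circle end
        if cig[-1][0] == 4 and cig[-1][1] >= min_clip:
            events.append(_ClipEvent(
                "end", rec.reference_end, rec.query_sequence[-cig[-1][1]:]
            ))
        # soft-clipped prefix: aligned part starts at a putative circle start
        if cig[0][0] == 4 and cig[0][1] >= min_clip:
            events.append(_ClipEvent(
                "start", rec.reference_start, rec.query_sequence[:cig[0][1]]
            ))
    return events


def _modal_position(events: list[_ClipEvent]) -> int | None:
    if not events:
        return None
    counts = Counter(e.pos for e in events)
    best = max(counts.values())
    # leftmost among tied modal positions, for determinism
    return min(pos for pos, c in counts.items() if c == best)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def _realign_clips(clips: list[str], seq: str, lo: int, hi: int,
                   anchor: str, max_mismatch: int) -> list[int]:
    """Slide clipped segments over [lo, hi) and return matching boundaries.

    ``anchor='prefix'``: a clip from a circle-end read matches the sequence
    *entering* the start boundary, so a match of the clip beginning at p
    votes for start = p.  ``anchor='suffix'``: a clip from a circle-start
    read matches the sequence just *before* the end boundary; a match of
    the clip ending at p votes for end = p.
    """
    positions = set()
    for clip in clips:
        for p in range(lo, hi + 1):
            if anchor == "prefix":
                target = seq[p:p + len(clip)]
            else:
                target = seq[max(0, p - len(clip)):p]
            if len(target) == len(clip) and _mismatches(clip, target) <= max_mismatch:
                positions.add(p)
    return sorted(positions)


def refine_junction(candidate: CandidateInterval, alignments: AlignmentSet,
                    genome: dict[str, str], params: CallerParams | None = None,
                    ) -> tuple[int, int, int]:
    """Refine a candidate interval to exact junction coordinates.

    Soft-clipped reads near the candidate vote for boundary positions; the
    modal positions win (leftmost on ties).  A read confirms the junction
    when its clipped segment matches the genome sequence entering the
    opposite boundary with at most ``clip_mismatch_max`` mismatches.
    Returns ``(start, end, n_split)``; with no confirming reads the
    candidate coordinates come back unchanged with ``n_split = 0``.
    """
    params = params or CallerParams()
    seq = genome[candidate.chrom]
    gap = params.cluster_gap_bp
    lo = max(0, candidate.start - gap)
    hi = min(len(seq), candidate.end + gap)
    events = _clip_events(alignments, candidate.chrom, lo, hi,
                          params.clip_match_min_bp)
    # only clips near the respective candidate boundary can be its junction
    start_events = [e for e in events
                    if e.kind == "start" and abs(e.pos - candidate.start) <= gap]
    end_events = [e for e in events
                  if e.kind == "end" and abs(e.pos - candidate.end) <= gap]
    start_positions = sorted({e.pos for e in start_events})
    end_positions = sorted({e.pos for e in end_events})
    # one-sided evidence: realign the clipped segments to locate the other
    # boundary within the candidate window
    if end_events and not start_positions:
        start_positions = _realign_clips(
            [e.clip_seq for e in end_events], seq,
            max(0, candidate.start - gap), candidate.start + gap,
            anchor="prefix", max_mismatch=params.clip_mismatch_max,
        )
    if start_events and not end_positions:
        end_positions = _realign_clips(
            [e.clip_seq for e in start_events], seq,
            max(0, candidate.end - gap), candidate.end + gap,
            anchor="suffix", max_mismatch=params.clip_mismatch_max,
        )
    start_positions = start_positions or [candidate.start]
    end_positions = end_positions or [candidate.end]

    def confirmations(ps: int, pe: int) -> int:
        n = 0
        for ev in end_events:
            if ev.pos == pe and _mismatches(
                ev.clip_seq, seq[ps:ps + len(ev.clip_seq)]
            ) <= params.clip_mismatch_max:
                n += 1
        for ev in start_events:
            if ev.pos == ps and _mismatches(
                ev.clip_seq, seq[max(0, pe - len(ev.clip_seq)):pe]
            ) <= params.clip_mismatch_max:
                n += 1
        return n

    best: tuple[int, int, int] | None = None  # (n_split, start, end)
    for ps in start_positions:
        for pe in end_positions:
            if pe <= ps:
                continue
            n = confirmations(ps, pe)
            if n == 0:
                continue
            if best is None or n > best[0] or (
                n == best[0] and (ps, pe) < (best[1], best[2])
            ):
                best = (n, ps, pe)
    if best is None:
        return candidate.start, candidate.end, 0
    return best[1], best[2], best[0]


def find_split_seed_candidates(alignments: AlignmentSet,
                               params: CallerParams | None = None,
                               ) -> list[CandidateInterval]:
    """Seed candidates from co-located soft-clip clusters alone.

    Circles shorter than roughly two read lengths produce no internal
    discordant pair, so both junction boundaries must come from clip
    positions: prefix- and suffix-clip events within ``cluster_gap_bp`` of
    each other whose modal positions bracket an interval become a
    zero-discordant candidate (it can still pass the structural-read
    threshold on split support alone).
    """
    params = params or CallerParams()
    out = []
    for chrom in sorted(alignments.by_chrom):
        length = alignments.chrom_length(chrom)
        events = sorted(
            _clip_events(alignments, chrom, 0, length, params.clip_match_min_bp),
            key=lambda e: e.pos,
        )
        cluster: list[_ClipEvent] = []
        for ev in events + [None]:
            if ev is not None and (not cluster
                                   or ev.pos - cluster[-1].pos <= params.cluster_gap_bp):
                cluster.append(ev)
                continue
            if cluster:
                start = _modal_position([e for e in cluster if e.kind == "start"])
                end = _modal_position([e for e in cluster if e.kind == "end"])
                if start is not None and end is not None and end > start:
                    out.append(CandidateInterval(chrom, start, end, n_discordant=0))
            cluster = [ev] if ev is not None else []
    return out


def compute_support_metrics(chrom: str, start: int, end: int,
                            alignments: AlignmentSet, flank_bp: int = 100,
                            ) -> tuple[float, float, float]:
    """Coverage fraction plus the relative depth step at each boundary.

    ``cov_increase_start = max(0, 1 - mean flank depth / mean interior
    depth)`` over ``flank_bp`` windows just outside/inside the start, and
    symmetrically at the end; both clamped to [0, 1].  An interior mean of
    zero gives a ratio of 0.
    """
    length = alignments.chrom_length(chrom)
    if start < 0 or end > length or end <= start:
        raise ValueError(f"interval {chrom}:{start}-{end} invalid on {length} bp")
    depth = alignments.depth(chrom)
    inside = depth[start:end]
    coverage_fraction = float((inside > 0).mean())

    def edge_ratio(outside: np.ndarray, interior: np.ndarray) -> float:
        mean_in = interior.mean() if interior.size else 0.0
        if mean_in <= 0:
            return 0.0
        mean_out = outside.mean() if outside.size else 0.0
        return float(min(1.0, max(0.0, 1.0 - mean_out / mean_in)))

    w = min(flank_bp, end - start)
    start_ratio = edge_ratio(depth[max(0, start - flank_bp):start],
                             depth[start:start + w])
    end_ratio = edge_ratio(depth[end:end + flank_bp], depth[end - w:end])
    return coverage_fraction, start_ratio, end_ratio


def load_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def call_circles(sam: str | Path | AlignmentSet, genome: dict[str, str] | str | Path,
                 params: CallerParams | None = None, sample_id: str = "",
                 ) -> CircleCallTable:
    """Run the full caller on one sample's coordinate-sorted SAM.

    Output rows are sorted by (chrom, start, end); every emitted call
    satisfies ``n_split + n_discordant >= min_structural_reads`` and
    ``n_split >= min_split``.
    """
    params = params or CallerParams()
    alignments = sam if isinstance(sam, AlignmentSet) else AlignmentSet.from_sam(sam)
    if not isinstance(genome, dict):
        genome = load_genome_fasta(genome)
    calls: dict[tuple[str, int, int], CircleCall] = {}
    candidates = (find_discordant_clusters(alignments, params)
                  + find_split_seed_candidates(alignments, params))
    for candidate in candidates:
        start, end, n_split = refine_junction(candidate, alignments, genome, params)
        if n_split + candidate.n_discordant < params.min_structural_reads:
            continue
        if n_split < params.min_split:
            continue
        coverage_fraction, inc_start, inc_end = compute_support_metrics(
            candidate.chrom, start, end, alignments, params.flank_bp
        )
        key = (candidate.chrom, start, end)
        call = CircleCall(
            chrom=candidate.chrom, start=start, end=end,
            n_split=n_split, n_discordant=candidate.n_discordant,
            coverage_fraction=coverage_fraction,
            cov_increase_start=inc_start, cov_increase_end=inc_end,
            sample_id=sample_id,
        )
        if key in calls:  # two clusters refined to one junction: keep best-supported
            prev = calls[key]
            if call.n_structural > prev.n_structural:
                calls[key] = call
        else:
            calls[key] = call
    rows = [calls[k] for k in sorted(calls)]
    return CircleCallTable(rows=rows, dialect="native")
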