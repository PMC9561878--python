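"""Caller stages: discordant clustering, junction refinement, support metrics."""

import numpy as np
import pytest

from eccatlas.circle_caller import (
    AlignmentSet,
    CallerParams,
    CandidateInterval,
    call_circles,
    compute_support_metrics,
    find_discordant_clusters,
    refine_junction,
)
from eccatlas.synthetic_data import SimConfig, build_truth, simulate_reads

RL = 100
REFS = [("chr1", 100_000)]


def _pair(pos_fwd, pos_rev, outward, name):
    """Segment specs for one read pair (only the forward read drives calls)."""
    flag_fwd = 0x1 | 0x20 | 0x40 | (0 if outward else 0x2)
    return [
        dict(name=name, ref_id=0, pos=pos_fwd, seq="A" * RL, cigar=f"{RL}M",
             flag=flag_fwd, mate_pos=pos_rev),
        dict(name=name, ref_id=0, pos=pos_rev, seq="A" * RL, cigar=f"{RL}M",
             flag=0x1 | 0x10 | 0x80 | (0 if outward else 0x2), mate_pos=pos_fwd),
    ]


def test_concordant_pairs_yield_no_candidates(alignment_builder):
    segs = []
    for i, p in enumerate([1000, 3000, 5000]):
        # inward/FR: forward read upstream of its reverse mate
        segs += _pair(pos_fwd=p, pos_rev=p + 200, outward=False, name=f"c{i}")
    aln = alignment_builder(REFS, segs)
    assert find_discordant_clusters(aln) == []


def test_three_outward_pairs_one_cluster(alignment_builder):
    segs = []
    for i, (fwd, rev) in enumerate([(1850, 1010), (1880, 1040), (1900, 1000)]):
        segs += _pair(pos_fwd=fwd, pos_rev=rev, outward=True, name=f"d{i}")
    aln = alignment_builder(REFS, segs)
    clusters = find_discordant_clusters(aln)
    assert len(clusters) == 1
    cluster = clusters[0]
    assert cluster.n_discordant == 3
    # outermost implied boundaries
    assert (cluster.start, cluster.end) == (1000, 2000)


def test_distant_outward_pairs_stay_separate(alignment_builder):
    segs = (_pair(1900, 1000, True, "d0") + _pair(11900, 11000, True, "d1"))
    aln = alignment_builder(REFS, segs)
    clusters = find_discordant_clusters(aln, CallerParams(cluster_gap_bp=500))
    assert len(clusters) == 2


def test_unpaired_stream_gives_empty_result(alignment_builder):
    segs = [dict(name="u", ref_id=0, pos=500, seq="A" * RL, cigar=f"{RL}M",
                 flag=0)]
    assert find_discordant_clusters(alignment_builder(REFS, segs)) == []


def test_unsorted_sam_is_rejected(tmp_path):
    sam = tmp_path / "unsorted.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000\n"
        "r1\t0\tchr1\t501\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        "r2\t0\tchr1\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
    )
    with pytest.raises(ValueError, match="not coordinate-sorted"):
        AlignmentSet.from_sam(sam)


def test_refinement_recovers_exact_junction(tmp_path):
    """Reads simulated for a circle at (5000, 5358) refine to exactly that."""
    from eccatlas.synthetic_data import PlantedCircle, SyntheticTruth, generate_genome

    cfg = SimConfig(seed=6, chromosomes=[("c1", 50_000)], n_circles=0,
                    background_depth=0.0, junction_read_depth=6)
    genome, index = generate_genome(cfg)
    truth = SyntheticTruth([PlantedCircle("c1", 5000, 5358)], [], genome, index)
    sam = tmp_path / "one.sam"
    simulate_reads(truth, cfg, sam)
    aln = AlignmentSet.from_sam(sam)
    candidate = CandidateInterval("c1", 5050, 5300, n_discordant=1)
    start, end, n_split = refine_junction(candidate, aln, genome)
    assert (start, end) == (5000, 5358)
    assert n_split >= 1


def test_unmatchable_clip_leaves_candidate_unchanged(alignment_builder):
    rng = np.random.default_rng(0)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 100_000))}
    segs = [dict(name="sc", ref_id=0, pos=1900, seq="A" * RL, cigar="50M50S",
                 flag=0)]
    aln = alignment_builder(REFS, segs)
    candidate = CandidateInterval("chr1", 1000, 1950, n_discordant=2)
    start, end, n_split = refine_junction(candidate, aln, genome)
    assert (start, end, n_split) == (1000, 1950, 0)


def test_equal_support_ties_break_leftmost(alignment_builder):
    """Two equally supported junction pairs: the leftmost wins."""
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), 10_000))
    genome = {"chr1": seq}
    refs = [("chr1", 10_000)]
    segs = []
    for s, e, tag in [(2000, 2400, "a"), (2005, 2405, "b")]:
        # one junction read each: aligned suffix ends at e, clip matches at s
        k = 60
        read = seq[e - k:e] + seq[s:s + RL - k]
        segs.append(dict(name=f"sr{tag}", ref_id=0, pos=e - k, seq=read,
                         cigar=f"{k}M{RL - k}S", flag=0))
        read2 = seq[e - (RL - k):e] + seq[s:s + k]
        segs.append(dict(name=f"sl{tag}", ref_id=0, pos=s, seq=read2,
                         cigar=f"{RL - k}S{k}M", flag=0))
    aln = alignment_builder(refs, segs)
    candidate = CandidateInterval("chr1", 2050, 2350, n_discordant=2)
    start, end, n_split = refine_junction(candidate, aln, genome)
    assert (start, end) == (2000, 2400)
    assert n_split == 2


def test_support_metrics_closed_forms(alignment_builder):
    refs = [("chr1", 2000)]
    inside = [dict(name=f"i{k}", ref_id=0, pos=500, seq="A" * 400,
                   cigar="400M", flag=0) for k in range(10)]
    aln = alignment_builder(refs, inside)
    cov, inc_s, inc_e = compute_support_metrics("chr1", 500, 900, aln)
    assert (cov, inc_s, inc_e) == (1.0, 1.0, 1.0)

    everywhere = [dict(name=f"e{k}", ref_id=0, pos=0, seq="A" * 2000,
                       cigar="2000M", flag=0) for k in range(10)]
    aln = alignment_builder(refs, everywhere)
    cov, inc_s, inc_e = compute_support_metrics("chr1", 500, 900, aln)
    assert (cov, inc_s, inc_e) == (1.0, 0.0, 0.0)

    aln = alignment_builder(refs, [])
    cov, inc_s, inc_e = compute_support_metrics("chr1", 500, 900, aln)
    assert (cov, inc_s, inc_e) == (0.0, 0.0, 0.0)

    with pytest.raises(ValueError, match="invalid"):
        compute_support_metrics("chr1", 1900, 2100, aln)


def _recovery(seed):
    cfg = SimConfig(seed=seed, chromosomes=[("chr1", 400_000), ("chr2", 300_000)],
                    n_circles=50, background_depth=5.0, junction_read_depth=6)
    truth = build_truth(cfg)
    import tempfile, os

    with tempfile.TemporaryDirectory() as tmp:
        sam = os.path.join(tmp, "s.sam")
        simulate_reads(truth, cfg, sam)
        table = call_circles(sam, truth.genome, CallerParams(), "S1")
    truth_set = {(c.chrom, c.start, c.end) for c in truth.circles}
    called = {(c.chrom, c.start, c.end) for c in table}
    return truth_set, called, table


@pytest.mark.parametrize("seed", [2, 3, 4, 5, 6])
def test_recovery_is_high_and_junctions_exact(seed):
    """On clean synthetic data: recall >= 0.9, exact coordinates, no spurious calls."""
    truth_set, called, table = _recovery(seed)
    assert len(truth_set & called) / len(truth_set) >= 0.9
    assert called <= truth_set
    for call in table:
        assert call.n_structural >= 2
        assert call.n_split >= 1


def test_raising_structural_threshold_never_adds_calls(recovery_dataset):
    cfg, truth, sam = recovery_dataset
    aln = AlignmentSet.from_sam(sam)
    counts = []
    for min_structural in (2, 4, 6, 8):
        params = CallerParams(min_structural_reads=min_structural)
        counts.append(len(call_circles(aln, truth.genome, params, "S1")))
    assert counts == sorted(counts, reverse=True)


def test_threshold_boundary_one_split_one_discordant(tmp_path):
    """1 split + 1 discordant passes the 2-structural-reads rule; 1 + 0 fails."""
    from eccatlas.synthetic_data import PlantedCircle, SyntheticTruth, generate_genome

    cfg = SimConfig(seed=10, chromosomes=[("c1", 50_000)], n_circles=0,
                    background_depth=0.0, junction_read_depth=2)
    genome, index = generate_genome(cfg)
    truth = SyntheticTruth([PlantedCircle("c1", 8000, 8600)], [], genome, index)
    sam = tmp_path / "pair.sam"
    simulate_reads(truth, cfg, sam)
    table = call_circles(sam, genome, CallerParams(), "S1")
    assert len(table) == 1
    call = table.rows[0]
    assert call.n_split >= 1 and call.n_discordant >= 1

    # drop the discordant pair: the lone split read no longer suffices
    lines = [l for l in sam.read_text().splitlines()
             if l.startswith("@") or not l.startswith("dp_")]
    solo = tmp_path / "solo.sam"
    solo.write_text("\n".join(lines) + "\n")
    assert len(call_circles(solo, genome, CallerParams(), "S1")) == 0
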