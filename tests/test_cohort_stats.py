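"""Size classes, length peaks, locus identity, consistency, Venn, correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eccatlas.cohort_stats import (
    ConsistencyConfig,
    consistency_filter,
    length_histogram,
    merge_locus_identity,
    partition_by_size,
    per_gene_quantity_correlation,
    venn_counts,
)
from eccatlas.io_formats import GroupLabel, Sample, SampleManifest
from eccatlas.synthetic_data import SimConfig, build_truth


def _manifest(n_per_group=7):
    samples = [Sample(f"A{i}", GroupLabel.AIONFH, "") for i in range(n_per_group)]
    samples += [Sample(f"C{i}", GroupLabel.CONTROL, "") for i in range(n_per_group)]
    return SampleManifest(samples=samples)


def test_partition_at_100kb_boundary(make_call):
    calls = [make_call(start=0, end=length)
             for length in (358, 99_700, 100_000, 100_001)]
    ecc, ec = partition_by_size(calls)
    assert [c.length for c in ecc] == [358, 99_700, 100_000]  # 100 kb inclusive
    assert [c.length for c in ec] == [100_001]
    assert partition_by_size([]) == ([], [])


def test_partition_conserves_all_calls(make_call):
    rng = np.random.default_rng(0)
    calls = [make_call(start=0, end=int(l))
             for l in rng.integers(100, 200_000, 500)]
    ecc, ec = partition_by_size(calls)
    assert len(ecc) + len(ec) == len(calls)


def test_length_histogram_peak_and_ties(make_call):
    same = [make_call(start=0, end=358) for _ in range(10)]
    assert length_histogram(same).peak_bp == 358
    bimodal = ([make_call(start=0, end=200)] * 5
               + [make_call(start=0, end=400)] * 5)
    assert length_histogram(bimodal).peak_bp == 200  # tie -> smaller length
    with pytest.raises(ValueError, match="at least one"):
        length_histogram([])


def test_length_peak_recovered_from_simulation(make_call):
    truth = build_truth(SimConfig(seed=5, n_circles=5000))
    calls = [make_call(chrom=c.chrom, start=c.start, end=c.end)
             for c in truth.circles]
    hist = length_histogram(calls)
    assert 304 <= hist.peak_bp <= 412
    assert hist.counts.sum() == 5000


@pytest.mark.parametrize(
    "delta,tolerance,n_loci",
    [(0, 0, 1), (5, 0, 2), (5, 10, 1)],
)
def test_locus_identity_tolerance(make_call, delta, tolerance, n_loci):
    calls = [
        make_call(start=1000, end=1500, sample_id="A0"),
        make_call(start=1000 + delta, end=1500 + delta, sample_id="A1"),
        make_call(start=1000, end=1500, sample_id="C0"),
    ]
    loci = merge_locus_identity(calls, ConsistencyConfig(match_tolerance_bp=tolerance))
    assert len(loci) == n_loci
    if n_loci == 1:
        assert loci[0].samples == {"A0", "A1", "C0"}
        assert (loci[0].start, loci[0].end) == (1000, 1500)  # leftmost member


def test_locus_components_are_transitive_chains(make_call):
    """A chain a~b~c (a not directly within tolerance of c) is one component."""
    calls = [make_call(start=1000 + 8 * i, end=1500 + 8 * i, sample_id=f"S{i}")
             for i in range(4)]
    loci = merge_locus_identity(calls, ConsistencyConfig(match_tolerance_bp=10))
    assert len(loci) == 1
    assert loci[0].start == 1000


def test_consistency_filter_rules(make_call):
    manifest = _manifest()
    calls = [
        make_call(start=100, end=600, sample_id="A0"),
        make_call(start=100, end=600, sample_id="A1"),
        make_call(start=5000, end=5600, sample_id="A2"),
        make_call(start=9000, end=9600, sample_id="C0"),
        make_call(start=9000, end=9600, sample_id="C1"),
    ]
    loci = merge_locus_identity(calls)
    cfg = ConsistencyConfig(min_samples=2)
    kept_a = consistency_filter(loci, manifest, GroupLabel.AIONFH, cfg)
    kept_c = consistency_filter(loci, manifest, GroupLabel.CONTROL, cfg)
    assert [(l.start, l.end) for l in kept_a] == [(100, 600)]
    assert [(l.start, l.end) for l in kept_c] == [(9000, 9600)]
    identity = ConsistencyConfig(min_samples=1)
    assert len(consistency_filter(loci, manifest, GroupLabel.AIONFH, identity)) == 2


def test_venn_counts_small_cases(make_call):
    def loci_at(starts, sample):
        calls = [make_call(start=s, end=s + 500, sample_id=sample) for s in starts]
        return merge_locus_identity(calls)

    a = loci_at([100, 200, 300], "A0")
    b = loci_at([200], "C0")
    v = venn_counts(a, b)
    assert (v.only_a, v.only_b, v.both) == (2, 0, 1)
    v = venn_counts(loci_at([1, 2, 3], "A0"), loci_at([10, 20, 30, 40], "C0"))
    assert (v.only_a, v.only_b, v.both) == (3, 4, 0)
    v = venn_counts(a, a)
    assert (v.only_a, v.only_b, v.both) == (0, 0, 3)


@settings(max_examples=200, derandomize=True)
@given(
    starts_a=st.sets(st.integers(0, 60), max_size=25),
    starts_b=st.sets(st.integers(0, 60), max_size=25),
)
def test_venn_agrees_with_set_algebra(starts_a, starts_b):
    """Randomized instances: venn partition == brute-force set operations."""
    from eccatlas.io_formats import CircleCall

    def loci(starts, sample):
        return merge_locus_identity(
            CircleCall(chrom="chr1", start=1000 * s, end=1000 * s + 500,
                       sample_id=sample)
            for s in starts
        )

    v = venn_counts(loci(starts_a, "A"), loci(starts_b, "B"))
    assert v.only_a == len(starts_a - starts_b)
    assert v.only_b == len(starts_b - starts_a)
    assert v.both == len(starts_a & starts_b)
    assert v.only_a + v.both == len(starts_a)
    assert v.only_b + v.both == len(starts_b)
    assert v.union_size == len(starts_a | starts_b)


def test_per_gene_quantity_correlation():
    import pandas as pd

    genes = [f"g{i}" for i in range(100)]
    rng = np.random.default_rng(1)
    a = pd.Series(rng.poisson(20, 100), index=genes, dtype=float)
    assert per_gene_quantity_correlation(a, a).r == pytest.approx(1.0)
    three = pd.Series([1.0, 2.0, 3.0], index=["x", "y", "z"])
    rev = pd.Series([3.0, 2.0, 1.0], index=["x", "y", "z"])
    assert per_gene_quantity_correlation(three, rev).r == pytest.approx(-1.0)
    b = a + pd.Series(rng.normal(0, 5, 100), index=genes)
    res = per_gene_quantity_correlation(a, b)
    xc = a.to_numpy() - a.mean()
    yc = b.to_numpy() - b.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    assert res.r == pytest.approx(r, abs=1e-12)
    with pytest.raises(ValueError, match="constant"):
        per_gene_quantity_correlation(three, pd.Series([1.0, 1.0, 1.0],
                                                       index=["x", "y", "z"]))
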