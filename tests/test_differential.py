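"""Group means, pseudocount log2FC, rank-sum testing, FDR, significance filter."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from eccatlas.differential import (
    DifferentialConfig,
    bh_fdr,
    compute_log2fc,
    exact_ranksum_p,
    group_means,
    load_reference_exon_table,
    normalize_columns,
    permutation_p,
    run_differential,
    significant_genes,
    test_gene,
)
from eccatlas.io_formats import GroupLabel, Sample, SampleManifest
from eccatlas.synthetic_data import simulate_gene_counts


def _manifest(case_ids, control_ids):
    samples = [Sample(s, GroupLabel.AIONFH, "") for s in case_ids]
    samples += [Sample(s, GroupLabel.CONTROL, "") for s in control_ids]
    return SampleManifest(samples=samples)


def test_group_means_plain_average():
    matrix = pd.DataFrame({"a1": [1], "a2": [2], "a3": [3],
                           "c1": [4], "c2": [5]}, index=["g"])
    manifest = _manifest(["a1", "a2", "a3"], ["c1", "c2"])
    cfg = DifferentialConfig(normalization="none")
    means = group_means(matrix, manifest, cfg)
    assert means.loc["g", "mean_case"] == pytest.approx(2.0)
    assert means.loc["g", "mean_control"] == pytest.approx(4.5)


def test_total_count_normalization_is_scale_invariant():
    rng = np.random.default_rng(0)
    matrix = pd.DataFrame(rng.poisson(10, (20, 4)),
                          columns=["a1", "a2", "c1", "c2"])
    doubled = matrix.copy()
    doubled["a1"] = matrix["a1"] * 2
    norm_a = normalize_columns(matrix)
    norm_b = normalize_columns(doubled)
    # doubling every count of one sample leaves its normalized column as-is
    # up to the shift in the cohort mean total, which rescales all columns
    ratio = norm_b["a1"] / norm_a["a1"]
    assert np.allclose(ratio, ratio.iloc[0])
    totals = norm_a.sum(axis=0)
    assert np.allclose(totals, totals.iloc[0])


@pytest.mark.parametrize(
    "control,case,expected",
    [
        (34.36, 610.1686, 4.150406),       # reference table row (CNTNAP2)
        (642.4114, 0.0, -19.2931),         # zero case mean -> pseudocount
        (642.4114, 0.001, -19.2931),       # pre-substituted zero, same result
        (2.771429, 445.0943, 7.327337),    # FAM110D
        (5.542857, 445.0943, 6.327337),    # C1orf232 (control doubled)
        (896.1243, 56.55429, -3.98599),    # MACF1
    ],
)
def test_log2fc_reproduces_reference_rows(control, case, expected):
    assert compute_log2fc(control, case) == pytest.approx(expected, abs=1e-3)


def test_log2fc_identity_antisymmetry_and_missing():
    assert compute_log2fc(7.5, 7.5) == 0.0
    for c, a in [(3.0, 12.0), (0.0, 5.0), (100.0, 0.0)]:
        assert compute_log2fc(c, a) == pytest.approx(-compute_log2fc(a, c))
    assert math.isnan(compute_log2fc(0.0, 0.0))


def test_pseudocount_only_triggers_at_exact_zero():
    base = compute_log2fc(10.0, 5.0)
    eps = 1e-9
    assert compute_log2fc(10.0, 5.0 + eps) == pytest.approx(base, abs=1e-8)
    assert abs(compute_log2fc(10.0, eps) - base) < 35  # continuous, no jump
    assert compute_log2fc(10.0, 0.0) == pytest.approx(math.log2(0.001 / 10.0))


def test_exact_ranksum_complete_separation_7v7():
    """Fully separated 7 vs 7 gives the enumeration value 2/C(14,7)."""
    control = np.arange(1.0, 8.0)
    case = np.arange(10.0, 17.0)
    p = exact_ranksum_p(control, case)
    assert p == pytest.approx(2 / 3432)
    assert exact_ranksum_p(np.ones(5), np.ones(5)) == 1.0


def test_permutation_p_tracks_exact_enumeration():
    rng = np.random.default_rng(3)
    control = rng.normal(0, 1, 5)
    case = rng.normal(1.0, 1, 5)
    exact = exact_ranksum_p(control, case)
    perm = permutation_p(control, case, n_permutations=20_000, seed=9)
    mc_se = math.sqrt(exact * (1 - exact) / 20_000)
    assert abs(perm - exact) <= 3 * mc_se + 1e-4


def test_test_gene_validates_group_sizes():
    with pytest.raises(ValueError, match="at least 2"):
        test_gene([1.0], [1.0, 2.0])


def test_bh_fdr_matches_step_up_definition():
    assert bh_fdr([0.03]) == pytest.approx([0.03])
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])
    # brute-force step-up on random vectors
    rng = np.random.default_rng(5)
    for _ in range(20):
        p = rng.random(17)
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        assert bh_fdr(p) == pytest.approx(brute, abs=1e-12)


def test_significance_filter_boundaries():
    table = pd.DataFrame({
        "id": ["a", "b", "c", "d"],
        "log2fc": [2.0, -1.5, 1.0, 3.0],
        "pvalue": [0.01, 0.04, 0.01, 0.05],
    })
    kept, n_up, n_down = significant_genes(table)
    # c fails |log2fc| > 1 (strict); d fails p < 0.05 (strict)
    assert list(kept["id"]) == ["a", "b"]
    assert (n_up, n_down) == (1, 1)


def test_reference_exon_table_filter_counts():
    """All 25 reference exon-region genes pass the filter: 18 up, 7 down."""
    table = load_reference_exon_table()
    kept, n_up, n_down = significant_genes(table)
    assert len(kept) == 25
    assert (n_up, n_down) == (18, 7)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_planted_differential_genes_are_recovered(seed):
    """7v7 Poisson cohorts with a 4x planted effect: >=80% recovered."""
    matrix, manifest, planted = simulate_gene_counts(
        n_genes=80, n_per_group=7, base_mean=20.0, planted_ratio=4.0,
        n_planted=10, seed=seed,
    )
    table = run_differential(matrix, manifest, seed=seed)
    kept, n_up, _ = significant_genes(table)
    recovered = set(kept["id"]) & set(planted)
    assert len(recovered) >= 8
    assert n_up >= len(recovered)  # planted effects raise the case group


def test_swapping_groups_negates_log2fc():
    matrix, manifest, _ = simulate_gene_counts(n_genes=30, seed=7)
    table = run_differential(matrix, manifest, seed=7)
    swapped = SampleManifest(samples=[
        Sample(s.sample_id,
               GroupLabel.CONTROL if s.group == GroupLabel.AIONFH
               else GroupLabel.AIONFH, s.path)
        for s in manifest.samples
    ])
    table_swapped = run_differential(matrix, swapped, seed=7)
    merged = table.merge(table_swapped, on="id", suffixes=("_f", "_r"))
    valid = merged[merged["log2fc_f"].notna()]
    assert np.allclose(valid["log2fc_f"], -valid["log2fc_r"], atol=1e-9)
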