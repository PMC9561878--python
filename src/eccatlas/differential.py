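"""Per-gene differential abundance of circles between two groups.

Group means (optionally total-count normalized) feed a log2 fold change in
which a group mean of exactly zero is *replaced* by a pseudocount (0.001
by default) before the ratio — substitution, not uniform addition, so
nonzero means are untouched.  P-values come from an exact two-sided
Wilcoxon rank-sum (full enumeration for group sizes <= 8, with a
permutation alternative), corrected by Benjamini-Hochberg FDR.  The
significance filter keeps genes with p < alpha and |log2FC| > 1 and
counts up- vs down-regulated targets.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from eccatlas.io_formats import GroupLabel, SampleManifest


@dataclass(frozen=True)
class DifferentialConfig:
    pseudocount: float = 0.001
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    normalization: str = "total_count"   # or "none"
    test: str = "ranksum"                # or "permutation"
    n_permutations: int = 10_000

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if self.normalization not in ("total_count", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.test not in ("ranksum", "permutation"):
            raise ValueError(f"unknown test {self.test!r}")


def normalize_columns(matrix: pd.DataFrame, mode: str = "total_count",
                      ) -> pd.DataFrame:
    """Scale each sample column so its total matches the cohort mean total."""
    if mode == "none":
        return matrix.astype(float)
    if mode != "total_count":
        raise ValueError(f"unknown normalization {mode!r}")
    totals = matrix.sum(axis=0).astype(float)
    target = totals[totals > 0].mean() if (totals > 0).any() else 0.0
    factors = pd.Series(
        [target / t if t > 0 else 1.0 for t in totals], index=matrix.columns
    )
    return matrix.astype(float).mul(factors, axis=1)


def group_means(matrix: pd.DataFrame, manifest: SampleManifest,
                cfg: DifferentialConfig | None = None,
                ) -> pd.DataFrame:
    """Per-gene (mean_control, mean_case) after optional normalization."""
    cfg = cfg or DifferentialConfig()
    manifest.require_both_groups()
    norm = normalize_columns(matrix, cfg.normalization)
    control_ids = [s for s in manifest.ids_in_group(GroupLabel.CONTROL)
                   if s in norm.columns]
    case_ids = [s for s in manifest.ids_in_group(GroupLabel.AIONFH)
                if s in norm.columns]
    if not control_ids or not case_ids:
        raise ValueError("matrix lacks columns for one of the groups")
    return pd.DataFrame({
        "mean_control": norm[control_ids].mean(axis=1),
        "mean_case": norm[case_ids].mean(axis=1),
    })


def compute_log2fc(mean_control: float, mean_case: float,
                   pseudocount: float = 0.001) -> float:
    """log2(case/control) with zero means replaced by the pseudocount.

    Returns NaN when both means are zero (fold change undefined).
    """
    if mean_control < 0 or mean_case < 0:
        raise ValueError("group means must be >= 0")
    if mean_control == 0 and mean_case == 0:
        return math.nan
    c = mean_control if mean_control > 0 else pseudocount
    a = mean_case if mean_case > 0 else pseudocount
    return math.log2(a / c)


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def exact_ranksum_p(control: np.ndarray, case: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration of group labelings.

    Midranks handle ties; the p-value is the fraction of the C(n, n1)
    labelings whose rank-sum deviates from its mean at least as much as
    the observed one.
    """
    pooled = np.concatenate([control, case])
    n1, n = len(control), len(pooled)
    ranks = _midranks(pooled)
    mu = n1 * (n + 1) / 2.0
    t_obs = abs(ranks[:n1].sum() - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        t = abs(ranks[list(combo)].sum() - mu)
        if t >= t_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def _normal_ranksum_p(control: np.ndarray, case: np.ndarray) -> float:
    # tie-corrected normal approximation for larger groups
    res = stats.mannwhitneyu(control, case, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def permutation_p(control: np.ndarray, case: np.ndarray,
                  n_permutations: int = 10_000, seed: int = 0) -> float:
    """Two-sided Monte-Carlo permutation p on the rank-sum statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([control, case])
    n1, n = len(control), len(pooled)
    ranks = _midranks(pooled)
    mu = n1 * (n + 1) / 2.0
    t_obs = abs(ranks[:n1].sum() - mu)
    hits = 0
    for _ in range(n_permutations):
        idx = rng.permutation(n)[:n1]
        if abs(ranks[idx].sum() - mu) >= t_obs - 1e-9:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def test_gene(control, case, cfg: DifferentialConfig | None = None,
              seed: int = 0) -> float:
    """P-value for one gene's control vs case counts."""
    cfg = cfg or DifferentialConfig()
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    if len(control) < 2 or len(case) < 2:
        raise ValueError("each group needs at least 2 values")
    if cfg.test == "permutation":
        return permutation_p(control, case, cfg.n_permutations, seed)
    if max(len(control), len(case)) <= 8:
        return exact_ranksum_p(control, case)
    return _normal_ranksum_p(control, case)


test_gene.__test__ = False  # a library function, despite the name


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_differential(matrix: pd.DataFrame, manifest: SampleManifest,
                     cfg: DifferentialConfig | None = None, seed: int = 0,
                     ) -> pd.DataFrame:
    """Full per-gene differential table.

    Columns: id, control_mean, case_mean, log2fc, pvalue, fdr,
    significant, direction.  Genes with zero counts in both groups keep a
    NaN log2fc and are never significant.
    """
    cfg = cfg or DifferentialConfig()
    means = group_means(matrix, manifest, cfg)
    norm = normalize_columns(matrix, cfg.normalization)
    control_ids = [s for s in manifest.ids_in_group(GroupLabel.CONTROL)
                   if s in norm.columns]
    case_ids = [s for s in manifest.ids_in_group(GroupLabel.AIONFH)
                if s in norm.columns]
    records = []
    for gene_id, row in means.iterrows():
        log2fc = compute_log2fc(row.mean_control, row.mean_case, cfg.pseudocount)
        pvalue = test_gene(norm.loc[gene_id, control_ids].to_numpy(),
                           norm.loc[gene_id, case_ids].to_numpy(), cfg, seed)
        records.append({
            "id": gene_id,
            "control_mean": row.mean_control,
            "case_mean": row.mean_case,
            "log2fc": log2fc,
            "pvalue": pvalue,
        })
    table = pd.DataFrame(records).set_index("id")
    table["fdr"] = bh_fdr(table["pvalue"].to_numpy())
    table["significant"] = (
        (table["pvalue"] < cfg.alpha)
        & (table["log2fc"].abs() > cfg.min_abs_log2fc)
        & table["log2fc"].notna()
    )
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    return table.reset_index()


def significant_genes(table: pd.DataFrame, cfg: DifferentialConfig | None = None,
                      ) -> tuple[pd.DataFrame, int, int]:
    """Apply the p < alpha and |log2FC| > threshold filter; count directions.

    Accepts any table with ``log2fc`` and ``pvalue`` columns (e.g. the
    bundled reference table or :func:`run_differential` output).
    """
    cfg = cfg or DifferentialConfig()
    keep = table[
        (table["pvalue"] < cfg.alpha)
        & (table["log2fc"].abs() > cfg.min_abs_log2fc)
        & table["log2fc"].notna()
    ].copy()
    n_up = int((keep["log2fc"] > 0).sum())
    n_down = int((keep["log2fc"] < 0).sum())
    return keep, n_up, n_down


def load_reference_exon_table() -> pd.DataFrame:
    """Bundled reference table: significant exon-region eccDNA genes.

    Reported group-mean abundances, log2 fold changes and p-values for the
    25 exon-region genes differential between AIONFH and control
    femoral-head Circle-seq cohorts; rows where one group printed the
    0.001 pseudocount mark genes absent from that group.  Columns:
    id, control, aionfh, log2fc, pvalue, fdr, symbol.
    """
    ref = importlib.resources.files("eccatlas.data") / "exon_gene_differential.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
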