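"""End-to-end pipeline: simulate -> call -> classify -> annotate -> cohort -> diff.

Every stage reads and writes plain TSV/FASTA/SAM files in the output
directory, so stages are independently runnable and testable; all
randomness flows from the single global seed in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from eccatlas import __version__
from eccatlas.circle_caller import AlignmentSet, CallerParams, call_circles
from eccatlas.cohort_stats import (
    ConsistencyConfig,
    consistency_filter,
    length_histogram,
    merge_locus_identity,
    partition_by_size,
    venn_counts,
)
from eccatlas.confidence import ConfidenceRules, classify_confidence, summarize_tiers
from eccatlas.differential import (
    DifferentialConfig,
    run_differential,
    significant_genes,
)
from eccatlas.genomic_context import (
    AnnotationIndex,
    build_gene_count_matrix,
    correlate_density,
    density_per_chromosome,
    region_distribution,
)
from eccatlas.io_formats import (
    GroupLabel,
    read_gene_models,
    read_genome_index,
    write_circle_table,
)
from eccatlas.synthetic_data import LengthModel, SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Nested configuration mirroring each stage's parameter set."""

    seed: int = 0
    out_dir: str = "eccatlas_run"
    log_level: str = "INFO"
    n_per_group: int = 7
    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    confidence: ConfidenceRules = field(default_factory=ConfidenceRules)
    flank_bp: int = 2000
    consistency: ConsistencyConfig = field(default_factory=ConsistencyConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = dict(raw.pop("sim", {}))
        if "length_model" in sim_raw:
            sim_raw["length_model"] = LengthModel(**sim_raw["length_model"])
        if "chromosomes" in sim_raw:
            sim_raw["chromosomes"] = [tuple(c) for c in sim_raw["chromosomes"]]
        sections = {
            "caller": CallerParams,
            "confidence": ConfidenceRules,
            "consistency": ConsistencyConfig,
            "differential": DifferentialConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            if name in raw:
                kwargs[name] = klass(**raw.pop(name))
        cfg = cls(sim=SimConfig(**sim_raw), **kwargs, **raw)
        cfg.sim.seed = cfg.seed
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(_as_plain_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _as_plain_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_plain_dict(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _as_plain_dict(v) for k, v in obj.items()}
    return obj


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every violation (empty list means the config is valid)."""
    errors = []
    if config.n_per_group < 1:
        errors.append("n_per_group must be >= 1")
    if not config.sim.chromosomes:
        errors.append("sim.chromosomes must list at least one chromosome")
    for name, length in config.sim.chromosomes:
        if length <= 0:
            errors.append(f"sim chromosome {name}: length must be positive")
    if config.sim.background_depth < 0:
        errors.append("sim.background_depth must be >= 0")
    if not 0 < config.differential.alpha < 1:
        errors.append("differential.alpha must be in (0, 1): "
                      f"got {config.differential.alpha}")
    if config.differential.pseudocount <= 0:
        errors.append("differential.pseudocount must be positive")
    if config.flank_bp < 0:
        errors.append("flank_bp must be >= 0")
    if config.consistency.min_samples < 1:
        errors.append("consistency.min_samples must be >= 1")
    if config.caller.min_structural_reads < 1:
        errors.append("caller.min_structural_reads must be >= 1")
    return errors


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the summary report."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"- {e}" for e in errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata = {
        "tool": "eccatlas", "version": __version__,
        "seed": config.seed, "config_hash": config.config_hash(),
    }

    logger.info("stage simulate: cohort of 2 x %d samples", config.n_per_group)
    try:
        manifest = simulate_cohort(config.sim, out, n_per_group=config.n_per_group)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    genome_index = read_genome_index(out / "genome.tsv")
    genes = read_gene_models(out / "genes.gff3", format="gff3")
    annotation_index = AnnotationIndex(genes, flank_bp=config.flank_bp)

    all_calls = []
    calls_by_sample = {}
    for sample in manifest.samples:
        logger.info("stage call: %s", sample.sample_id)
        try:
            alignments = AlignmentSet.from_sam(sample.path)
            table = call_circles(alignments, out / "genome.fa",
                                 config.caller, sample.sample_id)
        except Exception as exc:
            raise RuntimeError(
                f"stage call failed on {sample.sample_id}: {exc}") from exc
        write_circle_table(table, out / f"calls_{sample.sample_id}.tsv", metadata)
        calls_by_sample[sample.sample_id] = list(table)
        all_calls.extend(table)

    logger.info("stage classify/cohort/annotate")
    tiers = summarize_tiers(all_calls, config.confidence)
    ecc, ec = partition_by_size(all_calls)
    group_calls = {
        g: [c for c in all_calls
            if c.sample_id in set(manifest.ids_in_group(g))]
        for g in GroupLabel
    }
    peaks = {}
    for g, calls in group_calls.items():
        if calls:
            peaks[g.value] = length_histogram(calls).peak_bp
    regions = region_distribution(all_calls, annotation_index)
    correlations = {}
    for g, calls in group_calls.items():
        density = density_per_chromosome(calls, genome_index, genes)
        try:
            corr = correlate_density(density)
            correlations[g.value] = {"r": corr.r, "p": corr.p, "n": corr.n}
        except ValueError as exc:
            correlations[g.value] = {"error": str(exc)}

    loci = merge_locus_identity(all_calls, config.consistency)
    consistent = {
        g.value: consistency_filter(loci, manifest, g, config.consistency)
        for g in GroupLabel
    }
    venn = venn_counts(consistent[GroupLabel.AIONFH.value],
                       consistent[GroupLabel.CONTROL.value], config.consistency)

    logger.info("stage diff")
    matrix = build_gene_count_matrix(calls_by_sample, annotation_index)
    matrix.to_csv(out / "pergene_matrix.tsv", sep="\t")
    try:
        diff = run_differential(matrix, manifest, config.differential,
                                seed=config.seed)
    except Exception as exc:
        raise RuntimeError(f"stage diff failed: {exc}") from exc
    diff.to_csv(out / "differential.tsv", sep="\t", index=False)
    _sig, n_up, n_down = significant_genes(diff, config.differential)

    report = {
        "metadata": metadata,
        "n_samples": len(manifest),
        "n_calls": len(all_calls),
        "size_classes": {"eccDNA": len(ecc), "ecDNA": len(ec)},
        "tiers": tiers,
        "length_peak_bp": peaks,
        "region_distribution": regions,
        "density_correlation": correlations,
        "consistent_loci": {k: len(v) for k, v in consistent.items()},
        "venn": {"only_AIONFH": venn.only_a, "only_control": venn.only_b,
                 "both": venn.both},
        "differential": {"n_genes": int(len(diff)), "n_significant": n_up + n_down,
                         "n_up": n_up, "n_down": n_down},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out / "report.json")
    return report


def load_or_default_config(path: str | Path | None, seed: int | None = None,
                           out_dir: str | None = None) -> PipelineConfig:
    cfg = PipelineConfig.from_yaml(path) if path else PipelineConfig()
    if seed is not None:
        cfg.seed = seed
        cfg.sim.seed = seed
    if out_dir is not None:
        cfg.out_dir = out_dir
    return cfg


def demo_config_yaml() -> str:
    """A small, fast demo configuration (YAML text)."""
    return yaml.safe_dump({
        "seed": 0,
        "out_dir": "eccatlas_demo",
        "n_per_group": 3,
        "sim": {
            "chromosomes": [["chr1", 200000], ["chr2", 160000],
                            ["chr3", 130000], ["chr4", 110000]],
            "genes_per_mb": 30,
            "n_circles": 30,
            "background_depth": 4,
            "junction_read_depth": 6,
        },
    })
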