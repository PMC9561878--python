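"""Synthetic Circle-seq-like data: genomes, genes, planted circles, alignments.

Everything here is a pure function of ``(config, seed)``.  Circle lengths
follow a three-component mixture: a lognormal body whose mode sits at
``mode_bp`` (the short-eccDNA peak near 358 bp seen in Circle-seq cohorts),
a uniform tail reaching into the tens of kb, and a rare ecDNA band
(100 kb - 1 Mb).  Junction evidence is written directly as soft-clipped and
outward-oriented discordant alignments; no aligner is involved, which keeps
the loop hermetic and desk-scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from eccatlas.io_formats import (
    GenomeIndex,
    GeneModel,
    GroupLabel,
    Sample,
    SampleManifest,
    write_gene_models_gff3,
    write_genome_index,
    write_manifest,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class LengthModel:
    """Mixture model for circle lengths.

    ``mode_bp``/``sigma`` parameterize the lognormal body so its mode is at
    ``mode_bp``; ``tail_fraction`` of circles are drawn uniformly from
    ``[tail_min_bp, tail_max_bp]``; ``ecdna_fraction`` from the ecDNA band
    ``[ecdna_min_bp, ecdna_max_bp]``.
    """

    mode_bp: int = 358
    sigma: float = 0.45
    tail_fraction: float = 0.12
    tail_min_bp: int = 2_000
    tail_max_bp: int = 50_000
    ecdna_fraction: float = 0.0
    ecdna_min_bp: int = 100_000
    ecdna_max_bp: int = 1_000_000

    def __post_init__(self):
        if self.mode_bp <= 0:
            raise ValueError("mode_bp must be positive")
        if not 0.0 <= self.ecdna_fraction <= 1.0:
            raise ValueError("ecdna_fraction must be in [0, 1]")
        if self.tail_fraction < 0 or self.tail_fraction + self.ecdna_fraction > 1:
            raise ValueError("mixture fractions must be non-negative and sum <= 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` circle lengths (bp, >= 50)."""
        u = rng.random(n)
        lengths = np.empty(n, dtype=np.int64)
        body = u >= self.tail_fraction + self.ecdna_fraction
        tail = (~body) & (u >= self.ecdna_fraction)
        ecdna = u < self.ecdna_fraction
        # lognormal with mode at mode_bp: mu = ln(mode) + sigma^2
        mu = math.log(self.mode_bp) + self.sigma**2
        lengths[body] = np.round(rng.lognormal(mu, self.sigma, body.sum()))
        lengths[tail] = rng.integers(self.tail_min_bp, self.tail_max_bp + 1, tail.sum())
        lengths[ecdna] = rng.integers(self.ecdna_min_bp, self.ecdna_max_bp + 1,
                                      ecdna.sum())
        return np.maximum(lengths, 50)


@dataclass
class SimConfig:
    """Configuration for one synthetic sample/cohort.

    Rates and depths are per-sample; ``genes_per_mb`` may be a single rate
    or a per-chromosome mapping.  With ``gene_density_coupling`` on, circles
    are allocated to chromosomes proportionally to genes/Mb x Mb, emulating
    the positive coupling between eccDNA output and coding-gene density.
    """

    seed: int = 0
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("chr1", 200_000), ("chr2", 190_000), ("chr3", 180_000),
            ("chr4", 160_000), ("chr5", 150_000), ("chr6", 140_000),
            ("chr7", 120_000), ("chr8", 110_000),
        ]
    )
    genes_per_mb: float | dict[str, float] = 30.0
    n_circles: int = 50
    shared_fraction: float = 0.3
    shared_presence_prob: float = 0.7
    length_model: LengthModel = field(default_factory=LengthModel)
    read_length_bp: int = 100
    insert_mean_bp: int = 250
    insert_sd_bp: int = 25
    background_depth: float = 5.0
    junction_read_depth: int = 6
    gene_density_coupling: bool = False

    def __post_init__(self):
        if self.background_depth < 0 or self.junction_read_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.n_circles < 0:
            raise ValueError("n_circles must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.shared_presence_prob <= 1.0:
            raise ValueError("shared_presence_prob must be in [0, 1]")

    def rate_for(self, chrom: str) -> float:
        if isinstance(self.genes_per_mb, dict):
            if chrom not in self.genes_per_mb:
                raise ValueError(f"genes_per_mb missing for chromosome {chrom!r}")
            rate = self.genes_per_mb[chrom]
        else:
            rate = self.genes_per_mb
        if rate < 0:
            raise ValueError("genes_per_mb must be >= 0")
        return float(rate)


@dataclass
class PlantedCircle:
    chrom: str
    start: int
    end: int
    copy_weight: float = 1.0


@dataclass
class SyntheticTruth:
    """Planted ground truth: circles, gene models, and the genome itself."""

    circles: list[PlantedCircle]
    gene_models: list[GeneModel]
    genome: dict[str, str]
    index: GenomeIndex


def generate_genome(config: SimConfig) -> tuple[dict[str, str], GenomeIndex]:
    """Uniform-random nucleotide sequences for every configured chromosome."""
    if not config.chromosomes:
        raise ValueError("config lists zero chromosomes")
    rng = np.random.default_rng(config.seed)
    genome = {}
    for name, length in config.chromosomes:
        if length <= 0:
            raise ValueError(f"chromosome {name}: non-positive length")
        seq = _BASES[rng.integers(0, 4, int(length))]
        genome[name] = seq.tobytes().decode("ascii")
    return genome, GenomeIndex(entries=tuple((n, int(l)) for n, l in config.chromosomes))


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(Path(path), "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def generate_annotation(index: GenomeIndex, config: SimConfig,
                        max_tries: int = 200) -> list[GeneModel]:
    """Place non-overlapping genes (1-10 exons each) at ``genes_per_mb``.

    Per-chromosome gene counts are Poisson(rate x length/1e6); bodies are
    0.5 - 8 kb, capped at a tenth of the chromosome.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, 1))
    genes: list[GeneModel] = []
    for chrom, length in index.entries:
        rate = config.rate_for(chrom)
        n_genes = int(rng.poisson(rate * length / 1e6))
        placed: list[tuple[int, int]] = []
        for i in range(n_genes):
            for _ in range(max_tries):
                body = int(rng.integers(500, min(8_000, max(length // 10, 501))))
                body = min(body, length - 1)
                start = int(rng.integers(0, length - body))
                end = start + body
                if all(end <= s or start >= e for s, e in placed):
                    placed.append((start, end))
                    break
            else:
                raise RuntimeError(
                    f"could not place gene {i} on {chrom} after {max_tries} tries; "
                    "lower genes_per_mb"
                )
        placed.sort()
        for i, (start, end) in enumerate(placed):
            n_exons = int(rng.integers(1, 11))
            # cut the body into 2*n_exons-1 alternating exon/intron segments
            cuts = np.sort(rng.choice(
                np.arange(start + 1, end), size=max(2 * n_exons - 2, 0), replace=False
            ))
            bounds = [start, *cuts.tolist(), end]
            exons = [
                (bounds[j], bounds[j + 1]) for j in range(0, len(bounds) - 1, 2)
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"{chrom}_g{i + 1}", chrom, start, end, strand,
                                   exons))
    return genes


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def plant_circles(index: GenomeIndex, annotation: list[GeneModel],
                  config: SimConfig, max_tries: int = 100) -> list[PlantedCircle]:
    """Draw circle positions and lengths.

    With ``gene_density_coupling`` on, each circle's chromosome is chosen
    with probability proportional to genes/Mb x (length/1e6) = gene count;
    otherwise proportional to chromosome length.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, 2))
    chroms = index.names
    lengths_bp = np.array([index.length_of(c) for c in chroms], dtype=float)
    if config.gene_density_coupling:
        genes_per_chrom = np.array(
            [sum(1 for g in annotation if g.chrom == c) for c in chroms], dtype=float
        )
        weights = genes_per_chrom
        if weights.sum() == 0:
            weights = lengths_bp
    else:
        weights = lengths_bp
    probs = weights / weights.sum()
    chrom_idx = rng.choice(len(chroms), size=config.n_circles, p=probs)
    circle_lengths = config.length_model.sample(rng, config.n_circles)
    circles = []
    for ci, clen in zip(chrom_idx, circle_lengths):
        chrom = chroms[int(ci)]
        chrom_len = index.length_of(chrom)
        clen = int(clen)
        for _ in range(max_tries):
            if clen < chrom_len:
                break
            clen = int(config.length_model.sample(rng, 1)[0])
        else:
            raise RuntimeError(
                f"cannot fit a circle of the drawn lengths on {chrom} "
                f"({chrom_len} bp)"
            )
        start = int(rng.integers(0, chrom_len - clen))
        circles.append(PlantedCircle(chrom, start, start + clen, 1.0))
    circles.sort(key=lambda c: (c.chrom, c.start, c.end))
    return circles


def build_truth(config: SimConfig) -> SyntheticTruth:
    """Genome + annotation + planted circles in one deterministic call."""
    genome, index = generate_genome(config)
    annotation = generate_annotation(index, config)
    circles = plant_circles(index, annotation, config)
    return SyntheticTruth(circles=circles, gene_models=annotation, genome=genome,
                          index=index)


# ---------------------------------------------------------------------------
# read simulation


def _sam_header(index: GenomeIndex) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in index.entries],
    })


def _segment(header, name, ref_id, pos, seq, cigar, flag, mate_pos=-1,
             tlen=0, mapq=60):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = ref_id
    a.reference_start = pos
    a.query_sequence = seq
    a.cigarstring = cigar
    a.flag = flag
    a.mapping_quality = mapq
    a.next_reference_id = ref_id if mate_pos >= 0 else -1
    a.next_reference_start = mate_pos
    a.template_length = tlen
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


# SAM flag bits
_PAIRED = 0x1
_PROPER = 0x2
_REV = 0x10
_MREV = 0x20
_READ1 = 0x40
_READ2 = 0x80


def _background_pairs(rng, header, chrom, ref_id, seq, config):
    """Concordant inward (FR) pairs uniform over one chromosome."""
    chrom_len = len(seq)
    rl = config.read_length_bp
    n_pairs = int(round(config.background_depth * chrom_len / (2 * rl)))
    out = []
    for i in range(n_pairs):
        insert = int(max(2 * rl, rng.normal(config.insert_mean_bp,
                                            config.insert_sd_bp)))
        insert = min(insert, chrom_len)
        start = int(rng.integers(0, chrom_len - insert + 1))
        p1, p2 = start, start + insert - rl
        name = f"bg_{chrom}_{i}"
        s1 = seq[p1:p1 + rl]
        s2 = seq[p2:p2 + rl]
        out.append(_segment(header, name, ref_id, p1, s1, f"{rl}M",
                            _PAIRED | _PROPER | _MREV | _READ1,
                            mate_pos=p2, tlen=insert))
        out.append(_segment(header, name, ref_id, p2, s2, f"{rl}M",
                            _PAIRED | _PROPER | _REV | _READ2,
                            mate_pos=p1, tlen=-insert))
    return out


def _junction_records(rng, header, ref_id, seq, circle, config, serial):
    """Soft-clipped junction reads + outward discordant pairs for one circle.

    A junction read covers the wrap from the circle's end back to its start:
    aligned either ending exactly at ``end`` with a soft-clipped suffix that
    matches the sequence entering ``start``, or starting exactly at ``start``
    with a soft-clipped prefix matching the sequence before ``end``.
    """
    rl = config.read_length_bp
    s, e = circle.start, circle.end
    clen = e - s
    if rl >= clen:
        logger.warning(
            "circle %s:%d-%d shorter than read length; junction reads skipped",
            circle.chrom, s, e,
        )
        return []
    depth = config.junction_read_depth
    n_split = max((depth + 1) // 2, 1) if depth > 0 else 0
    n_disc = max(depth - n_split, 1 if depth >= 2 else 0)
    records = []
    min_clip = 15
    for j in range(n_split):
        k = int(rng.integers(min_clip, rl - min_clip + 1))  # matched prefix length
        if j % 2 == 0:
            # aligned part ends at e; clipped suffix = genome[s : s+rl-k]
            read = seq[e - k:e] + seq[s:s + rl - k]
            records.append(_segment(
                header, f"sr_{serial}_{j}", ref_id, e - k, read,
                f"{k}M{rl - k}S", 0
            ))
        else:
            # clipped prefix = genome[e-(rl-k) : e]; aligned part starts at s
            read = seq[e - (rl - k):e] + seq[s:s + k]
            records.append(_segment(
                header, f"sr_{serial}_{j}", ref_id, s, read,
                f"{rl - k}S{k}M", 0
            ))
    if clen >= 2 * rl:
        for j in range(n_disc):
            insert = int(max(2 * rl, rng.normal(config.insert_mean_bp,
                                                config.insert_sd_bp)))
            insert = min(insert, clen)
            # fragment wraps the junction: [e-a, e) upstream + [s, s+b) downstream
            a = int(rng.integers(rl, insert - rl + 1)) if insert > 2 * rl else rl
            b = insert - a
            p_fwd = e - a            # forward mate, ends before the junction
            p_rev = s + b - rl       # reverse mate, downstream of the wrap
            name = f"dp_{serial}_{j}"
            records.append(_segment(
                header, name, ref_id, p_fwd, seq[p_fwd:p_fwd + rl], f"{rl}M",
                _PAIRED | _MREV | _READ1, mate_pos=p_rev, tlen=0
            ))
            records.append(_segment(
                header, name, ref_id, p_rev, seq[p_rev:p_rev + rl], f"{rl}M",
                _PAIRED | _REV | _READ2, mate_pos=p_fwd, tlen=0
            ))
    else:
        logger.warning(
            "circle %s:%d-%d too short for discordant pairs at read length %d",
            circle.chrom, s, e, rl,
        )
    return records


def simulate_reads(truth: SyntheticTruth, config: SimConfig,
                   sam_path: str | Path, evidence_path: str | Path | None = None,
                   ) -> None:
    """Write a coordinate-sorted SAM with background + junction evidence.

    Alongside the SAM, a truth-to-evidence TSV maps every junction read name
    to the planted circle it supports (written when ``evidence_path`` given).
    """
    rng = np.random.default_rng(_derive_seed(config.seed, 3))
    header = _sam_header(truth.index)
    records = []
    evidence: list[tuple[str, str, int, int]] = []
    for ref_id, (chrom, _len) in enumerate(truth.index.entries):
        seq = truth.genome[chrom]
        records.extend(_background_pairs(rng, header, chrom, ref_id, seq, config))
        for serial, circle in enumerate(truth.circles):
            if circle.chrom != chrom:
                continue
            recs = _junction_records(rng, header, ref_id, seq, circle, config,
                                     f"{chrom}_{serial}")
            records.extend(recs)
            evidence.extend(
                (r.query_name, circle.chrom, circle.start, circle.end) for r in recs
            )
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name,
                                r.flag))
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for rec in records:
            out.write(rec)
    if evidence_path is not None:
        seen = set()
        with open(Path(evidence_path), "w") as fh:
            fh.write("read_name\tchrom\tstart\tend\n")
            for name, chrom, s, e in evidence:
                if name in seen:
                    continue
                seen.add(name)
                fh.write(f"{name}\t{chrom}\t{s}\t{e}\n")


def write_truth_table(circles: list[PlantedCircle], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("chrom\tstart\tend\tcopy_weight\n")
        for c in circles:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_weight}\n")


def simulate_cohort(config: SimConfig, out_dir: str | Path,
                    n_per_group: int = 7) -> SampleManifest:
    """Simulate a two-group cohort sharing one genome and annotation.

    A ``shared_fraction`` of each sample's circles comes from a
    cohort-level pool (each pool circle enters a sample with probability
    ``shared_presence_prob``), so loci recur across samples and the
    consistency/overlap analyses have signal; the remainder is private to
    the sample.  Genome, annotation, per-sample SAMs, truth tables and a
    manifest are written to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, index = generate_genome(config)
    annotation = generate_annotation(index, config)
    write_fasta(genome, out / "genome.fa")
    write_genome_index(index, out / "genome.tsv")
    write_gene_models_gff3(annotation, out / "genes.gff3")
    n_shared = int(round(config.shared_fraction * config.n_circles))
    pool_cfg = replace(config, seed=_derive_seed(config.seed, 4),
                       n_circles=n_shared)
    pool = plant_circles(index, annotation, pool_cfg) if n_shared else []
    samples = []
    groups = [GroupLabel.AIONFH] * n_per_group + [GroupLabel.CONTROL] * n_per_group
    for i, group in enumerate(groups):
        sample_id = f"{group.value}_{i % n_per_group + 1}"
        sample_cfg = replace(config, seed=_derive_seed(config.seed, 100 + i),
                             n_circles=config.n_circles - n_shared)
        rng = np.random.default_rng(_derive_seed(config.seed, 200 + i))
        shared = [c for c in pool
                  if rng.random() < config.shared_presence_prob]
        circles = sorted(shared + plant_circles(index, annotation, sample_cfg),
                         key=lambda c: (c.chrom, c.start, c.end))
        truth = SyntheticTruth(circles, annotation, genome, index)
        sam = out / f"sample_{sample_id}.sam"
        simulate_reads(truth, sample_cfg, sam, out / f"evidence_{sample_id}.tsv")
        write_truth_table(circles, out / f"truth_{sample_id}.tsv")
        samples.append(Sample(sample_id, group, str(sam)))
    manifest = SampleManifest(samples=samples)
    write_manifest(manifest, out / "manifest.tsv")
    return manifest


def simulate_gene_counts(n_genes: int = 100, n_per_group: int = 7,
                         base_mean: float = 20.0, planted_ratio: float = 4.0,
                         n_planted: int = 10, seed: int = 0,
                         ) -> tuple["pd.DataFrame", SampleManifest, list[str]]:
    """Per-gene circle-count matrix with a planted between-group effect.

    Counts are Poisson around a per-gene baseline (lognormal across genes);
    the first ``n_planted`` genes have their case-group mean multiplied by
    ``planted_ratio``.  Returns (matrix, manifest, planted gene ids); the
    manifest's paths are empty placeholders.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    baseline = base_mean * rng.lognormal(0.0, 0.5, n_genes)
    case_mean = baseline.copy()
    case_mean[:n_planted] *= planted_ratio
    columns = {}
    samples = []
    for g, label, means in ((GroupLabel.AIONFH, "AIONFH", case_mean),
                            (GroupLabel.CONTROL, "control", baseline)):
        for j in range(n_per_group):
            sid = f"{label}_{j + 1}"
            columns[sid] = rng.poisson(means)
            samples.append(Sample(sid, g, ""))
    matrix = pd.DataFrame(columns, index=gene_ids)
    return matrix, SampleManifest(samples=samples), gene_ids[:n_planted]
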