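"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open
(BED-style); ``length = end - start``.  GFF3 input (1-based closed) is
converted on read and back on write, so round-trips are exact.
Chromosome names are matched verbatim — no ``chr`` stripping.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class GroupLabel(str, enum.Enum):
    """Cohort group label: AIONFH cases vs femoral-neck-fracture controls."""

    AIONFH = "AIONFH"
    CONTROL = "control"

    @classmethod
    def parse(cls, text: str) -> "GroupLabel":
        for member in cls:
            if member.value == text:
                return member
        allowed = ", ".join(m.value for m in cls)
        raise ValueError(f"unknown group label {text!r}; allowed: {allowed}")


@dataclass(frozen=True)
class GenomeIndex:
    """Chromosome name/length table (the ``.fai``-like genome index)."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome index")
        for name, length in self.entries:
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def length_of(self, chrom: str) -> int:
        for name, length in self.entries:
            if name == chrom:
                return length
        raise KeyError(f"chromosome {chrom!r} not in genome index")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def total_length(self) -> int:
        return sum(length for _, length in self.entries)


@dataclass
class CircleCall:
    """One detected circular-DNA interval with its read-level evidence.

    ``n_split`` counts junction-confirming soft-clipped reads,
    ``n_discordant`` outward-oriented read pairs.  ``coverage_fraction`` is
    the fraction of interval bases with depth >= 1; the two
    ``cov_increase_*`` ratios measure the relative depth step at each
    boundary (flank vs interior), all in [0, 1].
    """

    chrom: str
    start: int
    end: int
    n_split: int = 0
    n_discordant: int = 0
    coverage_fraction: float = 0.0
    cov_increase_start: float = 0.0
    cov_increase_end: float = 0.0
    sample_id: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"circle end ({self.end}) must exceed start ({self.start})"
            )
        if self.n_split < 0 or self.n_discordant < 0:
            raise ValueError("read counts must be non-negative")
        for name in ("coverage_fraction", "cov_increase_start", "cov_increase_end"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_structural(self) -> int:
        return self.n_split + self.n_discordant


NATIVE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_split",
    "n_discordant",
    "coverage_fraction",
    "cov_increase_start",
    "cov_increase_end",
    "sample_id",
]

#: Headerless Circle-Map-style output layout (one call per line).
CIRCLEMAP_COLUMNS = [
    "chrom",
    "start",
    "end",
    "discordant_reads",
    "split_reads",
    "circle_score",
    "mean_coverage",
    "stdev",
    "coverage_increase_start",
    "coverage_increase_end",
    "coverage_continuity",
]


@dataclass
class CircleCallTable:
    """An ordered collection of :class:`CircleCall` rows."""

    rows: list[CircleCall] = field(default_factory=list)
    dialect: str = "native"

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def validate_against(self, genome: GenomeIndex) -> None:
        for row in self.rows:
            if row.chrom not in genome:
                raise ValueError(f"call chromosome {row.chrom!r} not in genome index")
            if row.end > genome.length_of(row.chrom):
                raise ValueError(
                    f"call {row.chrom}:{row.start}-{row.end} exceeds chromosome length"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in NATIVE_COLUMNS] for r in self.rows],
            columns=NATIVE_COLUMNS,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dialect: str = "native") -> "CircleCallTable":
        rows = [
            CircleCall(
                chrom=str(rec.chrom),
                start=int(rec.start),
                end=int(rec.end),
                n_split=int(rec.n_split),
                n_discordant=int(rec.n_discordant),
                coverage_fraction=float(rec.coverage_fraction),
                cov_increase_start=float(rec.cov_increase_start),
                cov_increase_end=float(rec.cov_increase_end),
                sample_id=str(rec.sample_id),
            )
            for rec in df.itertuples(index=False)
        ]
        return cls(rows=rows, dialect=dialect)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: GroupLabel
    path: str


@dataclass
class SampleManifest:
    """Binds sample ids to group labels and per-sample call files."""

    samples: list[Sample]

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in manifest")

    def __len__(self) -> int:
        return len(self.samples)

    def ids_in_group(self, group: GroupLabel) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    def require_both_groups(self) -> None:
        for group in GroupLabel:
            if not self.ids_in_group(group):
                raise ValueError(f"manifest has no samples in group {group.value!r}")


# ---------------------------------------------------------------------------
# circle call tables


def _parse_circle_row(fields: Sequence[str], dialect: str, lineno: int,
                      sample_id: str) -> CircleCall:
    try:
        if dialect == "circlemap":
            if len(fields) < 11:
                raise ParseError(
                    f"expected >=11 columns for circlemap dialect, got {len(fields)}",
                    lineno,
                )
            if len(fields) > 11:
                logger.warning(
                    "line %d: ignoring %d extra circlemap columns",
                    lineno, len(fields) - 11,
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            n_discordant, n_split = int(fields[3]), int(fields[4])
            cov_inc_start, cov_inc_end = float(fields[8]), float(fields[9])
            coverage_fraction = float(fields[10])
            return CircleCall(
                chrom=chrom, start=start, end=end,
                n_split=n_split, n_discordant=n_discordant,
                coverage_fraction=coverage_fraction,
                cov_increase_start=cov_inc_start,
                cov_increase_end=cov_inc_end,
                sample_id=sample_id,
            )
        raise ValueError(f"unknown dialect {dialect!r}")
    except ParseError:
        raise
    except ValueError as exc:
        raise ParseError(str(exc), lineno) from exc


def read_circle_table(path: str | Path, dialect: str = "native",
                      sample_id: str = "") -> CircleCallTable:
    """Read a circle-call table.

    ``native`` is the header-bearing TSV written by
    :func:`write_circle_table`; ``circlemap`` is the headerless 11-column
    layout (chrom, start, end, discordant reads, split reads, circle score,
    mean coverage, stdev, coverage increase start, coverage increase end,
    coverage continuity).  Coordinates are 0-based half-open in both.
    """
    path = Path(path)
    if dialect == "native":
        rows = []
        header: list[str] | None = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields
                    missing = set(NATIVE_COLUMNS) - set(header)
                    if missing:
                        raise ParseError(
                            f"native table missing columns: {sorted(missing)}", lineno
                        )
                    continue
                if len(fields) != len(header):
                    raise ParseError(
                        f"expected {len(header)} columns, got {len(fields)}", lineno
                    )
                rec = dict(zip(header, fields))
                try:
                    rows.append(
                        CircleCall(
                            chrom=rec["chrom"],
                            start=int(rec["start"]),
                            end=int(rec["end"]),
                            n_split=int(rec["n_split"]),
                            n_discordant=int(rec["n_discordant"]),
                            coverage_fraction=float(rec["coverage_fraction"]),
                            cov_increase_start=float(rec["cov_increase_start"]),
                            cov_increase_end=float(rec["cov_increase_end"]),
                            sample_id=rec["sample_id"],
                        )
                    )
                except ValueError as exc:
                    raise ParseError(str(exc), lineno) from exc
        if header is None:
            raise ParseError("empty native table (no header line)")
        return CircleCallTable(rows=rows, dialect="native")
    if dialect == "circlemap":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                rows.append(
                    _parse_circle_row(line.split("\t"), "circlemap", lineno, sample_id)
                )
        return CircleCallTable(rows=rows, dialect="circlemap")
    raise ValueError(f"unknown dialect {dialect!r}; use 'native' or 'circlemap'")


def write_circle_table(table: CircleCallTable, path: str | Path,
                       metadata: dict | None = None) -> None:
    """Write the native header-bearing TSV (with optional ``#`` metadata lines)."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(NATIVE_COLUMNS) + "\n")
        for row in table.rows:
            fh.write(
                "\t".join(str(getattr(row, c)) for c in NATIVE_COLUMNS) + "\n"
            )


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """A gene body with merged, sorted exons (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene span "
                    f"({self.start},{self.end})"
                )
        self.exons = merge_intervals(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s},{e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"BED12 needs 12 columns, got {len(fields)}", lineno)
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(offsets) != n_blocks:
                    raise ValueError("blockCount disagrees with blockSizes/blockStarts")
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                genes.append(GeneModel(name, chrom, start, end, strand, exons))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
    return genes


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path: Path) -> list[GeneModel]:
    gene_records: dict[str, dict] = {}
    exon_records: list[tuple[str, str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"GFF3 needs 9 columns, got {len(fields)}", lineno)
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = fields
            try:
                start = int(start1) - 1  # 1-based closed -> 0-based half-open
                end = int(end1)
                attributes = _parse_gff_attributes(attrs)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            if ftype == "gene":
                gene_id = attributes.get("ID")
                if gene_id is None:
                    raise ParseError("gene feature lacks ID attribute", lineno)
                if strand not in ("+", "-"):
                    raise ParseError(f"unknown strand {strand!r}", lineno)
                gene_records[gene_id] = dict(
                    chrom=chrom, start=start, end=end, strand=strand, exons=[]
                )
            elif ftype == "exon":
                parent = attributes.get("Parent")
                if parent is None:
                    raise ParseError("exon feature lacks Parent attribute", lineno)
                exon_records.append((parent, chrom, start, end, lineno))
    for parent, chrom, start, end, lineno in exon_records:
        if parent not in gene_records:
            raise ParseError(f"exon Parent {parent!r} references missing gene", lineno)
        gene = gene_records[parent]
        if chrom != gene["chrom"] or start < gene["start"] or end > gene["end"]:
            raise ParseError(
                f"exon ({chrom}:{start}-{end}) outside gene {parent!r} span", lineno
            )
        gene["exons"].append((start, end))
    return [
        GeneModel(gene_id, rec["chrom"], rec["start"], rec["end"], rec["strand"],
                  rec["exons"])
        for gene_id, rec in gene_records.items()
    ]


def read_gene_models(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from BED12 or a GFF3 subset (gene + exon, Parent-linked).

    GFF3's 1-based closed coordinates are converted to the internal 0-based
    half-open convention; exons are merged and sorted within each gene.
    """
    path = Path(path)
    if format == "bed12":
        return _read_bed12(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown gene-model format {format!r}; use 'bed12' or 'gff3'")


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a GFF3 subset (gene + exon features)."""
    with open(Path(path), "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write(
                f"{gene.chrom}\teccatlas\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for i, (s, e) in enumerate(gene.exons, start=1):
                fh.write(
                    f"{gene.chrom}\teccatlas\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# manifest and genome index


def read_manifest(path: str | Path) -> SampleManifest:
    """Read the sample manifest TSV (columns: sample_id, group, path)."""
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype=str)
    required = {"sample_id", "group", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"manifest missing columns: {sorted(missing)}")
    samples = [
        Sample(rec.sample_id, GroupLabel.parse(rec.group), rec.path)
        for rec in df.itertuples(index=False)
    ]
    return SampleManifest(samples=samples)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("sample_id\tgroup\tpath\n")
        for s in manifest.samples:
            fh.write(f"{s.sample_id}\t{s.group.value}\t{s.path}\n")


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Read a two-column chromosome/length TSV (``.fai``-compatible prefix)."""
    entries = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("genome index needs chrom and length columns", lineno)
            try:
                entries.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
    return GenomeIndex(entries=tuple(entries))


def write_genome_index(genome: GenomeIndex, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for name, length in genome.entries:
            fh.write(f"{name}\t{length}\n")
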