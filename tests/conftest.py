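"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import pytest

from eccatlas.circle_caller import AlignmentSet
from eccatlas.io_formats import CircleCall
from eccatlas.synthetic_data import (
    SimConfig,
    build_truth,
    simulate_reads,
    _sam_header,
    _segment,
)

RECOVERY_CONFIG = dict(
    chromosomes=[("chr1", 400_000), ("chr2", 300_000)],
    n_circles=50,
    background_depth=5.0,
    junction_read_depth=6,
)


@pytest.fixture(scope="session")
def recovery_dataset(tmp_path_factory):
    """One simulated sample: 50 planted circles with junction evidence."""
    cfg = SimConfig(seed=1, **RECOVERY_CONFIG)
    truth = build_truth(cfg)
    sam = tmp_path_factory.mktemp("recovery") / "sample.sam"
    simulate_reads(truth, cfg, sam, sam.with_suffix(".evidence.tsv"))
    return cfg, truth, sam


@pytest.fixture()
def make_call():
    """Factory for calls where only some metric fields matter."""

    def _make(chrom="chr1", start=100, end=458, n_split=1, n_discordant=1,
              coverage_fraction=1.0, cov_increase_start=1.0,
              cov_increase_end=1.0, sample_id="S1"):
        return CircleCall(
            chrom=chrom, start=start, end=end, n_split=n_split,
            n_discordant=n_discordant, coverage_fraction=coverage_fraction,
            cov_increase_start=cov_increase_start,
            cov_increase_end=cov_increase_end, sample_id=sample_id,
        )

    return _make


@pytest.fixture()
def alignment_builder():
    """Build an in-memory AlignmentSet from (pos, cigar, flag, ...) specs."""

    def _build(references, segments):
        from eccatlas.io_formats import GenomeIndex

        index = GenomeIndex(entries=tuple(references))
        header = _sam_header(index)
        aln = AlignmentSet(references=list(references))
        for spec in segments:
            seg = _segment(header, **spec)
            aln.by_chrom[references[spec["ref_id"]][0]].append(seg)
        return aln

    return _build
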