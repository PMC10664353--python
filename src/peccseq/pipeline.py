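"""End-to-end orchestration: reads in, accepted mutations out.

``call_sample`` wires the stages together in the order the method
prescribes: retain proper pairs at high MAPQ, reconstruct fragments,
compute the all-read depth profile and bulk-variant blacklist from the
*full* read set, subsample fragments, form 4-read consensus groups, call
consensus bases, and run the four-stage filter chain.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .alignment import AlignedRead, compute_depth, pair_reads, read_alignments
from .consensus import collect_candidates, form_consensus_groups, subsample_fragments
from .filters import (
    FilterReport,
    SampleCallResult,
    build_support_index,
    call_bulk_variants,
    run_filter_chain,
)
from .reference import ReferenceGenome

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of the calling pipeline, serialisable to YAML/JSON.

    Defaults are the method's published operating point: MAPQ >= 60 proper
    pairs, 10% fragment subsampling, a strict (30, 100) all-read depth
    window, at most 2 mutations per consensus group, and no terminal-end
    trimming (S1-nuclease-treated libraries need none).
    """

    min_mapq: int = 60
    require_proper_pair: bool = True
    subsample_fraction: float = 0.1
    subsample_seed: int = 0
    depth_low: int = 30
    depth_high: int = 100
    max_group_mutations: int = 2
    bulk_min_support: int = 2
    bulk_min_fraction: float = 0.25
    end_trim_bp: int = 0
    strict_denominator: bool = False
    group_average_mode: str = "mean_of_samples"
    fold_change_mode: str = "frequency_ratio"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class CallOutput:
    result: SampleCallResult
    report: FilterReport
    n_fragments: int = 0
    n_groups: int = 0


def call_reads(
    reads: list[AlignedRead],
    ref: ReferenceGenome,
    config: RunConfig | None = None,
    sample: str = "sample",
) -> CallOutput:
    """Run the pipeline on already-filtered in-memory reads."""
    config = config or RunConfig()
    fragments, pair_stats = pair_reads(reads)
    depth = compute_depth(reads, ref.lengths)
    support = build_support_index(reads, ref)
    bulk = call_bulk_variants(
        reads, ref, depth,
        min_alt_support=config.bulk_min_support,
        min_alt_fraction=config.bulk_min_fraction,
        support=support,
    )
    subsampled = subsample_fragments(
        fragments, config.subsample_fraction, seed=config.subsample_seed
    )
    groups, grouping_stats = form_consensus_groups(subsampled)
    pre = collect_candidates(
        groups, ref, end_trim_bp=config.end_trim_bp, grouping_stats=grouping_stats
    )
    result, report = run_filter_chain(
        pre, bulk, depth, support,
        depth_low=config.depth_low,
        depth_high=config.depth_high,
        max_group_mutations=config.max_group_mutations,
        sample=sample,
        strict_denominator=config.strict_denominator,
    )
    result.diagnostics["pairing"] = vars(pair_stats)
    result.diagnostics["n_bulk_sites"] = len(bulk)
    return CallOutput(
        result=result, report=report,
        n_fragments=len(fragments), n_groups=len(groups),
    )


def call_sample(
    sam_path: str | Path,
    ref: ReferenceGenome,
    config: RunConfig | None = None,
    sample: str = "sample",
) -> CallOutput:
    """Run the pipeline on a SAM/BAM file against ``ref``.

    The SAM header contigs must match the reference; a mismatch is fatal.
    """
    config = config or RunConfig()
    reads, read_stats = read_alignments(
        sam_path,
        min_mapq=config.min_mapq,
        require_proper_pair=config.require_proper_pair,
    )
    header_contigs = {r.contig for r in reads}
    unknown = header_contigs - set(ref.contigs)
    if unknown:
        raise ValueError(
            f"contigs in {sam_path} absent from reference: {sorted(unknown)}"
        )
    out = call_reads(reads, ref, config=config, sample=sample)
    out.result.diagnostics["read_filtering"] = vars(read_stats)
    return out
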