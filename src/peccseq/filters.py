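"""The four-stage artifact/SNP filter chain.

Candidates confirmed by 4-read duplex agreement still contain germline
SNPs (the consensus group faithfully reports the molecule's alleles) and
loci rendered unreliable by mapping depth.  Four set-reductions are
applied in a fixed order:

1. bulk-variant exclusion — sites also called from the full (non-
   subsampled) read set, i.e. germline alleles visible at bulk allele
   fractions;
2. depth window — candidate positions must have all-read depth strictly
   between a lower and upper bound (defaults 30 and 100);
3. group mutation count — a consensus group proposing more than
   ``max_group_mutations`` (default 2) surviving candidates is discarded
   wholesale (a chimeric or mismapped molecule);
4. external support — a candidate also carried by any read *outside* its
   own consensus group is discarded (residual animal-specific SNPs).

Each stage reports input / removed / surviving counts; survivors of stage
4 are the accepted mutations.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import AlignedRead, DepthProfile
from .consensus import CandidateMutation, ConsensusGroup, PreFilterResult
from .reference import ReferenceGenome

logger = logging.getLogger(__name__)

Site = tuple[str, int, str]  # (contig, 0-based pos, alt)


@dataclass
class SupportIndex:
    """Alt-supporting reads at every mismatched site in a read set.

    ``read_counts`` counts reads (mates separately); ``qnames`` records
    the supporting templates, which is what the external-support filter
    needs to exclude a group's own four reads.
    """

    qnames: dict[Site, set[str]]
    read_counts: dict[Site, int]

    def qnames_at(self, site: Site) -> set[str]:
        return self.qnames.get(site, set())


def build_support_index(reads: list[AlignedRead], ref: ReferenceGenome) -> SupportIndex:
    """One pass over all retained reads, recording every mismatch.

    Serves both bulk variant calling and the external-support filter.
    """
    qnames: dict[Site, set[str]] = defaultdict(set)
    counts: dict[Site, int] = Counter()
    for read in reads:
        refslice = ref.slice(read.contig, read.start, read.end)
        for off in np.flatnonzero(read.bases != refslice):
            site = (read.contig, read.start + int(off), chr(read.bases[off]))
            qnames[site].add(read.qname)
            counts[site] += 1
    return SupportIndex(qnames=dict(qnames), read_counts=dict(counts))


@dataclass
class BulkVariantSet:
    """Variant sites called from the full read set (germline blacklist)."""

    sites: set[Site]
    min_alt_support: int
    min_alt_fraction: float

    def __contains__(self, site: Site) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)


def call_bulk_variants(
    reads: list[AlignedRead],
    ref: ReferenceGenome,
    depth: DepthProfile,
    min_alt_support: int = 2,
    min_alt_fraction: float = 0.25,
    support: SupportIndex | None = None,
) -> BulkVariantSet:
    """Frequency-threshold variant caller over all retained reads.

    A (pos, alt) enters the bulk set iff at least ``min_alt_support``
    reads carry the alternate AND the supporting reads are at least
    ``min_alt_fraction`` of the all-read depth at the position.  The
    fraction requirement separates germline alleles (allele fraction ~0.5
    het, ~1 hom) from a single duplex molecule's four reads sitting inside
    an otherwise reference-matching pileup: without it every
    duplex-confirmed mutation would blacklist itself, and the 0.25 default
    keeps a lone family's self-support (at most 4/31 ~ 0.13 inside the
    default depth window) safely below threshold.
    """
    if support is None:
        support = build_support_index(reads, ref)
    sites = set()
    for site, n in support.read_counts.items():
        if n < min_alt_support:
            continue
        d = depth.depth(site[0], site[1])
        if d > 0 and n / d >= min_alt_fraction:
            sites.add(site)
    logger.info("call_bulk_variants: %d bulk sites", len(sites))
    return BulkVariantSet(sites, min_alt_support, min_alt_fraction)


# ---------------------------------------------------------------------------
# the four stages — each a pure set-reduction marking removed candidates


def filter_bulk_overlap(
    candidates: list[CandidateMutation], bulk: BulkVariantSet
) -> list[CandidateMutation]:
    survivors = []
    for c in candidates:
        if c.site in bulk:
            c.status = "bulk_overlap"
        else:
            survivors.append(c)
    return survivors


def filter_depth_window(
    candidates: list[CandidateMutation],
    depth: DepthProfile,
    low: int = 30,
    high: int = 100,
) -> list[CandidateMutation]:
    """Keep candidates with ``low < depth(pos) < high`` (strict bounds)."""
    survivors = []
    for c in candidates:
        if low < depth.depth(c.contig, c.pos) < high:
            survivors.append(c)
        else:
            c.status = "depth_window"
    return survivors


def filter_group_mutation_count(
    candidates: list[CandidateMutation], max_mutations: int = 2
) -> list[CandidateMutation]:
    """Discard all candidates of groups with more than ``max_mutations``.

    The tally is over the candidates given (i.e. survivors of the previous
    stage).
    """
    per_group = Counter(c.group_id for c in candidates)
    survivors = []
    for c in candidates:
        if per_group[c.group_id] > max_mutations:
            c.status = "group_mutation_count"
        else:
            survivors.append(c)
    return survivors


def filter_external_support(
    candidates: list[CandidateMutation],
    groups: dict[int, ConsensusGroup],
    support: SupportIndex,
) -> list[CandidateMutation]:
    """Discard candidates carried by any read outside their own group."""
    survivors = []
    for c in candidates:
        outside = support.qnames_at(c.site) - groups[c.group_id].qnames
        if outside:
            c.status = "external_support"
        else:
            survivors.append(c)
    return survivors


# ---------------------------------------------------------------------------
# chain


@dataclass
class FilterStage:
    name: str
    n_input: int
    n_removed: int
    n_surviving: int
    params: dict = field(default_factory=dict)


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def stage(self, name: str) -> FilterStage:
        return next(s for s in self.stages if s.name == name)

    def reconciles(self) -> bool:
        return all(s.n_input - s.n_removed == s.n_surviving for s in self.stages) and all(
            a.n_surviving == b.n_input for a, b in zip(self.stages, self.stages[1:])
        )

    def to_dict(self) -> dict:
        return {
            "stages": [vars(s) for s in self.stages],
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=int)


@dataclass
class SampleCallResult:
    """Accepted mutations and the analysed-base denominator for one sample."""

    sample: str
    accepted: list[CandidateMutation]
    candidates: list[CandidateMutation]  # all, with per-stage status
    analyzed_bases: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_mutations(self) -> int:
        return len(self.accepted)

    @property
    def mutation_frequency(self) -> float:
        if self.analyzed_bases == 0:
            raise ZeroDivisionError("no analysed bases")
        return self.n_mutations / self.analyzed_bases

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "sample": self.sample,
                    "contig": c.contig,
                    "pos": c.pos,
                    "ref": c.ref,
                    "alt": c.alt,
                    "context": c.context,
                    "group_id": c.group_id,
                    "status": c.status,
                }
                for c in self.candidates
            ],
            columns=["sample", "contig", "pos", "ref", "alt", "context", "group_id", "status"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_vcf(self, path: str | Path, contig_lengths: dict[str, int]) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for contig, length in contig_lengths.items():
                fh.write(f"##contig=<ID={contig},length={length}>\n")
            fh.write('##INFO=<ID=CTX,Number=1,Type=String,Description="Reference 3-mer context">\n')
            fh.write('##INFO=<ID=GRP,Number=1,Type=Integer,Description="Consensus group id">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for c in sorted(self.accepted, key=lambda c: (c.contig, c.pos)):
                fh.write(
                    f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                    f"CTX={c.context or '.'};GRP={c.group_id}\n"
                )


def run_filter_chain(
    pre: PreFilterResult,
    bulk: BulkVariantSet,
    depth: DepthProfile,
    support: SupportIndex,
    depth_low: int = 30,
    depth_high: int = 100,
    max_group_mutations: int = 2,
    sample: str = "sample",
    strict_denominator: bool = False,
) -> tuple[SampleCallResult, FilterReport]:
    """Apply the four stages in order and assemble the final call set.

    By default ``analyzed_bases`` passes through unchanged — the mutation
    frequency is computed against everything the consensus groups
    interrogated.  ``strict_denominator=True`` instead restricts the
    denominator to analysed positions inside the depth window, matching
    the numerator's depth constraint.
    """
    report = FilterReport()
    candidates = list(pre.candidates)

    def record(name: str, before: list, after: list, **params) -> None:
        report.stages.append(
            FilterStage(
                name=name,
                n_input=len(before),
                n_removed=len(before) - len(after),
                n_surviving=len(after),
                params=params,
            )
        )

    s0 = candidates
    s1 = filter_bulk_overlap(s0, bulk)
    record(
        "bulk_overlap", s0, s1,
        min_alt_support=bulk.min_alt_support, min_alt_fraction=bulk.min_alt_fraction,
    )
    s2 = filter_depth_window(s1, depth, low=depth_low, high=depth_high)
    record("depth_window", s1, s2, low=depth_low, high=depth_high)
    s3 = filter_group_mutation_count(s2, max_mutations=max_group_mutations)
    record("group_mutation_count", s2, s3, max_mutations=max_group_mutations)
    s4 = filter_external_support(s3, pre.groups, support)
    record("external_support", s3, s4)

    # the group-count tally is order-ambiguous in principle; report how many
    # groups the pre-depth tally would have discarded as a diagnostic
    pre_depth_tally = Counter(c.group_id for c in s1)
    report.diagnostics["groups_over_count_pre_depth"] = sum(
        1 for n in pre_depth_tally.values() if n > max_group_mutations
    )
    post_depth_tally = Counter(c.group_id for c in s2)
    report.diagnostics["groups_over_count_post_depth"] = sum(
        1 for n in post_depth_tally.values() if n > max_group_mutations
    )
    if pre.grouping_stats is not None:
        report.diagnostics["grouping"] = vars(pre.grouping_stats)

    analyzed = pre.analyzed_bases
    if strict_denominator:
        analyzed = 0
        for gid, call in pre.group_calls.items():
            group = pre.groups[gid]
            darr = depth.depths[group.contig][group.start : group.end]
            window = (darr > depth_low) & (darr < depth_high)
            analyzed += int((call.analyzed_mask & window).sum())

    result = SampleCallResult(
        sample=sample,
        accepted=s4,
        candidates=candidates,
        analyzed_bases=analyzed,
        diagnostics=dict(report.diagnostics),
    )
    logger.info(
        "filter chain (%s): %d candidates -> %d accepted over %d analysed bases",
        sample, len(candidates), len(s4), analyzed,
    )
    return result, report
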