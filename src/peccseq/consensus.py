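"""Duplex consensus: fragment subsampling, 4-read group formation, calling.

A consensus read group is exactly four reads: two fully coordinate-
coincident read pairs, one derived from each strand of one original
double-stranded molecule.  In a PCR-free library, exact coincidence of
fragment coordinates on opposite strands is, with high probability, the
signature of a shared molecule of origin — which is what makes agreement
of all four reads evidence for a true double-stranded variant rather than
sequencing error or single-strand damage.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .alignment import FragmentObservation
from .reference import ReferenceGenome
from .sbs96 import context_key

logger = logging.getLogger(__name__)


def subsample_fragments(
    fragments: list[FragmentObservation], fraction: float, seed: int = 0
) -> list[FragmentObservation]:
    """Keep each fragment independently with probability ``fraction``.

    The subsampling unit is the fragment (a read pair is kept or dropped
    whole).  ``fraction=1`` is the identity.  Used to bound the cost of
    grouping on deep libraries.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return list(fragments)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(fragments)) < fraction
    return [f for f, k in zip(fragments, keep) if k]


@dataclass(slots=True)
class ConsensusGroup:
    group_id: int
    contig: str
    start: int
    end: int
    frag_plus: FragmentObservation
    frag_minus: FragmentObservation

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def qnames(self) -> frozenset[str]:
        return frozenset((self.frag_plus.qname, self.frag_minus.qname))

    def read_matrix(self) -> np.ndarray:
        """(4, length) base-call matrix: plus-strand mates then minus."""
        return np.vstack([self.frag_plus.calls, self.frag_minus.calls])


@dataclass
class GroupingStats:
    n_fragments: int = 0
    n_keys: int = 0
    n_groups: int = 0
    n_keys_single: int = 0
    n_keys_same_strand: int = 0  # 2 fragments, but not complementary
    n_keys_overloaded: int = 0   # >2 coincident fragments, excluded


def form_consensus_groups(
    fragments: list[FragmentObservation],
) -> tuple[list[ConsensusGroup], GroupingStats]:
    """Group fragments sharing (contig, start, end) on opposite strands.

    A group forms iff a fragment key holds *exactly* two fragments with
    complementary strands of origin ("only four reads").  Keys with a
    single fragment, two same-strand fragments, or three or more
    coincident fragments form no group; the latter two cases are the
    coincident-molecule ambiguity and are reported in the diagnostics.
    """
    stats = GroupingStats(n_fragments=len(fragments))
    by_key: dict[tuple[str, int, int], list[FragmentObservation]] = defaultdict(list)
    for frag in fragments:
        by_key[frag.key].append(frag)
    stats.n_keys = len(by_key)
    groups: list[ConsensusGroup] = []
    for key in sorted(by_key):
        bucket = by_key[key]
        if len(bucket) == 1:
            stats.n_keys_single += 1
            continue
        if len(bucket) > 2:
            stats.n_keys_overloaded += 1
            continue
        a, b = bucket
        if a.strand == b.strand:
            stats.n_keys_same_strand += 1
            continue
        plus, minus = (a, b) if a.strand == "+" else (b, a)
        groups.append(
            ConsensusGroup(
                group_id=len(groups),
                contig=key[0],
                start=key[1],
                end=key[2],
                frag_plus=plus,
                frag_minus=minus,
            )
        )
    stats.n_groups = len(groups)
    return groups, stats


@dataclass(slots=True)
class CandidateMutation:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    context: str | None  # reference-strand 3-mer; None at contig edge
    group_id: int
    status: str = "pass"  # 'pass' or the name of the filter stage that removed it

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.alt)

    @property
    def context_key(self) -> str | None:
        if self.context is None:
            return None
        return context_key(self.ref, self.alt, self.context[0], self.context[2])


@dataclass
class GroupCall:
    group_id: int
    analyzed: int
    candidates: list[CandidateMutation]
    analyzed_mask: np.ndarray  # bool over the group interval (post-trim)


def call_group_consensus(
    group: ConsensusGroup,
    ref: ReferenceGenome,
    end_trim_bp: int = 0,
) -> GroupCall:
    """Compare the four base calls at every group position.

    All four equal to the reference -> position analysed, no call.  All
    four equal to the same alternate -> position analysed, candidate
    mutation.  Any disagreement (including a position some read does not
    cover) -> the position is excluded from numerator *and* denominator:
    it is neither confirmed reference nor confirmed variant.

    ``end_trim_bp`` masks that many bases off each fragment end — an
    option for libraries whose terminal bases carry end-repair artefacts;
    with S1-nuclease-treated libraries it stays 0.
    """
    mat = group.read_matrix()
    refslice = ref.slice(group.contig, group.start, group.end)
    covered = (mat > 0).all(axis=0)
    agree = covered & (mat == mat[0]).all(axis=0)
    if end_trim_bp > 0:
        agree = agree.copy()
        agree[:end_trim_bp] = False
        if end_trim_bp < agree.size:
            agree[-end_trim_bp:] = False
        else:
            agree[:] = False
    is_alt = agree & (mat[0] != refslice)
    candidates = [
        CandidateMutation(
            contig=group.contig,
            pos=group.start + int(off),
            ref=chr(refslice[off]),
            alt=chr(mat[0, off]),
            context=ref.trinucleotide(group.contig, group.start + int(off)),
            group_id=group.group_id,
        )
        for off in np.flatnonzero(is_alt)
    ]
    return GroupCall(
        group_id=group.group_id,
        analyzed=int(agree.sum()),
        candidates=candidates,
        analyzed_mask=agree,
    )


@dataclass
class PreFilterResult:
    """Candidate mutations and the analysed-base denominator, pre-filter.

    ``analyzed_bases`` is summed per group: two overlapping groups that
    both confirm the same locus each contribute it — the denominator is a
    throughput measure, not a genomic footprint.
    """

    candidates: list[CandidateMutation]
    analyzed_bases: int
    groups: dict[int, "ConsensusGroup"]
    group_calls: dict[int, GroupCall]
    grouping_stats: GroupingStats | None = None
    diagnostics: dict = field(default_factory=dict)


def collect_candidates(
    groups: list[ConsensusGroup],
    ref: ReferenceGenome,
    end_trim_bp: int = 0,
    grouping_stats: GroupingStats | None = None,
) -> PreFilterResult:
    """Call every group and accumulate candidates and analysed bases."""
    candidates: list[CandidateMutation] = []
    analyzed = 0
    calls: dict[int, GroupCall] = {}
    for group in groups:
        call = call_group_consensus(group, ref, end_trim_bp=end_trim_bp)
        calls[group.group_id] = call
        analyzed += call.analyzed
        candidates.extend(call.candidates)
    logger.info(
        "collect_candidates: %d groups, %d analysed bases, %d candidates",
        len(groups), analyzed, len(candidates),
    )
    return PreFilterResult(
        candidates=candidates,
        analyzed_bases=analyzed,
        groups={g.group_id: g for g in groups},
        group_calls=calls,
        grouping_stats=grouping_stats,
    )
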