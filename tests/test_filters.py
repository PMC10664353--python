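"""Filter chain: each stage against brute-force oracles, ordering, reports."""

import numpy as np
import pytest

import _oracles as oracles
from conftest import make_family, reads_for
from peccseq import (
    SomaticMutationModel,
    build_support_index,
    call_bulk_variants,
    collect_candidates,
    compute_depth,
    filter_bulk_overlap,
    filter_depth_window,
    filter_external_support,
    filter_group_mutation_count,
    form_consensus_groups,
    generate_reference,
    pair_reads,
    plant_germline_variants,
    run_filter_chain,
    simulate_fragments,
)
from peccseq.consensus import CandidateMutation
from peccseq.filters import BulkVariantSet, SupportIndex


def _cand(pos, group_id=0, contig="chr1", ref="A", alt="T"):
    return CandidateMutation(
        contig=contig, pos=pos, ref=ref, alt=alt, context=None, group_id=group_id
    )


@pytest.fixture()
def messy_sample():
    """A small library with germline SNPs, somatic mutations, lesions and
    sequencing error — enough structure to exercise every stage."""
    ref = generate_reference(1, 50_000, 0.45, seed=51)
    germ = plant_germline_variants(ref, 2e-3, 2e-3, seed=52)
    fams = simulate_fragments(
        ref, germ, SomaticMutationModel.flat(5e-4), 3000,
        duplex_yield=0.8, coincident_rate=0.05, lesion_rate=1e-5, seed=53,
    )
    reads = reads_for(ref, fams, error_rate=0.003, seed=54)
    frags, _ = pair_reads(reads)
    groups, gstats = form_consensus_groups(frags)
    pre = collect_candidates(groups, ref, grouping_stats=gstats)
    depth = compute_depth(reads, ref.lengths)
    support = build_support_index(reads, ref)
    return ref, fams, reads, pre, depth, support


# ---------------------------------------------------------------------------
# bulk variant calling


def test_bulk_calls_match_pileup_oracle(messy_sample):
    ref, _fams, reads, _pre, depth, support = messy_sample
    for min_support, min_fraction in [(2, 0.25), (1, 0.0), (5, 0.4)]:
        bulk = call_bulk_variants(
            reads, ref, depth,
            min_alt_support=min_support, min_alt_fraction=min_fraction,
            support=support,
        )
        assert bulk.sites == oracles.bulk_oracle(
            reads, ref, ref.lengths, min_support, min_fraction
        )


def test_bulk_includes_hom_snp_excludes_singleton(ref_small):
    pos, start = 300, 250
    alt = "C" if ref_small.base("chr1", pos) != "C" else "G"
    # ten coincident-but-distinct molecules all carrying the variant (hom-like)
    fams = [
        make_family(start=start, molecule_id=i, variants=[(pos, alt, "germline_hom")])
        for i in range(10)
    ]
    reads = reads_for(ref_small, fams)
    depth = compute_depth(reads, ref_small.lengths)
    bulk = call_bulk_variants(reads, ref_small, depth)
    assert ("chr1", pos, alt) in bulk

    # a singleton mismatch (one read) stays out at min_alt_support=2
    solo = reads_for(ref_small, [make_family(start=start, molecule_id=99)])
    solo[0].bases = solo[0].bases.copy()
    solo[0].bases[10] = ord("A") if chr(solo[0].bases[10]) != "A" else ord("T")
    all_reads = reads + solo
    depth2 = compute_depth(all_reads, ref_small.lengths)
    bulk2 = call_bulk_variants(all_reads, ref_small, depth2)
    site = ("chr1", start + 10, chr(solo[0].bases[10]))
    assert site not in bulk2


# ---------------------------------------------------------------------------
# individual stages


def test_bulk_overlap_stage():
    bulk = BulkVariantSet({("chr1", 5, "T")}, 2, 0.25)
    cands = [_cand(5), _cand(6)]
    kept = filter_bulk_overlap(cands, bulk)
    assert [c.pos for c in kept] == [6]
    assert cands[0].status == "bulk_overlap"
    assert cands[1].status == "pass"


def test_depth_window_strict_bounds(ref_small):
    class FakeDepth:
        def __init__(self, values):
            self.values = values

        def depth(self, contig, pos):
            return self.values[pos]

    depth = FakeDepth({0: 30, 1: 31, 2: 99, 3: 100, 4: 60})
    cands = [_cand(i) for i in range(5)]
    kept = filter_depth_window(cands, depth, low=30, high=100)
    assert [c.pos for c in kept] == [1, 2, 4]
    assert cands[0].status == "depth_window"
    assert cands[3].status == "depth_window"


def test_group_mutation_count_stage():
    cands = [_cand(1, 0), _cand(2, 0), _cand(3, 0), _cand(4, 1), _cand(5, 1)]
    kept = filter_group_mutation_count(cands, max_mutations=2)
    assert [c.pos for c in kept] == [4, 5]
    assert all(c.status == "group_mutation_count" for c in cands[:3])


def test_external_support_stage(ref_small):
    pos = 260
    alt = "T" if ref_small.base("chr1", pos) != "T" else "A"
    fam = make_family(start=200, variants=[(pos, alt, "somatic")])
    reads = reads_for(ref_small, [fam])
    frags, _ = pair_reads(reads)
    groups, _ = form_consensus_groups(frags)
    pre = collect_candidates(groups, ref_small)
    (cand,) = pre.candidates

    # only the group's own reads support -> retained
    support = build_support_index(reads, ref_small)
    assert filter_external_support([cand], pre.groups, support) == [cand]

    # one extra outside read with the same alt -> removed
    outside = reads_for(
        ref_small,
        [make_family(start=240, molecule_id=7, strands="plus_only",
                     variants=[(pos, alt, "somatic")])],
    )
    cand.status = "pass"
    support2 = build_support_index(reads + outside, ref_small)
    assert filter_external_support([cand], pre.groups, support2) == []
    assert cand.status == "external_support"


def test_stage_oracles_on_random_candidates(messy_sample):
    ref, _fams, reads, pre, depth, support = messy_sample
    assert pre.candidates, "fixture should produce candidates"

    survivors = filter_depth_window(list(pre.candidates), depth, 30, 100)
    brute_depth = oracles.depth_filter_oracle(
        pre.candidates, {c: depth.depths[c] for c in ref.contigs}, 30, 100
    )
    assert [c.site for c in survivors] == [c.site for c in brute_depth]

    kept = filter_group_mutation_count(list(pre.candidates), 2)
    assert [c.site for c in kept] == [
        c.site for c in oracles.group_count_oracle(pre.candidates, 2)
    ]

    for c in pre.candidates:
        c.status = "pass"
    kept_ext = filter_external_support(list(pre.candidates), pre.groups, support)
    brute_ext = oracles.external_support_oracle(pre.candidates, pre.groups, reads)
    assert [c.site for c in kept_ext] == [c.site for c in brute_ext]


# ---------------------------------------------------------------------------
# the chain


def test_empty_candidates_pass_through(messy_sample):
    ref, _fams, reads, pre, depth, support = messy_sample
    pre.candidates = []
    bulk = call_bulk_variants(reads, ref, depth, support=support)
    result, report = run_filter_chain(pre, bulk, depth, support)
    assert result.accepted == []
    assert all(s.n_removed == 0 for s in report.stages)
    assert report.reconciles()


def test_report_reconciles_and_statuses_partition(messy_sample):
    ref, _fams, reads, pre, depth, support = messy_sample
    bulk = call_bulk_variants(reads, ref, depth, support=support)
    result, report = run_filter_chain(
        pre, bulk, depth, support, depth_low=2, depth_high=60
    )
    assert report.reconciles()
    assert report.stages[0].n_input == len(pre.candidates)
    assert report.stages[-1].n_surviving == len(result.accepted)
    n_removed = sum(1 for c in result.candidates if c.status != "pass")
    assert n_removed + len(result.accepted) == len(result.candidates)
    assert set(c.status for c in result.candidates) <= {
        "pass", "bulk_overlap", "depth_window", "group_mutation_count",
        "external_support",
    }


def test_filter_order_matters_regression(ref_small):
    """A group proposing three candidates, one of which is a bulk
    (germline) site: bulk exclusion first leaves two candidates and the
    group survives the >2-mutations rule; tallying before bulk exclusion
    would have discarded the whole group."""
    positions = [220, 240, 260]
    alts = ["T" if ref_small.base("chr1", p) != "T" else "G" for p in positions]
    cands = [
        _cand(p, group_id=0, ref=ref_small.base("chr1", p), alt=a)
        for p, a in zip(positions, alts)
    ]
    bulk = BulkVariantSet({("chr1", positions[0], alts[0])}, 2, 0.25)

    class AnyDepth:
        def depth(self, contig, pos):
            return 50

    after_bulk = filter_bulk_overlap([c for c in cands], bulk)
    after_depth = filter_depth_window(after_bulk, AnyDepth())
    survivors = filter_group_mutation_count(after_depth, 2)
    assert len(survivors) == 2

    # swapped order: group-count tally sees all 3 and discards the group
    for c in cands:
        c.status = "pass"
    swapped = filter_group_mutation_count([c for c in cands], 2)
    assert swapped == []


def test_strict_denominator_restricts_to_depth_window(messy_sample):
    ref, _fams, reads, pre, depth, support = messy_sample
    bulk = call_bulk_variants(reads, ref, depth, support=support)
    loose, _ = run_filter_chain(pre, bulk, depth, support)
    strict, _ = run_filter_chain(
        pre, bulk, depth, support, strict_denominator=True
    )
    assert strict.analyzed_bases <= loose.analyzed_bases
    # brute force: per analysed position, is all-read depth in the window?
    expected = 0
    for gid, call in pre.group_calls.items():
        group = pre.groups[gid]
        for off in np.flatnonzero(call.analyzed_mask):
            if 30 < depth.depth(group.contig, group.start + int(off)) < 100:
                expected += 1
    assert strict.analyzed_bases == expected
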