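"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (per-position loops, text parsing,
dict bucketing) and shares no code with the package's implementations.
"""

from collections import Counter, defaultdict

import numpy as np


def depth_oracle(reads, contig_lengths):
    """Per-position depth by looping over every read and position."""
    depths = {c: np.zeros(n, dtype=int) for c, n in contig_lengths.items()}
    for read in reads:
        for pos in range(read.start, read.end):
            depths[read.contig][pos] += 1
    return depths


def sam_retained_oracle(sam_text, min_mapq=60):
    """Count records surviving the MAPQ/proper-pair filter by parsing SAM
    text directly and testing flag bits by hand."""
    n = 0
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        flag = int(fields[1])
        mapq = int(fields[4])
        cigar = fields[5]
        if flag & 0x4 or flag & 0x8:      # read or mate unmapped
            continue
        if flag & 0x100 or flag & 0x800:  # secondary / supplementary
            continue
        if not flag & 0x2:                # not a proper pair
            continue
        if mapq < min_mapq:
            continue
        if not cigar.endswith("M") or not cigar[:-1].isdigit():
            continue
        n += 1
    return n


def pair_interval_oracle(reads):
    """qname -> (contig, min start, max end) over its records."""
    spans = {}
    for read in reads:
        if read.qname in spans:
            c, s, e = spans[read.qname]
            spans[read.qname] = (c, min(s, read.start), max(e, read.end))
        else:
            spans[read.qname] = (read.contig, read.start, read.end)
    return spans


def grouping_oracle(fragments):
    """Set of frozenset-of-qnames forming valid 4-read groups, by sorting
    fragments into buckets and testing each bucket independently."""
    buckets = defaultdict(list)
    for frag in fragments:
        buckets[(frag.contig, frag.start, frag.end)].append(frag)
    groups = set()
    for members in buckets.values():
        if len(members) != 2:
            continue
        strands = sorted(f.strand for f in members)
        if strands == ["+", "-"]:
            groups.add(frozenset(f.qname for f in members))
    return groups


def bulk_oracle(reads, ref, contig_lengths, min_support, min_fraction):
    """Per-position pileup: count alt-carrying reads and compare against
    both thresholds."""
    support = Counter()
    for read in reads:
        for off in range(len(read.bases)):
            pos = read.start + off
            base = chr(read.bases[off])
            if base != chr(ref.contigs[read.contig][pos]):
                support[(read.contig, pos, base)] += 1
    depths = depth_oracle(reads, contig_lengths)
    sites = set()
    for (contig, pos, alt), n in support.items():
        d = depths[contig][pos]
        if n >= min_support and d > 0 and n / d >= min_fraction:
            sites.add((contig, pos, alt))
    return sites


def depth_filter_oracle(candidates, depths, low, high):
    return [
        c for c in candidates if low < depths[c.contig][c.pos] < high
    ]


def group_count_oracle(candidates, max_mutations):
    tally = Counter(c.group_id for c in candidates)
    return [c for c in candidates if tally[c.group_id] <= max_mutations]


def external_support_oracle(candidates, groups, reads):
    """Scan every read for every candidate: any outside read carrying the
    alt at the position removes the candidate."""
    kept = []
    for c in candidates:
        group_qnames = groups[c.group_id].qnames
        supported_outside = False
        for read in reads:
            if read.qname in group_qnames or read.contig != c.contig:
                continue
            if read.start <= c.pos < read.end:
                if chr(read.bases[c.pos - read.start]) == c.alt:
                    supported_outside = True
                    break
        kept.append((c, not supported_outside))
    return [c for c, keep in kept if keep]


def consensus_oracle(group, ref):
    """Per-position 4-read comparison by explicit looping."""
    analyzed = 0
    candidates = []
    reads = [group.frag_plus.calls[0], group.frag_plus.calls[1],
             group.frag_minus.calls[0], group.frag_minus.calls[1]]
    for off in range(group.end - group.start):
        calls = [int(r[off]) for r in reads]
        if 0 in calls or len(set(calls)) != 1:
            continue
        analyzed += 1
        refbase = int(ref.contigs[group.contig][group.start + off])
        if calls[0] != refbase:
            candidates.append((group.start + off, chr(refbase), chr(calls[0])))
    return analyzed, candidates
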