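"""Aligned-read ingestion, mate pairing, and depth computation.

Reads are reduced to the minimum the duplex pipeline needs: reference
coordinates, reference-oriented base calls, mapping quality and the pairing
flags.  Only full-match (M-only CIGAR) alignments are supported; reads with
indels or clips are dropped and counted, consistent with the pipeline's
substitution-only scope.  Base qualities are never consulted — error
correction comes from 4-read agreement, not quality scores.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class AlignedRead:
    """One mapped read: reference-oriented bases at a contig interval."""

    qname: str
    contig: str
    start: int  # 0-based
    bases: np.ndarray  # uint8 ASCII, reference orientation
    mapq: int = 60
    is_read1: bool = True
    is_reverse: bool = False
    mate_is_reverse: bool = True
    is_proper_pair: bool = True

    @property
    def end(self) -> int:
        return self.start + len(self.bases)


@dataclass
class ReadFilterStats:
    n_records: int = 0
    n_kept: int = 0
    n_unmapped: int = 0
    n_secondary: int = 0
    n_not_proper: int = 0
    n_low_mapq: int = 0
    n_bad_cigar: int = 0


def read_alignments(
    path: str | Path,
    min_mapq: int = 60,
    require_proper_pair: bool = True,
) -> tuple[list[AlignedRead], ReadFilterStats]:
    """Load mapped reads from SAM/BAM, keeping proper pairs at high MAPQ.

    The MAPQ threshold is inclusive (``mapq >= min_mapq``): BWA caps MAPQ at
    60, so the conventional "high quality" cut retains the cap value.
    Secondary, supplementary and unmapped records are discarded, as are
    reads whose CIGAR is not a single match run.
    """
    stats = ReadFilterStats()
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=True) as fh:
        if not fh.header.references:
            raise ValueError(f"{path}: SAM/BAM header has no reference contigs")
        for rec in fh.fetch(until_eof=True):
            stats.n_records += 1
            if rec.is_unmapped or rec.mate_is_unmapped:
                stats.n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.n_secondary += 1
                continue
            if require_proper_pair and not rec.is_proper_pair:
                stats.n_not_proper += 1
                continue
            if rec.mapping_quality < min_mapq:
                stats.n_low_mapq += 1
                continue
            cig = rec.cigartuples
            if cig is None or len(cig) != 1 or cig[0][0] != 0:
                stats.n_bad_cigar += 1
                continue
            reads.append(
                AlignedRead(
                    qname=rec.query_name,
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    bases=np.frombuffer(
                        rec.query_sequence.upper().encode("ascii"), dtype=np.uint8
                    ).copy(),
                    mapq=rec.mapping_quality,
                    is_read1=rec.is_read1,
                    is_reverse=rec.is_reverse,
                    mate_is_reverse=rec.mate_is_reverse,
                    is_proper_pair=rec.is_proper_pair,
                )
            )
            stats.n_kept += 1
    logger.info(
        "read_alignments: kept %d/%d records (unmapped %d, secondary %d, "
        "improper %d, low MAPQ %d, non-M CIGAR %d)",
        stats.n_kept, stats.n_records, stats.n_unmapped, stats.n_secondary,
        stats.n_not_proper, stats.n_low_mapq, stats.n_bad_cigar,
    )
    return reads, stats


@dataclass(slots=True)
class FragmentObservation:
    """A properly-paired read pair reduced to its fragment footprint.

    ``calls`` is a (2, fragment length) array of ASCII base codes — row 0 is
    read 1, row 1 is read 2 — padded with 0 where a mate does not cover a
    position.  ``strand`` records which strand of the original duplex the
    library insert derived from: '+' when read 1 mapped forward, '-' when
    read 1 mapped reverse.
    """

    qname: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    calls: np.ndarray  # (2, end-start) uint8, 0 = not covered

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    def mate_agreement(self) -> np.ndarray:
        """Boolean mask of positions where both mates agree."""
        covered = (self.calls > 0).all(axis=0)
        return covered & (self.calls[0] == self.calls[1])


@dataclass
class PairingStats:
    n_reads: int = 0
    n_fragments: int = 0
    n_orphans: int = 0
    n_overpaired_names: int = 0  # query names with >2 records, discarded


def pair_reads(reads: list[AlignedRead]) -> tuple[list[FragmentObservation], PairingStats]:
    """Join mates by query name into fragment observations.

    The fragment interval is the union of the two mate spans; orphaned
    mates and names with more than two records are discarded and counted.
    """
    stats = PairingStats(n_reads=len(reads))
    by_name: dict[str, list[AlignedRead]] = defaultdict(list)
    for read in reads:
        by_name[read.qname].append(read)
    fragments: list[FragmentObservation] = []
    for qname, mates in by_name.items():
        if len(mates) == 1:
            stats.n_orphans += 1
            continue
        if len(mates) > 2:
            stats.n_overpaired_names += 1
            continue
        a, b = mates
        if a.contig != b.contig:
            stats.n_orphans += 1
            continue
        read1 = a if a.is_read1 else b
        start = min(a.start, b.start)
        end = max(a.end, b.end)
        calls = np.zeros((2, end - start), dtype=np.uint8)
        for row, mate in ((0, read1), (1, b if read1 is a else a)):
            calls[row, mate.start - start : mate.end - start] = mate.bases
        fragments.append(
            FragmentObservation(
                qname=qname,
                contig=a.contig,
                start=start,
                end=end,
                strand="-" if read1.is_reverse else "+",
                calls=calls,
            )
        )
        stats.n_fragments += 1
    if stats.n_orphans or stats.n_overpaired_names:
        logger.info(
            "pair_reads: %d fragments, %d orphans, %d over-paired names dropped",
            stats.n_fragments, stats.n_orphans, stats.n_overpaired_names,
        )
    return fragments, stats


@dataclass
class DepthProfile:
    """Per-contig read depth from all retained mapped reads.

    Mates of a pair are counted separately, so a fully overlapping pair
    contributes depth 2 over its fragment.
    """

    depths: dict[str, np.ndarray]

    def depth(self, contig: str, pos: int) -> int:
        arr = self.depths.get(contig)
        if arr is None or pos < 0 or pos >= arr.size:
            return 0
        return int(arr[pos])

    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.depths.values()))

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.depths):
                arr = self.depths[contig]
                # run-length encode constant-depth intervals
                change = np.flatnonzero(np.diff(arr)) + 1
                bounds = np.concatenate(([0], change, [arr.size]))
                for s, e in zip(bounds[:-1], bounds[1:]):
                    if arr[s]:
                        fh.write(f"{contig}\t{s}\t{e}\t{int(arr[s])}\n")


def compute_depth(
    reads: list[AlignedRead], contig_lengths: dict[str, int]
) -> DepthProfile:
    """Depth(p) = number of retained reads whose aligned span covers p."""
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in contig_lengths.items()}
    for read in reads:
        d = diffs[read.contig]
        d[read.start] += 1
        d[read.end] -= 1
    return DepthProfile({c: np.cumsum(d[:-1]) for c, d in diffs.items()})
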