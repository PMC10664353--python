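"""Reference genomes: random generation, FASTA I/O, context lookup.

Sequences are held internally as numpy ``uint8`` arrays of ASCII codes
(A/C/G/T only), which lets downstream read comparison and consensus calling
run as vectorised array operations.  Coordinates are 0-based half-open
throughout the library; the 1-based convention of SAM/VCF is confined to the
I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: ASCII codes of the four bases in alphabetical order.
BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII -> 0..3 lookup (255 for non-ACGT).
ASCII_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    ASCII_TO_INDEX[_c] = _i

# ASCII -> complement ASCII.
ASCII_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    ASCII_COMPLEMENT[_a] = _b


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class ReferenceGenome:
    """Named contigs of A/C/G/T with a (nominal) GC fraction.

    ``gc_fraction`` records the target used at generation time (or the
    observed fraction for genomes read from FASTA); every contig must be at
    least 3 bp so that interior positions have a trinucleotide context.
    """

    contigs: dict[str, np.ndarray] = field(default_factory=dict)
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        for name, arr in self.contigs.items():
            if arr.size < 3:
                raise ValueError(f"contig {name!r} shorter than 3 bp")
            if not np.isin(arr, BASE_CODES).all():
                raise ValueError(f"contig {name!r} contains non-ACGT bases")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: int(arr.size) for name, arr in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(arr.size for arr in self.contigs.values())

    def sequence(self, contig: str) -> str:
        return array_to_seq(self.contigs[contig])

    def slice(self, contig: str, start: int, end: int) -> np.ndarray:
        """Read-only view of a contig interval (0-based half-open)."""
        arr = self.contigs[contig]
        if start < 0 or end > arr.size:
            raise IndexError(f"[{start}, {end}) outside contig {contig!r}")
        return arr[start:end]

    def base(self, contig: str, pos: int) -> str:
        return chr(self.contigs[contig][pos])

    def trinucleotide(self, contig: str, pos: int) -> str | None:
        """Reference 3-mer centred on ``pos``; None at contig edges."""
        arr = self.contigs[contig]
        if pos < 1 or pos > arr.size - 2:
            return None
        return array_to_seq(arr[pos - 1 : pos + 2])

    def observed_gc(self) -> float:
        gc = total = 0
        for arr in self.contigs.values():
            gc += int(((arr == ord("G")) | (arr == ord("C"))).sum())
            total += arr.size
        return gc / total


def generate_reference(
    n_contigs: int,
    contig_length: int,
    gc_fraction: float,
    seed: int,
) -> ReferenceGenome:
    """Draw i.i.d. bases with P(G) = P(C) = gc_fraction / 2.

    Deterministic for a fixed seed. ``contig_length`` must be at least
    1000 bp — shorter contigs are dominated by edge effects and are not a
    meaningful substrate for fragment simulation.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    if n_contigs < 1:
        raise ValueError("n_contigs must be positive")
    if contig_length < 1000:
        raise ValueError("contig_length must be >= 1000")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    probs = np.array([at, gc, gc, at])
    contigs = {
        f"chr{i + 1}": BASE_CODES[rng.choice(4, size=contig_length, p=probs)]
        for i in range(n_contigs)
    }
    return ReferenceGenome(contigs=contigs, gc_fraction=gc_fraction)


def read_fasta(path: str | Path) -> ReferenceGenome:
    contigs = {rec.id: seq_to_array(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    ref = ReferenceGenome(contigs=contigs)
    ref.gc_fraction = ref.observed_gc()
    return ref


def write_fasta(ref: ReferenceGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(array_to_seq(arr)), id=name, description="")
        for name, arr in ref.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
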