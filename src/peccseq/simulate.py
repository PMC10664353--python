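"""Synthetic PCR-free duplex sequencing libraries with known truth.

The generator emulates the structure that UMI-free duplex error correction
relies on: genomic DNA is fragmented to ~150 bp and both strands of each
double-stranded molecule become independent library inserts with *identical*
mapped coordinates (no PCR, so coordinate coincidence implies a shared
molecule of origin).  Each sequenced strand yields one fully overlapping
2x150 read pair, so a duplex molecule is observed as four reads.

What is modelled, per molecule:

* true double-stranded somatic mutations, drawn so that the planted
  96-context class distribution equals a configurable signature exactly
  (per-position rates are inversely weighted by genome context abundance)
  with an overall expected rate of ``target_frequency`` per base;
* germline SNPs — heterozygous sites are carried by each molecule with
  probability 1/2, homozygous sites always;
* single-strand lesions (e.g. oxidative damage), present on one strand
  only and therefore visible in exactly two of the four reads;
* i.i.d. substitution sequencing error per read at a configurable rate.

Indels, PCR amplification, quality-score error profiles and alignment
artefacts are out of scope; reads are emitted truth-aligned (MAPQ 60,
proper-pair flags) so no external aligner is needed, with FASTQ export for
users who want to run one.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .alignment import AlignedRead
from .reference import (
    ASCII_COMPLEMENT,
    ASCII_TO_INDEX,
    BASE_CODES,
    ReferenceGenome,
    array_to_seq,
)
from . import sbs96

logger = logging.getLogger(__name__)

_DEFAULT_QUAL_CHAR = "F"  # Q37; the pipeline never consults base qualities


# ---------------------------------------------------------------------------
# somatic mutation model


@dataclass
class SomaticMutationModel:
    """A 96-context substitution signature plus a per-base mutation rate.

    ``signature`` is a nonnegative vector over the 96 pyrimidine-centric
    (class x 5' flank x 3' flank) categories in conventional SBS96 order,
    summing to 1.  ``target_frequency`` is the expected number of somatic
    mutations per base per molecule.
    """

    signature: np.ndarray
    target_frequency: float

    def __post_init__(self) -> None:
        self.signature = np.asarray(self.signature, dtype=float)
        if self.signature.shape != (96,):
            raise ValueError("signature must have 96 entries")
        if (self.signature < 0).any():
            raise ValueError("signature weights must be nonnegative")
        if abs(self.signature.sum() - 1.0) > 1e-9:
            raise ValueError("signature weights must sum to 1 (tol 1e-9)")
        if not 0.0 <= self.target_frequency <= 1e-2:
            raise ValueError("target_frequency must be in [0, 1e-2]")

    @classmethod
    def flat(cls, target_frequency: float) -> "SomaticMutationModel":
        """Uniform weight on all 96 categories (control-like spectrum)."""
        return cls(np.full(96, 1.0 / 96.0), target_frequency)

    @classmethod
    def den_like(cls, target_frequency: float) -> "SomaticMutationModel":
        """T>A-dominant spectrum like the one diethylnitrosamine induces
        in rodent liver: mostly A:T>T:A transversions, with A:T>C:G and
        A:T>G:C as the next most frequent classes.  Weights are uniform
        across the 16 contexts within each class.
        """
        class_mass = {
            "T>A": 0.70, "T>G": 0.12, "T>C": 0.10,
            "C>T": 0.04, "C>A": 0.03, "C>G": 0.01,
        }
        w = np.empty(96)
        for i, key in enumerate(sbs96.SBS96_CONTEXTS):
            w[i] = class_mass[sbs96.key_class(key)] / 16.0
        return cls(w, target_frequency)


# ---------------------------------------------------------------------------
# germline variants


@dataclass(slots=True)
class GermlineVariant:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    zygosity: str  # 'het' | 'hom'


@dataclass
class GermlineVariantSet:
    entries: list[GermlineVariant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def by_contig(self) -> dict[str, list[GermlineVariant]]:
        out: dict[str, list[GermlineVariant]] = defaultdict(list)
        for v in self.entries:
            out[v.contig].append(v)
        for lst in out.values():
            lst.sort(key=lambda v: v.pos)
        return dict(out)


def plant_germline_variants(
    ref: ReferenceGenome,
    het_rate: float = 1e-4,
    hom_rate: float = 1e-3,
    seed: int = 0,
) -> GermlineVariantSet:
    """Scatter het/hom SNPs uniformly at the given per-base rates.

    Rates are modest by construction (the combined rate may not exceed
    0.1): these emulate animal-specific SNPs, a false-positive confounder,
    not dense divergence.  Defaults reflect an inbred laboratory strain
    mapped against a different strain's assembly: little residual
    heterozygosity (1e-4) and ~1e-3 homozygous divergence.
    """
    if het_rate < 0 or hom_rate < 0:
        raise ValueError("germline rates must be nonnegative")
    if het_rate + hom_rate > 0.1:
        raise ValueError("het_rate + hom_rate must be <= 0.1")
    rng = np.random.default_rng(seed)
    entries: list[GermlineVariant] = []
    total = het_rate + hom_rate
    if total == 0:
        return GermlineVariantSet(entries)
    for contig, arr in ref.contigs.items():
        positions = np.flatnonzero(rng.random(arr.size) < total)
        if positions.size == 0:
            continue
        is_het = rng.random(positions.size) < (het_rate / total)
        shifts = rng.integers(1, 4, size=positions.size)
        for pos, het, shift in zip(positions, is_het, shifts):
            ref_code = arr[pos]
            alt_code = BASE_CODES[(ASCII_TO_INDEX[ref_code] + shift) % 4]
            entries.append(
                GermlineVariant(
                    contig=contig,
                    pos=int(pos),
                    ref=chr(ref_code),
                    alt=chr(alt_code),
                    zygosity="het" if het else "hom",
                )
            )
    return GermlineVariantSet(entries)


# ---------------------------------------------------------------------------
# fragment families


@dataclass(slots=True)
class FragmentFamily:
    """One original double-stranded molecule and what was sequenced of it.

    ``variants`` are double-stranded (molecule-private somatic mutations
    plus the germline alleles this molecule carries): (pos, alt, kind).
    ``lesions`` are strand-private: (strand, pos, alt) with strand '+'/'-'.
    """

    molecule_id: int
    contig: str
    start: int
    end: int
    sequenced_strands: str  # 'both' | 'plus_only' | 'minus_only'
    variants: tuple[tuple[int, str, str], ...] = ()
    lesions: tuple[tuple[str, int, str], ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


def _per_position_somatic_rates(
    ref: ReferenceGenome, model: SomaticMutationModel
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Per-contig arrays driving context-aware mutation planting.

    For each interior position i with pyrimidine-collapsed context c and
    each of its 3 possible alternate bases a, the event rate is

        q_i(a) = target_frequency * G * signature[class(c, a)] / N(c)

    where G is the genome length and N(c) the genome-wide count of context
    c.  Summed over the genome this gives an expected ``target_frequency``
    mutations per base with a planted class distribution exactly equal to
    the signature.  Returns, per contig: cumulative total weight (for
    interval rates and inverse-CDF position sampling), per-position/per-alt
    weights, the alt base codes, and the per-position total weight.
    """
    sig = model.signature
    per_contig: dict[str, tuple] = {}
    context_counts = np.zeros(32, dtype=np.int64)
    raw: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    for contig, arr in ref.contigs.items():
        codes = ASCII_TO_INDEX[arr].astype(np.int64)
        L = arr.size
        class96 = np.full((L, 3), -1, dtype=np.int64)
        alt_codes = np.zeros((L, 3), dtype=np.uint8)
        if L >= 3:
            c = codes[1:-1]
            left = codes[:-2]
            right = codes[2:]
            is_pyr = (c == 1) | (c == 3)
            # pyrimidine-strand central base: C -> 0, T -> 1
            sub_base = np.where(is_pyr, np.where(c == 1, 0, 1), np.where(c == 2, 0, 1))
            pl = np.where(is_pyr, left, 3 - right)
            pr = np.where(is_pyr, right, 3 - left)
            ctx32 = sub_base * 16 + pl * 4 + pr
            np.add.at(context_counts, ctx32, 1)
            # class6 of (pyrimidine base, pyrimidine-strand alt):
            #   C: A->C>A(0) C is ref, G->C>G(1), T->C>T(2)
            #   T: A->T>A(3), C->T>C(4), G->T>G(5)
            pyr_alt_class = {
                0: {0: 0, 2: 1, 3: 2},  # central C
                1: {0: 3, 1: 4, 2: 5},  # central T
            }
            for j in range(3):
                alt_ref_strand = (c + 1 + j) % 4  # the 3 non-ref bases
                alt_codes[1:-1, j] = BASE_CODES[alt_ref_strand]
                alt_pyr = np.where(is_pyr, alt_ref_strand, 3 - alt_ref_strand)
                cls6 = np.empty(L - 2, dtype=np.int64)
                for sb, mapping in pyr_alt_class.items():
                    for a_idx, cl in mapping.items():
                        sel = (sub_base == sb) & (alt_pyr == a_idx)
                        cls6[sel] = cl
                class96[1:-1, j] = cls6 * 16 + pl * 4 + pr
            ctx_full = np.full(L, -1, dtype=np.int64)
            ctx_full[1:-1] = ctx32
        else:
            ctx_full = np.full(L, -1, dtype=np.int64)
        raw[contig] = (class96, alt_codes, ctx_full)

    scale = model.target_frequency * ref.total_length
    for contig, (class96, alt_codes, ctx_full) in raw.items():
        L = class96.shape[0]
        w = np.zeros((L, 3), dtype=np.float64)
        interior = ctx_full >= 0
        counts = np.where(context_counts > 0, context_counts, 1)
        for j in range(3):
            valid = interior & (class96[:, j] >= 0)
            w[valid, j] = (
                scale
                * sig[class96[valid, j]]
                / counts[ctx_full[valid]]
            )
        total = w.sum(axis=1)
        per_contig[contig] = (np.concatenate(([0.0], np.cumsum(total))), w, alt_codes, total)
    return per_contig


def simulate_fragments(
    ref: ReferenceGenome,
    germline: GermlineVariantSet | None,
    model: SomaticMutationModel | None,
    n_molecules: int,
    duplex_yield: float = 1.0,
    coincident_rate: float = 0.0,
    lesion_rate: float = 0.0,
    fragment_length_mean: int = 150,
    fragment_length_sd: float = 0.0,
    seed: int = 0,
) -> list[FragmentFamily]:
    """Draw molecules, assign variants/lesions, decide sequenced strands.

    Fragment intervals are uniform over each contig (contigs weighted by
    the number of valid start positions).  With probability
    ``coincident_rate`` an *additional independent* molecule with the same
    interval is appended — the confounder for coordinate-based grouping —
    and is off by default, matching the PCR-free assumption that
    coincidence implies a shared molecule.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    for name, val in (
        ("duplex_yield", duplex_yield),
        ("coincident_rate", coincident_rate),
        ("lesion_rate", lesion_rate),
    ):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    rng = np.random.default_rng(seed)
    contigs = list(ref.contigs)
    clens = np.array([ref.contigs[c].size for c in contigs], dtype=np.int64)

    if fragment_length_sd > 0:
        lengths = np.rint(
            rng.normal(fragment_length_mean, fragment_length_sd, n_molecules)
        ).astype(np.int64)
        lengths = np.clip(lengths, 20, clens.min())
    else:
        if fragment_length_mean > clens.min():
            raise ValueError("fragment_length_mean exceeds shortest contig")
        lengths = np.full(n_molecules, fragment_length_mean, dtype=np.int64)

    n_starts = clens - lengths.max() + 1
    contig_idx = rng.choice(len(contigs), size=n_molecules, p=n_starts / n_starts.sum())
    starts = (rng.random(n_molecules) * (clens[contig_idx] - lengths + 1)).astype(np.int64)

    # coincident independent molecules share the exact interval
    extra = np.flatnonzero(rng.random(n_molecules) < coincident_rate)
    if extra.size:
        contig_idx = np.concatenate([contig_idx, contig_idx[extra]])
        starts = np.concatenate([starts, starts[extra]])
        lengths = np.concatenate([lengths, lengths[extra]])
    n_total = starts.size
    ends = starts + lengths

    u = rng.random(n_total)
    single_plus = rng.random(n_total) < 0.5
    strands = np.where(
        u < duplex_yield, "both", np.where(single_plus, "plus_only", "minus_only")
    )

    variants: dict[int, list[tuple[int, str, str]]] = defaultdict(list)
    lesions: dict[int, list[tuple[str, int, str]]] = defaultdict(list)

    # --- somatic mutations, context-weighted
    if model is not None and model.target_frequency > 0:
        rates = _per_position_somatic_rates(ref, model)
        cum = {c: rates[c][0] for c in rates}
        lam = np.empty(n_total)
        for m in range(n_total):
            cq = cum[contigs[contig_idx[m]]]
            lam[m] = cq[ends[m]] - cq[starts[m]]
        counts = rng.poisson(lam)
        for m in np.flatnonzero(counts):
            contig = contigs[contig_idx[m]]
            cq, w, alt_codes, _ = rates[contig]
            lo, hi = cq[starts[m]], cq[ends[m]]
            for _ in range(counts[m]):
                pos = int(np.searchsorted(cq, lo + rng.random() * (hi - lo), side="right") - 1)
                pw = w[pos]
                j = int(rng.choice(3, p=pw / pw.sum()))
                variants[m].append((pos, chr(alt_codes[pos, j]), "somatic"))

    # --- germline alleles carried by covering molecules
    if germline is not None and len(germline):
        by_contig = germline.by_contig()
        for ci, contig in enumerate(contigs):
            sites = by_contig.get(contig)
            if not sites:
                continue
            sel = np.flatnonzero(contig_idx == ci)
            if sel.size == 0:
                continue
            order = sel[np.argsort(starts[sel], kind="stable")]
            s_sorted = starts[order]
            max_len = int(lengths[order].max())
            for v in sites:
                lo = np.searchsorted(s_sorted, v.pos - max_len + 1, side="left")
                hi = np.searchsorted(s_sorted, v.pos, side="right")
                for m in order[lo:hi]:
                    if v.pos < ends[m]:
                        if v.zygosity == "hom" or rng.random() < 0.5:
                            variants[m].append((v.pos, v.alt, f"germline_{v.zygosity}"))

    # --- single-strand lesions
    if lesion_rate > 0:
        n_lesions = rng.poisson(lesion_rate * 2 * lengths.sum())
        if n_lesions:
            mol = rng.choice(n_total, size=n_lesions, p=lengths / lengths.sum())
            offs = (rng.random(n_lesions) * lengths[mol]).astype(np.int64)
            strand_plus = rng.random(n_lesions) < 0.5
            shifts = rng.integers(1, 4, size=n_lesions)
            for m, off, on_plus, shift in zip(mol, offs, strand_plus, shifts):
                pos = int(starts[m] + off)
                ref_code = ref.contigs[contigs[contig_idx[m]]][pos]
                alt = chr(BASE_CODES[(ASCII_TO_INDEX[ref_code] + shift) % 4])
                lesions[m].append(("+" if on_plus else "-", pos, alt))

    families = [
        FragmentFamily(
            molecule_id=m,
            contig=contigs[contig_idx[m]],
            start=int(starts[m]),
            end=int(ends[m]),
            sequenced_strands=str(strands[m]),
            variants=tuple(sorted(variants.get(m, ()))),
            lesions=tuple(sorted(lesions.get(m, ()))),
        )
        for m in range(n_total)
    ]
    logger.info(
        "simulate_fragments: %d molecules (%d coincident extras), "
        "%d somatic/germline variant assignments, %d lesions",
        n_total, extra.size,
        sum(len(v) for v in variants.values()),
        sum(len(v) for v in lesions.values()),
    )
    return families


# ---------------------------------------------------------------------------
# truth accounting


@dataclass
class TruthSet:
    """Planted events with coordinates and contexts, one row per
    (molecule, event); germline rows are per carrying molecule."""

    records: list[dict] = field(default_factory=list)

    def unique_sites(self, kinds: set[str] | None = None) -> set[tuple[str, int, str]]:
        return {
            (r["contig"], r["pos"], r["alt"])
            for r in self.records
            if kinds is None or r["kind"] in kinds
        }

    def count(self, kind: str) -> int:
        return sum(r["kind"] == kind for r in self.records)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.records,
            columns=["sample", "contig", "pos", "ref", "alt", "kind", "context", "molecule_id"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def truth_from_families(
    families: list[FragmentFamily], ref: ReferenceGenome, sample: str = "sample"
) -> TruthSet:
    records = []
    for fam in families:
        for pos, alt, kind in fam.variants:
            records.append(
                {
                    "sample": sample,
                    "contig": fam.contig,
                    "pos": pos,
                    "ref": ref.base(fam.contig, pos),
                    "alt": alt,
                    "kind": kind,
                    "context": ref.trinucleotide(fam.contig, pos),
                    "molecule_id": fam.molecule_id,
                }
            )
        for strand, pos, alt in fam.lesions:
            records.append(
                {
                    "sample": sample,
                    "contig": fam.contig,
                    "pos": pos,
                    "ref": ref.base(fam.contig, pos),
                    "alt": alt,
                    "kind": "lesion",
                    "context": ref.trinucleotide(fam.contig, pos),
                    "molecule_id": fam.molecule_id,
                }
            )
    return TruthSet(records)


# ---------------------------------------------------------------------------
# sequencing


def sequence_fragments(
    families: list[FragmentFamily],
    ref: ReferenceGenome,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    sample: str = "sample",
) -> tuple[list[AlignedRead], TruthSet]:
    """Turn fragment families into truth-aligned read records.

    Each sequenced strand yields one read pair.  When ``read_length`` is at
    least the fragment length (the default full-overlap regime of ~150 bp
    inserts on 2x150 chemistry) both mates cover every fragment base;
    shorter reads cover the two fragment ends.  Substitution errors are
    i.i.d. per read position at ``error_rate`` with a uniform choice among
    the three alternatives.  Read names encode molecule and strand, e.g.
    ``m17p`` / ``m17n``.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    if read_length < 1:
        raise ValueError("read_length must be positive")
    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    for fam in families:
        L = fam.length
        frag = ref.slice(fam.contig, fam.start, fam.end).copy()
        for pos, alt, _kind in fam.variants:
            frag[pos - fam.start] = ord(alt)
        if fam.sequenced_strands == "both":
            strand_list = ("+", "-")
        elif fam.sequenced_strands == "plus_only":
            strand_list = ("+",)
        else:
            strand_list = ("-",)
        for strand in strand_list:
            sfrag = frag
            strand_lesions = [l for l in fam.lesions if l[0] == strand]
            if strand_lesions:
                sfrag = frag.copy()
                for _s, pos, alt in strand_lesions:
                    sfrag[pos - fam.start] = ord(alt)
            qname = f"m{fam.molecule_id}{'p' if strand == '+' else 'n'}"
            if read_length >= L:
                spans = ((0, L), (0, L))
            elif strand == "+":
                spans = ((0, read_length), (L - read_length, L))
            else:
                spans = ((L - read_length, L), (0, read_length))
            for mate_i, (a, b) in enumerate(spans):
                bases = sfrag[a:b].copy()
                if error_rate > 0:
                    hit = np.flatnonzero(rng.random(b - a) < error_rate)
                    if hit.size:
                        codes = ASCII_TO_INDEX[bases[hit]].astype(np.int64)
                        bases[hit] = BASE_CODES[
                            (codes + rng.integers(1, 4, size=hit.size)) % 4
                        ]
                is_read1 = mate_i == 0
                # FR orientation: on '+' inserts read 1 is forward,
                # on '-' inserts read 1 is reverse.
                is_reverse = (strand == "+") == (mate_i == 1)
                reads.append(
                    AlignedRead(
                        qname=qname,
                        contig=fam.contig,
                        start=fam.start + a,
                        bases=bases,
                        mapq=60,
                        is_read1=is_read1,
                        is_reverse=is_reverse,
                        mate_is_reverse=not is_reverse,
                        is_proper_pair=True,
                    )
                )
    return reads, truth_from_families(families, ref, sample=sample)


# ---------------------------------------------------------------------------
# serialisation


def write_sam(reads: list[AlignedRead], ref: ReferenceGenome, path: str | Path) -> None:
    """Write truth-aligned reads as SAM (proper-pair flags, MAPQ as given)."""
    names = list(ref.contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(ref.contigs[name].size)} for name in names],
    }
    tid = {name: i for i, name in enumerate(names)}
    mates: dict[str, list[AlignedRead]] = defaultdict(list)
    for read in reads:
        mates[read.qname].append(read)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            pair = mates[read.qname]
            other = next((m for m in pair if m is not read), read)
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.qname
            seg.reference_id = tid[read.contig]
            seg.reference_start = read.start
            seg.mapping_quality = read.mapq
            seg.cigarstring = f"{len(read.bases)}M"
            seg.query_sequence = array_to_seq(read.bases)
            seg.query_qualities = pysam.qualitystring_to_array(
                _DEFAULT_QUAL_CHAR * len(read.bases)
            )
            seg.flag = (
                0x1
                | 0x2
                | (0x10 if read.is_reverse else 0)
                | (0x20 if read.mate_is_reverse else 0)
                | (0x40 if read.is_read1 else 0x80)
            )
            seg.next_reference_id = tid[other.contig]
            seg.next_reference_start = other.start
            tlen = max(read.end, other.end) - min(read.start, other.start)
            seg.template_length = tlen if not read.is_reverse else -tlen
            out.write(seg)


def write_fastq(reads: list[AlignedRead], path_r1: str | Path, path_r2: str | Path) -> None:
    """Write read pairs as two FASTQ files in sequencing orientation
    (reverse-mapped reads are reverse-complemented back)."""
    with open(path_r1, "w") as r1, open(path_r2, "w") as r2:
        for read in reads:
            bases = read.bases
            if read.is_reverse:
                bases = ASCII_COMPLEMENT[bases[::-1]]
            out = r1 if read.is_read1 else r2
            mate = "1" if read.is_read1 else "2"
            out.write(
                f"@{read.qname}/{mate}\n{array_to_seq(bases)}\n+\n"
                f"{_DEFAULT_QUAL_CHAR * len(bases)}\n"
            )

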