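"""Trinucleotide (SBS96) substitution classification.

Single-base substitutions are reported on the pyrimidine strand: a mutation
whose reference base is a purine (A or G) is reverse-complemented, flanks
included, before classification.  This yields 6 substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G), each observed in 16 trinucleotide contexts,
for 96 categories in the conventional order used by signature tools
(classes in the order above; within a class, contexts sorted by 5' then 3'
flank, A < C < G < T).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 context keys, e.g. ``"A[C>A]A"``, in conventional SBS96 order.
SBS96_CONTEXTS = tuple(
    f"{left}[{sub}]{right}"
    for sub in SUB_TYPES
    for left in BASES
    for right in BASES
)

_SBS96_INDEX = {key: i for i, key in enumerate(SBS96_CONTEXTS)}

#: Substitution class in double-stranded (base-pair) notation, as used when
#: mutation spectra are reported per complementary base pair.
CLASS_TO_PAIR_NOTATION = {
    "C>A": "G:C>T:A",
    "C>G": "G:C>C:G",
    "C>T": "G:C>A:T",
    "T>A": "A:T>T:A",
    "T>C": "A:T>G:C",
    "T>G": "A:T>C:G",
}
PAIR_NOTATION_TO_CLASS = {v: k for k, v in CLASS_TO_PAIR_NOTATION.items()}


def complement(base: str) -> str:
    return _COMP[base]


def collapse_to_pyrimidine(
    ref: str, alt: str, left: str, right: str
) -> tuple[str, str, str]:
    """Collapse a stranded substitution onto the pyrimidine strand.

    Parameters are single reference-strand bases: the mutated base, its
    alternate, and the 5' and 3' flanking reference bases.  Returns
    ``(sub_class, left, right)`` where ``sub_class`` is one of the six
    pyrimidine-centric classes and the flanks are given on the same strand
    as the (possibly complemented) central base.
    """
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}")
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}", left, right
    return f"{_COMP[ref]}>{_COMP[alt]}", _COMP[right], _COMP[left]


def context_key(ref: str, alt: str, left: str, right: str) -> str:
    """96-category key, e.g. ``A>T`` in ``CAG`` -> ``"C[T>A]T"``."""
    sub, lft, rgt = collapse_to_pyrimidine(ref, alt, left, right)
    return f"{lft}[{sub}]{rgt}"


def sbs96_index(key: str) -> int:
    return _SBS96_INDEX[key]


def key_class(key: str) -> str:
    """Substitution class of a 96-category key (``"C[T>A]T"`` -> ``"T>A"``)."""
    return key[2:5]


def cosine_similarity(a, b) -> float:
    """Cosine similarity between two nonnegative spectra (0 if either is 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))
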