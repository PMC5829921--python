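"""Canonical trinucleotide-context definitions for substitution spectra.

All single-base substitutions are reported on the pyrimidine-containing
strand (COSMIC convention), giving six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G) and, with the 5' and 3' flanking bases,
96 context bins.  Trinucleotide *opportunities* (how often each context
occurs in the analyzed territory) live in 32 pyrimidine-centered bins.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 96 bin labels, class-major then 5' base then 3' base, "A[C>A]A" style.
CONTEXT_LABELS_96 = tuple(
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)
CONTEXT_INDEX_96 = {lab: i for i, lab in enumerate(CONTEXT_LABELS_96)}

#: 32 pyrimidine-centered trinucleotide labels ("ACA" ... "TTT").
TRINUC_LABELS_32 = tuple(
    f"{five}{center}{three}"
    for center in PYRIMIDINES
    for five in BASES
    for three in BASES
)
TRINUC_INDEX_32 = {lab: i for i, lab in enumerate(TRINUC_LABELS_32)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class AmbiguousBaseError(ValueError):
    """A base outside {A,C,G,T} was encountered where one is required."""


def canonical_substitution(
    ref_base: str, alt_base: str, context5: str, context3: str
) -> tuple[str, str]:
    """Map a substitution with flanks to its pyrimidine-strand (class, bin).

    Purine-reference substitutions are reflected onto the opposite strand,
    reverse-complementing the flanks, so that e.g. G>T with flanks A_A
    becomes C>A in a TCT context.

    Returns ``(class_label, context_label)`` such as ``("C>A", "T[C>A]T")``.
    Raises :class:`AmbiguousBaseError` for non-ACGT input and ``ValueError``
    when ref equals alt.
    """
    for b in (ref_base, alt_base, context5, context3):
        if b not in COMPLEMENT:
            raise AmbiguousBaseError(f"ambiguous or invalid base {b!r}")
    if ref_base == alt_base:
        raise ValueError(f"ref and alt are both {ref_base!r}")
    if ref_base in PYRIMIDINES:
        cls = f"{ref_base}>{alt_base}"
        label = f"{context5}[{cls}]{context3}"
    else:
        cls = f"{COMPLEMENT[ref_base]}>{COMPLEMENT[alt_base]}"
        label = f"{COMPLEMENT[context3]}[{cls}]{COMPLEMENT[context5]}"
    return cls, label


def class_of_bin(bin_index: int) -> int:
    """Index (0..5) of the substitution class a 96-bin belongs to."""
    return bin_index // 16


def trinuc_of_bin(bin_index: int) -> int:
    """Index (0..31) of the pyrimidine-centered trinucleotide of a 96-bin."""
    cls = bin_index // 16
    flanks = bin_index % 16
    center = 0 if cls < 3 else 1  # C for C>N classes, T for T>N
    return center * 16 + flanks


# --- fast trinucleotide census ------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

# 64 forward trinucleotide codes -> 32 canonical pyrimidine-centered bins
_TRINUC_CANON = np.empty(64, dtype=np.int64)
for _c5 in range(4):
    for _c in range(4):
        for _c3 in range(4):
            tri = BASES[_c5] + BASES[_c] + BASES[_c3]
            if tri[1] in PYRIMIDINES:
                canon = tri
            else:
                canon = revcomp(tri)
            _TRINUC_CANON[_c5 * 16 + _c * 4 + _c3] = TRINUC_INDEX_32[canon]


def trinucleotide_census(seq: str) -> np.ndarray:
    """Count pyrimidine-centered trinucleotide occurrences in a sequence.

    Every overlapping 3-mer of ``seq`` contributes to exactly one of the 32
    canonical bins (purine-centered 3-mers count toward their reverse
    complement).  Windows containing non-ACGT characters are skipped.

    Returns an int array of length 32 in :data:`TRINUC_LABELS_32` order.
    """
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < 3:
        return np.zeros(32, dtype=np.int64)
    c5, c, c3 = codes[:-2], codes[1:-1], codes[2:]
    valid = (c5 >= 0) & (c >= 0) & (c3 >= 0)
    tri = c5[valid] * 16 + c[valid] * 4 + c3[valid]
    return np.bincount(_TRINUC_CANON[tri], minlength=32)
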