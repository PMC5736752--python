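"""Single-base-substitution channel conventions.

Every somatic SNV is represented in its trinucleotide context with the
mutated base written as a pyrimidine (C or T): a substitution whose
reference base is a purine is reverse-complemented — both alleles and
both flanking bases, with the flanks swapped — before classification.
This yields 96 channels (6 substitution classes x 16 flank contexts),
or 192 when the coding/noncoding transcriptional strand is tracked.

Channel ordering is the COSMIC convention: substitution classes in the
order C>A, C>G, C>T, T>A, T>C, T>G; within a class the 16 contexts are
ordered by 5' flank then 3' flank over A, C, G, T.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CHANNELS_96 = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_CLASSES
    for f5 in BASES
    for f3 in BASES
)

#: Stranded channels: each pyrimidine channel split into the coding (+,
#: untranscribed) and noncoding (-, transcribed) strand of the gene.
CHANNELS_192 = tuple(f"{ch}|{s}" for ch in CHANNELS_96 for s in "+-")

#: The 32 pyrimidine-centered trinucleotides, ordered center C then T,
#: flanks over A, C, G, T. Used for territory context-frequency tables.
CONTEXTS_32 = tuple(
    f"{f5}{c}{f3}" for c in "CT" for f5 in BASES for f3 in BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}
_CONTEXT_INDEX = {ctx: i for i, ctx in enumerate(CONTEXTS_32)}


class InvalidBaseError(ValueError):
    """A base outside {A, C, G, T} where an unambiguous base is required."""


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise InvalidBaseError(f"not an unambiguous DNA base: {base!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence of unambiguous bases."""
    return "".join(complement(b) for b in reversed(seq))


def collapse_to_pyrimidine(ref: str, alt: str, flank5: str, flank3: str) -> tuple[int, str]:
    """Map one substitution with flanks to its 96-channel index and label.

    Purine-reference substitutions are reverse-complemented (alleles and
    flanks, flanks swapped) so the channel is always written with a C or
    T reference.

    Returns ``(index, label)`` with ``label`` like ``"A[C>A]A"``.
    """
    for b in (ref, alt, flank5, flank3):
        if b not in _COMPLEMENT:
            raise InvalidBaseError(f"not an unambiguous DNA base: {b!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if ref not in PYRIMIDINES:
        ref, alt = complement(ref), complement(alt)
        flank5, flank3 = complement(flank3), complement(flank5)
    label = f"{flank5}[{ref}>{alt}]{flank3}"
    return _CHANNEL_INDEX[label], label


def channel_index(label: str) -> int:
    """Index of a 96-channel label in the fixed ordering."""
    try:
        return _CHANNEL_INDEX[label]
    except KeyError:
        raise KeyError(f"unknown channel label: {label!r}") from None


def channel_context(label: str) -> str:
    """Pyrimidine-centered trinucleotide context of a 96-channel label.

    ``"A[C>A]G"`` -> ``"ACG"``.
    """
    return label[0] + label[2] + label[6]


def collapse_context(trinuc: str) -> str:
    """Pyrimidine-centered spelling of a trinucleotide window.

    A window with a purine center base is recorded under its reverse
    complement, matching the mutation-channel convention.
    """
    if len(trinuc) != 3:
        raise ValueError(f"need a trinucleotide, got {trinuc!r}")
    for b in trinuc:
        if b not in _COMPLEMENT:
            raise InvalidBaseError(f"not an unambiguous DNA base: {b!r}")
    return trinuc if trinuc[1] in PYRIMIDINES else revcomp(trinuc)


def context_index(trinuc: str) -> int:
    """Index of a trinucleotide window in the 32-context ordering."""
    return _CONTEXT_INDEX[collapse_context(trinuc)]


def stranded_label(channel96: str, strand: str) -> str:
    """192-channel label for a pyrimidine channel on a strand (+ or -)."""
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return f"{channel96}|{strand}"


def substitution_class(label: str) -> str:
    """Substitution class (e.g. ``"C>A"``) of a 96- or 192-channel label."""
    return label[2:5]
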