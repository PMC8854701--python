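"""Trinucleotide-context machinery shared by spectra, signatures and selection.

Single-base substitutions are reported in 96 classes: the six pyrimidine
substitutions (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16 combinations
of flanking 5' and 3' bases. Substitutions whose reference base is a purine
are reverse-complemented (flanks swapped and complemented) onto the
pyrimidine strand before classification.
"""

from __future__ import annotations

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")

#: The six pyrimidine-strand substitutions, in canonical order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical ordering of the 96 classes: substitution-major, then 5' flank,
#: then 3' flank, each in alphabetical base order. Labels look like "A[C>T]G".
SBS96_CLASSES = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

SBS96_INDEX = {label: i for i, label in enumerate(SBS96_CLASSES)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in {seq!r}") from exc


def sbs96_label(ref: str, alt: str, context: str) -> str:
    """Classify one SNV into its 96-class label.

    Parameters
    ----------
    ref, alt
        Reference and alternate bases on the reference strand.
    context
        3-mer centred on the mutated site, reference strand; its middle
        base must equal ``ref``.

    Raises
    ------
    ValueError
        For non-ACGT input, ref == alt, or a context inconsistent with ref.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if len(context) != 3 or any(b not in BASES for b in context):
        raise ValueError(f"invalid trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]} != ref {ref}")
    if ref not in PYRIMIDINES:
        ref, alt, context = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def sbs96_index(ref: str, alt: str, context: str) -> int:
    """Index of the SNV's class in :data:`SBS96_CLASSES`."""
    return SBS96_INDEX[sbs96_label(ref, alt, context)]


def class_components(label: str) -> tuple[str, str, str]:
    """Split a class label into (ref, alt, pyrimidine-strand context)."""
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    return ref, alt, five + ref + three
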