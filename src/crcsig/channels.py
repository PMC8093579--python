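"""The 96 pyrimidine-centric trinucleotide substitution channels.

Single-base substitutions are collapsed onto the pyrimidine strand and
classified by substitution type (C>A, C>G, C>T, T>A, T>C, T>G) and the
two flanking bases, giving 6 x 16 = 96 channels.  The fixed channel order
is the COSMIC v2 convention: the six substitution blocks in the order
above, contexts sorted alphabetically within each block (A_A ... T_T).
This ordering is what makes cosine comparison against a reference
signature table index-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: channel labels in fixed COSMIC v2 order, e.g. "A[C>A]A"
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}

N_CHANNELS = 96


class AmbiguousBaseError(ValueError):
    """Raised when a base outside {A,C,G,T} enters channel classification."""


@dataclass(frozen=True)
class TrinucleotideChannel:
    """One of the 96 substitution channels."""

    substitution: str
    five_prime: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @property
    def index(self) -> int:
        return CHANNEL_INDEX[self.label]


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise AmbiguousBaseError(f"non-ACGT base in {seq!r}") from exc


def classify_substitution(
    ref: str, alt: str, five_prime: str, three_prime: str
) -> TrinucleotideChannel:
    """Classify a single-base substitution into its trinucleotide channel.

    If the reference base is a purine (A/G) the substitution and its
    context are reverse-complemented so that the central base is a
    pyrimidine; classification is therefore strand-symmetric.

    Parameters
    ----------
    ref, alt : str
        Reference and alternate alleles, single bases, ``ref != alt``.
    five_prime, three_prime : str
        Bases immediately flanking the mutated site on the reference
        strand (the strand on which ``ref`` is reported).

    Raises
    ------
    AmbiguousBaseError
        If any base is outside {A, C, G, T}.
    ValueError
        If ``ref == alt``.
    """
    ref, alt = ref.upper(), alt.upper()
    five_prime, three_prime = five_prime.upper(), three_prime.upper()
    for b in (ref, alt, five_prime, three_prime):
        if b not in BASES:
            raise AmbiguousBaseError(f"ambiguous base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if ref in ("A", "G"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five_prime, three_prime = COMPLEMENT[three_prime], COMPLEMENT[five_prime]
    return TrinucleotideChannel(f"{ref}>{alt}", five_prime, three_prime)
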