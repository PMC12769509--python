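"""Motif equivalence classes for short tandem repeats.

A repeat motif of unit length 1-6 nt is identified up to cyclic permutation
and reverse complementation: outside of special contexts (coding frame,
transcription direction) these variants are bioinformatically and
biologically indistinguishable, so e.g. CAG, AGC, GCA, CTG, GCT and TGC all
denote the same repeat class.  Each class is labelled by its alphabetically
smallest member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number repetition of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def minimal_period(seq: str) -> int:
    """Smallest d such that seq is a repetition of its first d characters."""
    n = len(seq)
    for d in range(1, n + 1):
        if n % d == 0 and seq == seq[:d] * (n // d):
            return d
    return n


class InvalidAlphabetError(ValueError):
    """Motif or sequence contains characters outside A/C/G/T."""


class DegenerateMotifError(ValueError):
    """Motif is a repetition of a shorter motif (e.g. 'AA', 'CACA')."""


@dataclass(frozen=True)
class MotifClass:
    """Equivalence class of a repeat motif.

    Attributes
    ----------
    label : canonical (alphabetically smallest) member.
    unit_length : motif length in nt (1-6).
    members : all cyclic permutations of the label and of its reverse
        complement.  For self-complementary unit sets the two orbits merge
        (e.g. class "A" has members {"A", "T"}; class "AT" has {"AT", "TA"}).
    """

    label: str
    unit_length: int
    members: frozenset = field(compare=False)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def _cyclic(seq: str) -> set:
    return {seq[i:] + seq[:i] for i in range(len(seq))}


def canonical_label(motif: str) -> MotifClass:
    """Return the motif class containing ``motif``.

    Raises
    ------
    InvalidAlphabetError
        for characters outside {A, C, G, T} or empty/overlong motifs.
    DegenerateMotifError
        for non-primitive motifs, which belong to the class of their
        primitive root (e.g. "CACA" is the AC class at unit length 2).
    """
    if not motif or len(motif) > 6 or not set(motif) <= _ALPHABET:
        raise InvalidAlphabetError(
            f"motif must be a 1-6 nt string over A/C/G/T, got {motif!r}"
        )
    if not is_primitive(motif):
        raise DegenerateMotifError(f"motif {motif!r} repeats a shorter unit")
    members = _cyclic(motif) | _cyclic(reverse_complement(motif))
    return MotifClass(
        label=min(members), unit_length=len(motif), members=frozenset(members)
    )


def all_classes(unit_length: int) -> list:
    """All distinct motif classes of a given unit length, sorted by label."""
    seen: dict = {}
    from itertools import product

    for tup in product("ACGT", repeat=unit_length):
        motif = "".join(tup)
        if not is_primitive(motif):
            continue
        cls = canonical_label(motif)
        seen[cls.label] = cls
    return [seen[k] for k in sorted(seen)]
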