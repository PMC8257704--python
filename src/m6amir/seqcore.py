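"""Nucleotide alphabet handling, reverse complementation and IUPAC motif scanning.

The internal alphabet is RNA: DNA input is accepted and T is mapped to U on
normalization, because both the m6A consensus motifs (RRACH, GGACH) and miRNA
seed sequences are conventionally written on the RNA strand.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

# IUPAC nucleotide codes on the RNA alphabet.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

CONCRETE_BASES = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
# Ambiguity codes complement to the code covering the complements of their set.
_AMBIG_COMPLEMENT = str.maketrans("RYSWKMBDHVN", "YRSWMKVHDBN")


class SequenceError(ValueError):
    """Raised for malformed sequences or motifs."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence normalized to the RNA alphabet.

    Parameters
    ----------
    id : str
        Sequence label.
    residues : str
        Upper-case residues over the IUPAC RNA alphabet (T already mapped to U).
    original_alphabet : str
        ``"RNA"`` or ``"DNA"`` — the alphabet the input was declared in.
    """

    id: str
    residues: str
    original_alphabet: str = "RNA"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r}: empty sequences are rejected")
        for pos, ch in enumerate(self.residues):
            if ch not in IUPAC_EXPANSION:
                raise SequenceError(
                    f"sequence {self.id!r}: illegal character {ch!r} at position {pos}"
                )
        if self.original_alphabet not in ("RNA", "DNA"):
            raise SequenceError(
                f"sequence {self.id!r}: alphabet must be 'RNA' or 'DNA', "
                f"got {self.original_alphabet!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def normalize_sequence(
    raw: str, declared_alphabet: str = "RNA", seq_id: str = ""
) -> NucleotideSequence:
    """Normalize a raw sequence string: upper-case, T→U, validate IUPAC letters.

    Raises :class:`SequenceError` naming the first illegal character and its
    0-based position.
    """
    if not raw:
        raise SequenceError(f"sequence {seq_id!r}: empty sequences are rejected")
    folded = raw.upper().replace("T", "U")
    for pos, ch in enumerate(folded):
        if ch not in IUPAC_EXPANSION:
            raise SequenceError(
                f"sequence {seq_id!r}: illegal character {raw[pos]!r} at position {pos}"
            )
    return NucleotideSequence(id=seq_id, residues=folded, original_alphabet=declared_alphabet)


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson–Crick RNA reverse complement (A↔U, G↔C), an involution.

    Ambiguity codes complement to the code for the complementary set
    (R↔Y, etc.); N maps to N.
    """
    rc = seq.residues.translate(_COMPLEMENT).translate(_AMBIG_COMPLEMENT)[::-1]
    return NucleotideSequence(
        id=f"{seq.id}_rc" if seq.id else "", residues=rc, original_alphabet=seq.original_alphabet
    )


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC-degenerate motif such as RRACH or GGACH.

    R expands to {A,G}; H to {A,C,U}; the methylated adenosine of the m6A
    consensus is the invariant A at position 3 of both built-ins.
    """

    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise SequenceError("motif pattern must be non-empty")
        pat = self.pattern.upper().replace("T", "U")
        for pos, ch in enumerate(pat):
            if ch not in IUPAC_EXPANSION:
                raise SequenceError(
                    f"motif {self.pattern!r}: invalid IUPAC code {ch!r} at position {pos}"
                )
        object.__setattr__(self, "pattern", pat)
        if not self.name:
            object.__setattr__(self, "name", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    def expansion(self) -> list[frozenset[str]]:
        """Per-position sets of concrete bases the motif admits."""
        return [IUPAC_EXPANSION[ch] for ch in self.pattern]

    def matches(self, window: str, n_matches_all: bool = False) -> bool:
        """Whether a concrete window of equal length satisfies the motif.

        Ambiguity codes in the *window* match nothing by default (conservative);
        with ``n_matches_all`` an N in the window matches any motif position.
        """
        if len(window) != len(self.pattern):
            return False
        for ch, allowed in zip(window, self.expansion()):
            if ch in allowed:
                continue
            if n_matches_all and ch == "N":
                continue
            return False
        return True


# The two built-in m6A consensus motifs. Every GGACH match is an RRACH match.
RRACH = DegenerateMotif("RRACH")
GGACH = DegenerateMotif("GGACH")


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence: 0-based half-open window on a named sequence."""

    sequence_id: str
    start: int
    end: int
    matched_text: str

    def overlaps(self, start: int, end: int) -> bool:
        """Half-open interval intersection test."""
        return self.start < end and start < self.end


def _motif_regex(motif: DegenerateMotif, n_matches_all: bool) -> re.Pattern[str]:
    parts = []
    for ch in motif.pattern:
        allowed = sorted(IUPAC_EXPANSION[ch])
        if n_matches_all:
            allowed = sorted(set(allowed) | {"N"})
        parts.append("[" + "".join(allowed) + "]")
    # Lookahead so overlapping hits are all reported.
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(
    seq: NucleotideSequence, motif: DegenerateMotif, n_matches_all: bool = False
) -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences, sorted by start.

    A motif longer than the sequence yields an empty list. Ambiguity codes in
    the sequence match nothing unless ``n_matches_all`` is set, in which case
    an N matches every motif position.
    """
    k = len(motif)
    if k > len(seq):
        return []
    rx = _motif_regex(motif, n_matches_all)
    return [
        MotifHit(seq.id, m.start(), m.start() + k, m.group(1))
        for m in rx.finditer(seq.residues)
    ]


def iter_windows(seq: NucleotideSequence, k: int) -> Iterator[tuple[int, str]]:
    """All length-k windows of a sequence with their start offsets."""
    for i in range(len(seq) - k + 1):
        yield i, seq.residues[i : i + k]
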