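"""Screen a miRNA catalogue for seeds inversely complementary to m6A motifs.

For each mature miRNA the seed region (positions 2–8 by default, 1-based
inclusive on the mature strand) is extracted, reverse-complemented to give the
mRNA-strand target-site sequence, and that 7-mer is scanned for the stringent
(GGACH) and relaxed (RRACH) m6A consensus motifs. A 5-nt motif can occur at
three offsets inside a 7-nt site; containment at any offset counts.

Match classes: FULL = stringent motif present; PARTIAL = relaxed motif only;
NONE = neither. Because every GGACH match is an RRACH match, FULL implies the
relaxed condition also holds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seqcore import (
    GGACH,
    RRACH,
    DegenerateMotif,
    MotifHit,
    NucleotideSequence,
    SequenceError,
    reverse_complement,
    scan_motif,
)

MATCH_NONE = "NONE"
MATCH_PARTIAL = "PARTIAL"
MATCH_FULL = "FULL"

DEFAULT_SEED_SPAN = (2, 8)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence (5'→3') with a defined seed region.

    ``seed_span`` is 1-based inclusive on the mature strand; the default
    (2, 8) is the canonical 7-mer seed. Position 1 is excluded from seed
    pairing by convention, so the span must start at 2 or later.
    """

    name: str
    sequence: NucleotideSequence
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN

    def __post_init__(self) -> None:
        start, end = self.seed_span
        if start < 2:
            raise SequenceError(
                f"miRNA {self.name!r}: seed span must start at position >= 2, got {start}"
            )
        if end < start:
            raise SequenceError(f"miRNA {self.name!r}: invalid seed span {self.seed_span}")
        if len(self.sequence) < end:
            raise SequenceError(
                f"miRNA {self.name!r}: mature sequence ({len(self.sequence)} nt) "
                f"shorter than seed span end {end}"
            )


@dataclass(frozen=True)
class SeedScreenResult:
    """Outcome of screening one miRNA seed against the two motif tiers."""

    mirna_name: str
    seed: str
    site_sequence: str  # reverse complement of the seed, mRNA strand 5'->3'
    motif_name: str
    hits: tuple[MotifHit, ...]
    match_class: str


def extract_seed(mirna: MatureMiRNA) -> NucleotideSequence:
    """The seed subsequence at 1-based inclusive ``seed_span`` of the mature strand."""
    start, end = mirna.seed_span
    return NucleotideSequence(
        id=f"{mirna.name}_seed",
        residues=mirna.sequence.residues[start - 1 : end],
        original_alphabet=mirna.sequence.original_alphabet,
    )


def screen_mirna(
    mirna: MatureMiRNA,
    relaxed: DegenerateMotif = RRACH,
    stringent: DegenerateMotif = GGACH,
) -> SeedScreenResult:
    """Classify one miRNA by motif containment in its seed's reverse complement."""
    seed = extract_seed(mirna)
    site = NucleotideSequence(id=mirna.name, residues=reverse_complement(seed).residues)
    stringent_hits = scan_motif(site, stringent)
    relaxed_hits = scan_motif(site, relaxed)
    if stringent_hits:
        match_class, motif_name, hits = MATCH_FULL, stringent.name, stringent_hits
    elif relaxed_hits:
        match_class, motif_name, hits = MATCH_PARTIAL, relaxed.name, relaxed_hits
    else:
        match_class, motif_name, hits = MATCH_NONE, "", []
    return SeedScreenResult(
        mirna_name=mirna.name,
        seed=seed.residues,
        site_sequence=site.residues,
        motif_name=motif_name,
        hits=tuple(hits),
        match_class=match_class,
    )


def screen_catalogue(
    mirnas: list[MatureMiRNA],
    relaxed: DegenerateMotif = RRACH,
    stringent: DegenerateMotif = GGACH,
) -> list[SeedScreenResult]:
    """Screen a catalogue; one result per miRNA, in input order.

    Duplicate miRNA names are rejected (reporting would be ambiguous).
    """
    if not mirnas:
        raise SequenceError("miRNA catalogue is empty")
    names = Counter(m.name for m in mirnas)
    dupes = sorted(n for n, c in names.items() if c > 1)
    if dupes:
        raise SequenceError(f"duplicate miRNA names in catalogue: {', '.join(dupes)}")
    return [screen_mirna(m, relaxed=relaxed, stringent=stringent) for m in mirnas]


def summarize_screen(results: list[SeedScreenResult]) -> dict[str, int]:
    """Counts per match class, e.g. the 1-FULL / 9-PARTIAL / 129-NONE style summary."""
    counts = Counter(r.match_class for r in results)
    return {
        "n_total": len(results),
        "n_full": counts.get(MATCH_FULL, 0),
        "n_partial": counts.get(MATCH_PARTIAL, 0),
        "n_none": counts.get(MATCH_NONE, 0),
        "n_relaxed_or_better": counts.get(MATCH_FULL, 0) + counts.get(MATCH_PARTIAL, 0),
    }
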