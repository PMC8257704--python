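"""Locate canonical seed-match target sites in 3'UTRs and classify genes by m6A status.

Site taxonomy follows the canonical scheme:

* 6mer    — UTR matches the reverse complement of miRNA seed positions 2–7;
* 7mer-m8 — positions 2–8;
* 7mer-A1 — positions 2–7 plus an adenosine in the UTR opposite miRNA position 1;
* 8mer    — positions 2–8 plus that adenosine.

The miRNA pairs antiparallel to the UTR, so the position opposite miRNA
position 1 is the UTR base immediately 3' of the seed-paired region. Reported
site intervals cover the seed-paired region only (0-based half-open): 6 nt for
6mer/7mer-A1, 7 nt for 7mer-m8/8mer; the A1 adenosine sits at offset ``end``.

A gene is an m6A-modified target when it is a target AND is in the supplied
m6A gene set AND carries a GGACH motif in its UTR; the stricter rule
additionally requires a motif hit overlapping a target-site interval.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .mirna_screen import MatureMiRNA
from .seqcore import (
    GGACH,
    DegenerateMotif,
    MotifHit,
    NucleotideSequence,
    SequenceError,
    reverse_complement,
    scan_motif,
)

logger = logging.getLogger(__name__)

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}


@dataclass(frozen=True)
class UTRRecord:
    """A gene's 3'UTR sequence, 5'→3'."""

    gene_id: str
    sequence: NucleotideSequence


@dataclass(frozen=True)
class TargetSite:
    """A seed-match locus in a UTR, typed by pairing extent."""

    gene_id: str
    mirna_name: str
    start: int
    end: int
    site_type: str

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene target and m6A status flags plus the combined call."""

    gene_id: str
    is_target: bool
    m6a_in_gene_set: bool
    ggach_in_utr: bool
    motif_overlaps_site: bool
    m6a_modified_target: bool


def find_target_sites(
    utr: UTRRecord,
    mirna: MatureMiRNA,
    min_site_type: str = "7mer-m8",
) -> list[TargetSite]:
    """All seed-match loci of at least ``min_site_type``, sorted by start.

    Each locus is labeled with its strongest type; overlapping type calls at
    one core-match locus are merged (an 8mer is not additionally reported as
    a 7mer). Seed positions are the canonical 2–8 (core 2–7, m8 = position 8),
    independent of the miRNA's configurable screening seed span.
    """
    if min_site_type not in SITE_RANK:
        raise SequenceError(f"unknown site type {min_site_type!r}; expected one of {SITE_TYPES}")
    mat = mirna.sequence.residues
    if len(mat) < 8:
        raise SequenceError(f"miRNA {mirna.name!r}: mature sequence shorter than 8 nt")
    core = reverse_complement(NucleotideSequence(id="", residues=mat[1:7])).residues  # pos 2-7
    m8_complement = reverse_complement(NucleotideSequence(id="", residues=mat[7])).residues
    u = utr.sequence.residues
    sites: list[TargetSite] = []
    min_rank = SITE_RANK[min_site_type]
    for s in range(len(u) - 6 + 1):
        if u[s : s + 6] != core:
            continue
        has_m8 = s >= 1 and u[s - 1] == m8_complement
        has_a1 = s + 6 < len(u) and u[s + 6] == "A"
        if has_m8 and has_a1:
            stype, start, end = "8mer", s - 1, s + 6
        elif has_m8:
            stype, start, end = "7mer-m8", s - 1, s + 6
        elif has_a1:
            stype, start, end = "7mer-A1", s, s + 6
        else:
            stype, start, end = "6mer", s, s + 6
        if SITE_RANK[stype] >= min_rank:
            sites.append(TargetSite(utr.gene_id, mirna.name, start, end, stype))
    return sorted(sites, key=lambda t: (t.start, t.end))


def annotate_genes(
    utrs: list[UTRRecord],
    mirna: MatureMiRNA,
    m6a_gene_set: set[str],
    motif: DegenerateMotif = GGACH,
    strict_site_overlap: bool = False,
    min_site_type: str = "7mer-m8",
) -> list[GeneAnnotation]:
    """One annotation per UTR, combining target sites, gene-set membership and motif presence.

    ``m6a_modified_target`` is is_target AND m6a_in_gene_set AND ggach_in_utr;
    with ``strict_site_overlap`` a motif hit must additionally intersect a
    target-site interval (half-open intersection). Gene-set members absent
    from the UTR list are logged, not an error.
    """
    ids = Counter(u.gene_id for u in utrs)
    dupes = sorted(g for g, c in ids.items() if c > 1)
    if dupes:
        raise SequenceError(f"duplicate gene_id in UTR list: {', '.join(dupes)}")
    missing = m6a_gene_set - set(ids)
    if missing:
        logger.info("%d m6A gene-set members have no supplied UTR", len(missing))

    annotations: list[GeneAnnotation] = []
    for utr in utrs:
        sites = find_target_sites(utr, mirna, min_site_type=min_site_type)
        hits = scan_motif(utr.sequence, motif)
        is_target = bool(sites)
        in_set = utr.gene_id in m6a_gene_set
        has_motif = bool(hits)
        overlaps = any(h.overlaps(s.start, s.end) for h in hits for s in sites)
        modified = is_target and in_set and has_motif
        if strict_site_overlap:
            modified = modified and overlaps
        annotations.append(
            GeneAnnotation(
                gene_id=utr.gene_id,
                is_target=is_target,
                m6a_in_gene_set=in_set,
                ggach_in_utr=has_motif,
                motif_overlaps_site=overlaps,
                m6a_modified_target=modified,
            )
        )
    return annotations


def sites_for_genes(
    utrs: list[UTRRecord], mirna: MatureMiRNA, min_site_type: str = "7mer-m8"
) -> list[TargetSite]:
    """Target sites across a UTR collection, grouped by input gene order."""
    out: list[TargetSite] = []
    for utr in utrs:
        out.extend(find_target_sites(utr, mirna, min_site_type=min_site_type))
    return out
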