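"""Readers and writers for the pipeline's plain-text formats.

Tabular files are TSV with a header row; '#' lines are comments. Intervals
use BED (0-based half-open, chrom column = gene id, UTR-relative). FASTA goes
through Biopython, wrapped at 60 columns on write.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mirna_screen import MatureMiRNA, SeedScreenResult
from .seqcore import NucleotideSequence, SequenceError, normalize_sequence
from .stage_dynamics import RegulationCall, StageMatrix
from .target_annotation import GeneAnnotation, TargetSite, UTRRecord


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path, alphabet: str = "RNA") -> list[NucleotideSequence]:
    """Order-preserving FASTA reader; ids parsed to the first whitespace.

    Duplicate ids are rejected; a file whose first non-blank line is not a
    header is rejected with its line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}:{lineno}: expected a '>' header before sequence data"
                )
            break
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: set[str] = set()
    out: list[NucleotideSequence] = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append(normalize_sequence(str(rec.seq), declared_alphabet=alphabet, seq_id=rec.id))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, residues) pairs as FASTA, wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(residues), id=name, description="") for name, residues in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_mirnas(path: str | Path, seed_span: tuple[int, int] = (2, 8)) -> list[MatureMiRNA]:
    """miRNA catalogue from FASTA (headers = names) or 2-column TSV (name, sequence)."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        seqs = read_fasta(path)
        return [MatureMiRNA(name=s.id, sequence=s, seed_span=seed_span) for s in seqs]
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: miRNA TSV needs 2 columns (name, sequence)")
    out = []
    for _, row in frame.iterrows():
        name, residues = str(row.iloc[0]), str(row.iloc[1])
        out.append(
            MatureMiRNA(
                name=name,
                sequence=normalize_sequence(residues, seq_id=name),
                seed_span=seed_span,
            )
        )
    return out


def read_utrs(path: str | Path) -> list[UTRRecord]:
    return [UTRRecord(gene_id=s.id, sequence=s) for s in read_fasta(path)]


# ---------------------------------------------------------------- TSV

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_gene_set(path: str | Path) -> set[str]:
    """One gene id per line; a 'gene_id' header line is tolerated."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if not token or token.startswith("#") or token == "gene_id":
                continue
            genes.add(token)
    return genes


def write_gene_set(path: str | Path, genes: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\n")
        for g in genes:
            fh.write(f"{g}\n")


def read_scores(path: str | Path) -> dict[str, float]:
    """Score TSV: columns gene_id, score."""
    frame = _read_tsv(path)
    if not {"gene_id", "score"} <= set(frame.columns):
        raise FormatError(f"{path}: score TSV needs 'gene_id' and 'score' columns")
    return {str(g): float(s) for g, s in zip(frame["gene_id"], frame["score"])}


def write_scores(path: str | Path, scores: dict[str, float]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tscore\n")
        for g in sorted(scores):
            fh.write(f"{g}\t{scores[g]:.6f}\n")


def read_matrix(path: str | Path, reference_stage: str) -> StageMatrix:
    """Stage matrix TSV: first column gene_id, remaining columns = stage labels."""
    frame = _read_tsv(path, index_col=0)
    return StageMatrix(values=frame, reference_stage=reference_stage)


def write_matrix(path: str | Path, matrix: StageMatrix) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------- BED

def read_bed(path: str | Path) -> list[tuple[str, int, int, list[str]]]:
    """BED intervals (chrom = gene id, 0-based half-open); extra columns kept opaque.

    Rejects malformed lines (fewer than 3 columns, non-integer bounds,
    start >= end or start < 0) with their line numbers.
    """
    out: list[tuple[str, int, int, list[str]]] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED bounds") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) (need 0 <= start < end)"
                )
            out.append((cols[0], start, end, cols[3:]))
    return out


def write_bed(path: str | Path, intervals: Iterable[tuple]) -> None:
    """Write (chrom, start, end[, extra...]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            extras = list(iv[3]) if len(iv) > 3 and isinstance(iv[3], (list, tuple)) else list(iv[3:])
            fields = [str(chrom), str(int(start)), str(int(end))] + [str(x) for x in extras]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------- stage outputs

def write_screen_results(path: str | Path, results: Sequence[SeedScreenResult]) -> None:
    """Screen TSV: mirna, seed, site_sequence, match_class, motif_hits."""
    with open(path, "w") as fh:
        fh.write("mirna\tseed\tsite_sequence\tmatch_class\tmotif_hits\n")
        for r in results:
            hits = ";".join(f"{h.start}:{h.matched_text}" for h in r.hits)
            fh.write(f"{r.mirna_name}\t{r.seed}\t{r.site_sequence}\t{r.match_class}\t{hits}\n")


def read_screen_results(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, keep_default_na=False)


def write_sites_bed(path: str | Path, sites: Sequence[TargetSite]) -> None:
    write_bed(
        path,
        [(s.gene_id, s.start, s.end, [f"{s.mirna_name}|{s.site_type}"]) for s in sites],
    )


def write_annotations(path: str | Path, annotations: Sequence[GeneAnnotation]) -> None:
    """Annotation TSV, boolean columns rendered 0/1."""
    cols = (
        "is_target",
        "m6a_in_gene_set",
        "ggach_in_utr",
        "motif_overlaps_site",
        "m6a_modified_target",
    )
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(cols) + "\n")
        for a in annotations:
            fh.write(a.gene_id + "\t" + "\t".join(str(int(getattr(a, c))) for c in cols) + "\n")


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    frame = _read_tsv(path)
    out = []
    for _, row in frame.iterrows():
        out.append(
            GeneAnnotation(
                gene_id=str(row["gene_id"]),
                is_target=bool(int(row["is_target"])),
                m6a_in_gene_set=bool(int(row["m6a_in_gene_set"])),
                ggach_in_utr=bool(int(row["ggach_in_utr"])),
                motif_overlaps_site=bool(int(row["motif_overlaps_site"])),
                m6a_modified_target=bool(int(row["m6a_modified_target"])),
            )
        )
    return out


def write_calls(path: str | Path, calls: Sequence[RegulationCall]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2_ratio\tcall\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.log2_ratio:.6f}\t{c.call}\n")
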