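"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design end to end: a catalogue of mature
miRNAs in which a chosen number of seeds are inversely complementary to the
stringent (GGACH) or only the relaxed (RRACH) m6A consensus; a 3'UTR genome
with planted seed-match sites and planted m6A status (gene-set membership and
GGACH motifs); AGO2 pull-down style enrichment scores with a group shift for
m6A-modified targets; and a stage matrix with Bernoulli-planted down/up
regulation at stratum-specific rates.

Background sequences are rejection-sampled so that no accidental seed site or
motif hit contradicts the planted truth — the discrete layers of the pipeline
must recover the truth table exactly, with no sampling slack. All randomness
flows through one ``numpy.random.default_rng`` (PCG64) seeded from the config,
so outputs are byte-identical across runs for a given seed.

A planted seed site can itself contain the m6A motif (the miR-133a situation:
the site sequence GGACCAA carries GGACC); the truth table accounts for this —
every target of such a miRNA has the motif in its UTR by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mirna_screen import MATCH_FULL, MATCH_NONE, MATCH_PARTIAL, MatureMiRNA
from .seqcore import GGACH, RRACH, NucleotideSequence, reverse_complement, scan_motif
from .stage_dynamics import CALL_DOWN, CALL_UP, StageMatrix
from .target_annotation import UTRRecord, find_target_sites

BASES = "ACGU"


class GenerationError(RuntimeError):
    """Raised when planted construction fails within the attempt budget."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions the pipeline is built for: a
    139-miRNA cardiac catalogue with 1 stringent and 9 relaxed-only seed
    matches; ~30% of genes targeted, with m6A modification on ~30.2% of
    targets; a unit enrichment-score shift for m6A-modified targets; and
    two-stage developmental dynamics with 86.2% vs 72.3% down-regulation in
    the m6A-modified vs unmodified strata.
    """

    rng_seed: int = 0
    # miRNA catalogue
    n_mirnas: int = 139
    n_full_match: int = 1
    n_partial_match: int = 9
    mature_length: int = 22
    # UTR genome
    n_genes: int = 500
    utr_length_mean: int = 200
    p_target: float = 0.30
    p_m6a_given_target: float = 0.302
    p_m6a_given_nontarget: float = 0.302
    p_geneset_only: float = 0.05  # in m6A gene set but no motif planted
    p_motif_only: float = 0.05  # motif planted but not in the gene set
    plant_site_type: str = "7mer-m8"
    motif_in_site: bool = False  # place planted motifs inside planted sites when possible
    # enrichment scores
    score_mean_base: float = 2.0
    score_delta_m6a: float = 1.0
    score_sd: float = 1.0
    # stage dynamics
    n_stages: int = 2
    f_down_m6a: float = 0.862
    f_down_non_m6a: float = 0.723
    fold_change_magnitude: float = 2.0
    # construction
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "p_target",
            "p_m6a_given_target",
            "p_m6a_given_nontarget",
            "p_geneset_only",
            "p_motif_only",
            "f_down_m6a",
            "f_down_non_m6a",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_full_match + self.n_partial_match > self.n_mirnas:
            raise ValueError("n_full_match + n_partial_match exceeds n_mirnas")
        if self.score_sd <= 0:
            raise ValueError("score_sd must be positive")
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2 (reference plus a comparison)")
        if self.fold_change_magnitude <= 1.0:
            raise ValueError("fold_change_magnitude must be > 1")


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _seq(s: str) -> NucleotideSequence:
    return NucleotideSequence(id="", residues=s)


def _site7_with_class(rng: np.random.Generator, match_class: str, max_attempts: int) -> str:
    """A 7-mer target-site sequence whose motif content realizes the class."""
    for _ in range(max_attempts):
        if match_class == MATCH_FULL:
            offset = int(rng.integers(0, 3))
            inst = "GGAC" + "ACU"[rng.integers(0, 3)]
            flank = _random_rna(rng, 2)
            site = flank[:offset] + inst + flank[offset:]
        elif match_class == MATCH_PARTIAL:
            offset = int(rng.integers(0, 3))
            # an RRACH instance that is not also GGACH: (R1,R2) != (G,G)
            r1r2 = [("A", "A"), ("A", "G"), ("G", "A")][rng.integers(0, 3)]
            inst = r1r2[0] + r1r2[1] + "AC" + "ACU"[rng.integers(0, 3)]
            flank = _random_rna(rng, 2)
            site = flank[:offset] + inst + flank[offset:]
        else:
            site = _random_rna(rng, 7)
        has_g = bool(scan_motif(_seq(site), GGACH))
        has_r = bool(scan_motif(_seq(site), RRACH))
        if match_class == MATCH_FULL and has_g:
            return site
        if match_class == MATCH_PARTIAL and has_r and not has_g:
            return site
        if match_class == MATCH_NONE and not has_r:
            return site
    raise GenerationError(
        f"could not construct a {match_class} site in {max_attempts} attempts; "
        "relax the configuration"
    )


def gen_mirna_catalogue(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[MatureMiRNA], dict[str, str]]:
    """A catalogue with planted FULL / PARTIAL / NONE seed classes.

    Returns the miRNAs (catalogue order, with classes shuffled across
    positions) and the truth map name → match class.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    classes = np.array(
        [MATCH_FULL] * cfg.n_full_match
        + [MATCH_PARTIAL] * cfg.n_partial_match
        + [MATCH_NONE] * (cfg.n_mirnas - cfg.n_full_match - cfg.n_partial_match)
    )
    classes = classes[rng.permutation(len(classes))]
    mirnas: list[MatureMiRNA] = []
    truth: dict[str, str] = {}
    width = max(3, len(str(cfg.n_mirnas)))
    for i, cls in enumerate(classes):
        name = f"syn-miR-{i + 1:0{width}d}"
        site = _site7_with_class(rng, str(cls), cfg.max_attempts)
        seed = reverse_complement(_seq(site)).residues  # becomes mature positions 2-8
        first = BASES[rng.integers(0, 4)]
        tail = _random_rna(rng, cfg.mature_length - 8)
        mature = first + seed + tail
        mirnas.append(
            MatureMiRNA(name=name, sequence=NucleotideSequence(id=name, residues=mature))
        )
        truth[name] = str(cls)
    return mirnas, truth


def _planted_site_sequence(mirna: MatureMiRNA, site_type: str) -> str:
    """UTR-strand sequence realizing a site of the given type for this miRNA."""
    mat = mirna.sequence.residues
    rc28 = reverse_complement(_seq(mat[1:8])).residues  # pairs miRNA positions 2-8
    rc27 = reverse_complement(_seq(mat[1:7])).residues  # pairs positions 2-7
    if site_type == "8mer":
        return rc28 + "A"
    if site_type == "7mer-m8":
        return rc28
    if site_type == "7mer-A1":
        return rc27 + "A"
    if site_type == "6mer":
        return rc27
    raise ValueError(f"unknown site type {site_type!r}")


@dataclass
class GeneTruth:
    """Planted per-gene truth, consistent with the emitted sequences."""

    gene_id: str
    is_target: bool
    site_start: int | None
    site_end: int | None
    site_type: str | None
    m6a_in_gene_set: bool
    ggach_in_utr: bool
    motif_start: int | None
    motif_end: int | None
    motif_overlaps_site: bool
    m6a_modified_target: bool
    m6a_modified_target_strict: bool


def _attempt_utr(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    mirna: MatureMiRNA,
    gene_id: str,
    is_target: bool,
    plant_motif: bool,
) -> tuple[str, GeneTruth] | None:
    """One construction attempt; None when the verification screen rejects it."""
    length = max(60, int(rng.poisson(cfg.utr_length_mean)))
    site_seq = _planted_site_sequence(mirna, cfg.plant_site_type) if is_target else ""
    site_motif_hits = scan_motif(_seq(site_seq), GGACH) if site_seq else []

    seq = _random_rna(rng, length)
    pos = None
    if is_target:
        pos = int(rng.integers(5, length - len(site_seq) - 5))
        seq = seq[:pos] + site_seq + seq[pos + len(site_seq) :]
        end = pos + len(site_seq)
        # keep the planted type exact: no chance A1 promotion downstream,
        # no chance m8 extension upstream of a core-only plant
        if cfg.plant_site_type in ("7mer-m8", "6mer") and end < len(seq) and seq[end] == "A":
            seq = seq[:end] + "CGU"[rng.integers(0, 3)] + seq[end + 1 :]
        if cfg.plant_site_type in ("6mer", "7mer-A1") and pos >= 1:
            m8c = reverse_complement(_seq(mirna.sequence.residues[7])).residues
            if seq[pos - 1] == m8c:
                repl = [b for b in BASES if b != m8c][rng.integers(0, 3)]
                seq = seq[: pos - 1] + repl + seq[pos:]

    motif_start = motif_end = None
    if plant_motif:
        if cfg.motif_in_site and site_motif_hits:
            hit = site_motif_hits[0]
            motif_start, motif_end = pos + hit.start, pos + hit.end
        else:
            inst = "GGAC" + "ACU"[rng.integers(0, 3)]
            placed = False
            for _ in range(50):
                mpos = int(rng.integers(0, len(seq) - 4))
                if site_seq and not (mpos + 5 <= pos or mpos >= pos + len(site_seq)):
                    continue
                placed = True
                break
            if not placed:
                return None
            seq = seq[:mpos] + inst + seq[mpos + 5 :]
            motif_start, motif_end = mpos, mpos + 5

    # verification against the pipeline's own primitives: the planted truth
    # must be exactly what the discrete layers will recover
    rec = UTRRecord(gene_id=gene_id, sequence=NucleotideSequence(id=gene_id, residues=seq))
    sites = find_target_sites(rec, mirna, min_site_type="6mer")
    if is_target:
        if len(sites) != 1:
            return None
        found = sites[0]
        if found.site_type != cfg.plant_site_type or found.start != pos:
            return None
        site_start, site_end = found.start, found.end
    else:
        if sites:
            return None
        site_start = site_end = None

    hits = scan_motif(rec.sequence, GGACH)
    expected_intervals: set[tuple[int, int]] = set()
    if plant_motif and motif_start is not None:
        expected_intervals.add((motif_start, motif_end))
    if is_target:
        for h in site_motif_hits:
            expected_intervals.add((pos + h.start, pos + h.end))
    if {(h.start, h.end) for h in hits} != expected_intervals:
        return None
    expected_ggach = bool(expected_intervals)
    overlaps = any(
        h.overlaps(site_start, site_end) for h in hits
    ) if is_target else False

    return seq, GeneTruth(
        gene_id=gene_id,
        is_target=is_target,
        site_start=site_start,
        site_end=site_end,
        site_type=cfg.plant_site_type if is_target else None,
        m6a_in_gene_set=False,  # filled by gen_utr_genome
        ggach_in_utr=expected_ggach,
        motif_start=motif_start,
        motif_end=motif_end,
        motif_overlaps_site=overlaps,
        m6a_modified_target=False,
        m6a_modified_target_strict=False,
    )


def gen_utr_genome(
    cfg: SimulationConfig,
    mirna: MatureMiRNA,
    rng: np.random.Generator | None = None,
) -> tuple[list[UTRRecord], set[str], list[tuple[str, int, int]], dict[str, GeneTruth]]:
    """A 3'UTR genome with planted sites and m6A status for one screened miRNA.

    Returns (UTR records, m6A gene set, motif peak intervals, truth by gene).
    Per gene: target status ~ Bernoulli(p_target); m6A modification (gene-set
    membership AND planted motif) ~ Bernoulli(p_m6a_given_target or
    p_m6a_given_nontarget); discordant genes (set-only, motif-only) are added
    at small rates so the conjunction rule is exercised.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    utrs: list[UTRRecord] = []
    gene_set: set[str] = set()
    peaks: list[tuple[str, int, int]] = []
    truth: dict[str, GeneTruth] = {}
    width = max(4, len(str(cfg.n_genes)))
    for i in range(cfg.n_genes):
        gene_id = f"gene{i + 1:0{width}d}"
        is_target = bool(rng.random() < cfg.p_target)
        p_mod = cfg.p_m6a_given_target if is_target else cfg.p_m6a_given_nontarget
        modified = bool(rng.random() < p_mod)
        if modified:
            in_set, plant_motif = True, True
        else:
            in_set = bool(rng.random() < cfg.p_geneset_only)
            plant_motif = bool(rng.random() < cfg.p_motif_only)
        built = None
        for _ in range(cfg.max_attempts):
            built = _attempt_utr(cfg, rng, mirna, gene_id, is_target, plant_motif)
            if built is not None:
                break
        if built is None:
            raise GenerationError(
                f"could not construct UTR for {gene_id} in {cfg.max_attempts} attempts; "
                "shorten utr_length_mean or relax the configuration"
            )
        seq, gt = built
        gt.m6a_in_gene_set = in_set
        gt.m6a_modified_target = gt.is_target and in_set and gt.ggach_in_utr
        gt.m6a_modified_target_strict = gt.m6a_modified_target and gt.motif_overlaps_site
        utrs.append(
            UTRRecord(gene_id=gene_id, sequence=NucleotideSequence(id=gene_id, residues=seq))
        )
        if in_set:
            gene_set.add(gene_id)
        if gt.motif_start is not None:
            peaks.append((gene_id, gt.motif_start, gt.motif_end))
        truth[gene_id] = gt
    return utrs, gene_set, peaks, truth


def gen_scores(
    cfg: SimulationConfig,
    truth: dict[str, GeneTruth],
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Per-target-gene enrichment scores with a group shift for m6A-modified targets.

    score ~ Normal(score_mean_base + score_delta_m6a·[m6A-modified target], score_sd).
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    scores: dict[str, float] = {}
    for gene_id, gt in truth.items():
        if not gt.is_target:
            continue
        mu = cfg.score_mean_base + (cfg.score_delta_m6a if gt.m6a_modified_target else 0.0)
        scores[gene_id] = float(rng.normal(mu, cfg.score_sd))
    return scores


def gen_timecourse(
    cfg: SimulationConfig,
    truth: dict[str, GeneTruth],
    rng: np.random.Generator | None = None,
) -> tuple[StageMatrix, dict[str, dict[str, str]]]:
    """A gene × stage abundance matrix with Bernoulli-planted regulation calls.

    Reference-stage abundances are lognormal; each later stage scales every
    gene by fold_change_magnitude^±1, the sign drawn DOWN with probability
    f_down_m6a for m6A-modified targets and f_down_non_m6a for all other
    genes. Returns the matrix and planted calls[stage][gene].
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    genes = list(truth)
    stage_labels = [f"S{k}" for k in range(cfg.n_stages)]
    ref = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=len(genes))
    cols = {stage_labels[0]: ref}
    planted: dict[str, dict[str, str]] = {}
    for stage in stage_labels[1:]:
        f = np.array(
            [
                cfg.f_down_m6a if truth[g].m6a_modified_target else cfg.f_down_non_m6a
                for g in genes
            ]
        )
        down = rng.random(len(genes)) < f
        vals = ref * np.where(down, 1.0 / cfg.fold_change_magnitude, cfg.fold_change_magnitude)
        cols[stage] = vals
        planted[stage] = {
            g: (CALL_DOWN if d else CALL_UP) for g, d in zip(genes, down)
        }
    frame = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return StageMatrix(values=frame, reference_stage=stage_labels[0]), planted


@dataclass
class SimulationResult:
    """All synthetic inputs plus their joint ground truth."""

    config: SimulationConfig
    mirnas: list[MatureMiRNA]
    mirna_truth: dict[str, str]
    focal_mirna: MatureMiRNA
    utrs: list[UTRRecord]
    m6a_gene_set: set[str]
    peaks: list[tuple[str, int, int]]
    gene_truth: dict[str, GeneTruth]
    scores: dict[str, float]
    matrix: StageMatrix
    regulation_truth: dict[str, dict[str, str]]


def simulate_all(cfg: SimulationConfig) -> SimulationResult:
    """Run every generator off one seeded RNG stream.

    The focal miRNA for the genome/scores/timecourse stages is the first
    planted FULL match (the miR-133a analogue); with no FULL plants, the
    first catalogue entry.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    mirnas, mirna_truth = gen_mirna_catalogue(cfg, rng)
    focal = next(
        (m for m in mirnas if mirna_truth[m.name] == MATCH_FULL), mirnas[0]
    )
    utrs, gene_set, peaks, gene_truth = gen_utr_genome(cfg, focal, rng)
    scores = gen_scores(cfg, gene_truth, rng)
    matrix, reg_truth = gen_timecourse(cfg, gene_truth, rng)
    return SimulationResult(
        config=cfg,
        mirnas=mirnas,
        mirna_truth=mirna_truth,
        focal_mirna=focal,
        utrs=utrs,
        m6a_gene_set=gene_set,
        peaks=peaks,
        gene_truth=gene_truth,
        scores=scores,
        matrix=matrix,
        regulation_truth=reg_truth,
    )


def truth_as_json(result: SimulationResult) -> dict:
    """The ground truth as a JSON-serializable dictionary."""
    return {
        "config": dataclasses.asdict(result.config),
        "focal_mirna": result.focal_mirna.name,
        "mirna_classes": dict(result.mirna_truth),
        "genes": {g: dataclasses.asdict(t) for g, t in result.gene_truth.items()},
        "regulation": {s: dict(c) for s, c in result.regulation_truth.items()},
    }


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write mirnas.fasta, utrs.fasta, m6a_genes.tsv, m6a_peaks.bed, scores.tsv,
    matrix.tsv and truth.json; returns the path of each artifact."""
    from . import io as mio  # local import to avoid a cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirnas": outdir / "mirnas.fasta",
        "utrs": outdir / "utrs.fasta",
        "m6a_genes": outdir / "m6a_genes.tsv",
        "m6a_peaks": outdir / "m6a_peaks.bed",
        "scores": outdir / "scores.tsv",
        "matrix": outdir / "matrix.tsv",
        "truth": outdir / "truth.json",
    }
    mio.write_fasta(paths["mirnas"], [(m.name, m.sequence.residues) for m in result.mirnas])
    mio.write_fasta(paths["utrs"], [(u.gene_id, u.sequence.residues) for u in result.utrs])
    mio.write_gene_set(paths["m6a_genes"], sorted(result.m6a_gene_set))
    mio.write_bed(paths["m6a_peaks"], result.peaks)
    mio.write_scores(paths["scores"], result.scores)
    mio.write_matrix(paths["matrix"], result.matrix)
    with open(paths["truth"], "w") as fh:
        json.dump(truth_as_json(result), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
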