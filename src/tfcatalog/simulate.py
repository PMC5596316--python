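"""Synthetic data with known ground truth for the whole pipeline.

Three generators emulate the statistical structure the downstream stages
assume, so that every stage can be exercised closed-loop against planted
truth:

* :func:`gen_transcriptome` — transcripts in which each planted TF gene
  carries an ATG-initiated, stop-terminated ORF in a known forward frame,
  with accepted-family domain hits inside that ORF, plus optional decoy
  hits that must never survive filtering;
* :func:`gen_homology_hits` — 12-column alignment-hit tables (frog->human
  and human->frog) with planted one-to-one orthologs and family expansions,
  bitscores strictly ordered so reciprocal-best-hit recovery is exact;
* :func:`gen_counts` — negative-binomial count matrices for the regional
  dissection design (5 regions + whole embryo, 2 replicates) with planted
  pole enrichment, and a dense time course with unimodal expression bursts.

Everything is driven by one integer seed; sub-generators derive child
streams deterministically, so identical configs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .expression import ExpressionSet, REGIONS, WHOLE_EMBRYO
from .families import DEFAULT_FAMILIES, ZINC_FINGER_ACCESSIONS
from .orf import DomainHit, TranscriptModel, find_orf

logger = logging.getLogger(__name__)

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study.

    Defaults mirror the regional dissection design the pipeline targets:
    five embryo regions plus whole embryo, two clutch replicates, a planted
    4-fold pole enrichment, and moderate biological dispersion (NB size 10,
    i.e. squared biological CV of 0.1 between clutches).
    """

    n_genes: int = 200
    frac_tf: float = 0.3
    frac_c2h2_only: float = 0.25  # of TFs
    family_alphabet: tuple[str, ...] = tuple(acc for acc, _ in DEFAULT_FAMILIES)
    n_regions: int = 5
    n_replicates: int = 2
    n_timepoints: int = 30
    nb_dispersion: float = 10.0  # NB size parameter
    pole_fold: float = 4.0
    frac_pole_genes: float = 0.05  # of TFs, per pole
    frac_orthologs: float = 0.9  # of TFs with a planted human partner
    decoy_frac: float = 0.2  # of genes receiving a decoy hit
    n_burst_windows: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_tf", "frac_c2h2_only", "frac_pole_genes",
                     "frac_orthologs", "decoy_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pole_fold < 1:
            raise ValueError("pole_fold must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion (NB size) must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic child generator for one sub-stream."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators."""

    tf_gene_ids: set[str] = field(default_factory=set)
    c2h2_only_ids: set[str] = field(default_factory=set)
    orf_truth: dict[str, dict] = field(default_factory=dict)  # gene -> coords/frame
    transcript_of: dict[str, str] = field(default_factory=dict)
    ortholog_map: dict[str, str] = field(default_factory=dict)  # frog gene -> human
    reciprocal_of: dict[str, str] = field(default_factory=dict)  # human -> frog gene
    symbol_map: dict[str, str] = field(default_factory=dict)  # human -> symbol
    expansions: dict[str, list[str]] = field(default_factory=dict)
    pole_truth: dict[str, set[str]] = field(default_factory=dict)
    temporal_cluster_truth: dict[str, int] = field(default_factory=dict)
    decoy_genes: set[str] = field(default_factory=set)
    gene_families: dict[str, set[str]] = field(default_factory=dict)
    #: optional gene -> base expression mean; prespecified entries are
    #: honored by gen_counts, drawn values are recorded here
    base_mean: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.c2h2_only_ids <= self.tf_gene_ids
        assert set(self.pole_truth) <= self.tf_gene_ids


class EmptySimulationError(ValueError):
    """Raised when a generator is asked for zero output."""


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _random_sense_codons(rng: np.random.Generator, n: int) -> str:
    """n random codons, none a stop codon."""
    out = []
    while len(out) < n:
        codon = _random_seq(rng, 3)
        if codon not in _STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _plant_tf_transcript(rng: np.random.Generator) -> tuple[str, dict]:
    """A transcript whose unique longest ORF is planted with known coords.

    Rejection-samples until the planted ORF is what both the frame-aware
    and frame-free ORF callers recover, so closed-loop recovery holds by
    construction.
    """
    for _ in range(60):
        n_codons = int(rng.integers(120, 250))
        flank5 = int(rng.integers(20, 90))
        flank3 = int(rng.integers(20, 90))
        seq = (
            _random_seq(rng, flank5)
            + "ATG"
            + _random_sense_codons(rng, n_codons - 1)
            + _STOP_CODONS[int(rng.integers(3))]
            + _random_seq(rng, flank3)
        )
        frame = flank5 % 3
        nt_start = flank5
        nt_end = flank5 + 3 * n_codons  # excludes the stop codon
        protein_start = (nt_start - frame) // 3
        truth = {
            "frame": frame,
            "nt_start": nt_start,
            "nt_end": nt_end,
            "protein_start": protein_start,
            "protein_end": protein_start + n_codons,
        }
        framed = find_orf(seq, frame)
        free = find_orf(seq, None)
        if (
            framed.nt_start == free.nt_start == nt_start
            and framed.nt_end == free.nt_end == nt_end
            and free.frame == frame
        ):
            return seq, truth
    raise RuntimeError("could not plant a uniquely recoverable ORF")


def gen_transcriptome(
    cfg: SimConfig,
) -> tuple[list[TranscriptModel], list[DomainHit], GroundTruth]:
    """Generate transcripts, a domain-hit table and the planted truth.

    TF genes carry 1-3 accepted-family domain hits inside their planted ORF
    (e-value < 0.01 or significance flag 1); a ``decoy_frac`` fraction of
    genes additionally receives a decoy hit that fails the filter (below
    threshold, outside the ORF, or in the wrong frame).  Non-TF genes get
    no passing hits.  Also plants the orthology structure (human partners,
    expansions), pole truth and temporal burst labels consumed by the other
    generators.
    """
    if cfg.n_genes == 0:
        raise EmptySimulationError("n_genes is 0: nothing to generate")
    rng = cfg.rng(1)
    n_tf = int(round(cfg.frac_tf * cfg.n_genes))
    if cfg.frac_tf > 0 and n_tf == 0:
        logger.warning("frac_tf*n_genes < 1: zero TF genes generated")

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    tf_ids = sorted(rng.choice(gene_ids, size=n_tf, replace=False).tolist())
    n_zinc = int(round(cfg.frac_c2h2_only * n_tf))
    zinc_ids = sorted(rng.choice(tf_ids, size=n_zinc, replace=False).tolist()) if n_tf else []

    zinc_alphabet = sorted(set(cfg.family_alphabet) & ZINC_FINGER_ACCESSIONS)
    nonzinc_alphabet = sorted(set(cfg.family_alphabet) - ZINC_FINGER_ACCESSIONS)
    if n_zinc and not zinc_alphabet:
        raise ValueError("frac_c2h2_only > 0 requires zinc families in the alphabet")
    if n_tf - n_zinc > 0 and not nonzinc_alphabet:
        raise ValueError("non-zinc TFs require non-zinc families in the alphabet")
    fam_names = dict(DEFAULT_FAMILIES)

    truth = GroundTruth(tf_gene_ids=set(tf_ids), c2h2_only_ids=set(zinc_ids))
    transcripts: list[TranscriptModel] = []
    hits: list[DomainHit] = []

    def domain_hit(tx: str, acc: str, orf: dict, decoy: Optional[str] = None) -> DomainHit:
        p0, p1 = orf["protein_start"], orf["protein_end"]
        length = int(rng.integers(30, min(61, p1 - p0 - 2)))
        start = int(rng.integers(p0, p1 - length))
        frame = orf["frame"]
        e_value = 10.0 ** -float(rng.uniform(3, 30))
        significance = int(rng.random() < 0.8)
        if decoy == "threshold":
            e_value, significance = float(rng.uniform(0.05, 5.0)), 0
        elif decoy == "frame":
            frame = (frame + 1 + int(rng.integers(2))) % 3
        elif decoy == "outside":
            start = p1 + 2 + int(rng.integers(0, 10))
        return DomainHit(
            transcript_id=tx, accession=acc, family=fam_names.get(acc, acc),
            env_start=start, env_end=start + length, frame=frame,
            e_value=e_value, significance=significance,
            bit_score=float(rng.uniform(30, 300)),
        )

    for gene in gene_ids:
        tx_id = f"{gene}.t1"
        truth.transcript_of[gene] = tx_id
        if gene in truth.tf_gene_ids:
            seq, orf = _plant_tf_transcript(rng)
            truth.orf_truth[gene] = orf
            if gene in truth.c2h2_only_ids:
                fams = [str(f) for f in rng.choice(zinc_alphabet,
                                                   size=int(rng.integers(1, 3)))]
            else:
                fams = [str(f) for f in rng.choice(nonzinc_alphabet,
                                                   size=int(rng.integers(1, 3)))]
                if zinc_alphabet and rng.random() < 0.3:
                    fams.append(zinc_alphabet[int(rng.integers(len(zinc_alphabet)))])
            truth.gene_families[gene] = set(fams)
            for acc in fams:
                hits.append(domain_hit(tx_id, acc, orf))
            if cfg.decoy_frac > 0 and rng.random() < cfg.decoy_frac:
                truth.decoy_genes.add(gene)
                mode = ["threshold", "frame", "outside"][int(rng.integers(3))]
                acc = cfg.family_alphabet[int(rng.integers(len(cfg.family_alphabet)))]
                hits.append(domain_hit(tx_id, acc, orf, decoy=mode))
        else:
            seq = _random_seq(rng, int(rng.integers(300, 900)))
            if cfg.decoy_frac > 0 and rng.random() < cfg.decoy_frac:
                truth.decoy_genes.add(gene)
                acc = cfg.family_alphabet[int(rng.integers(len(cfg.family_alphabet)))]
                fake_orf = {"frame": 0, "protein_start": 0,
                            "protein_end": len(seq) // 3}
                hits.append(domain_hit(tx_id, acc, fake_orf, decoy="threshold"))
        transcripts.append(TranscriptModel(transcript_id=tx_id, gene_id=gene, sequence=seq))

    _plant_orthology(cfg, rng, truth, tf_ids)
    _plant_expression_truth(cfg, rng, truth, tf_ids)
    truth.validate()
    return transcripts, hits, truth


def _plant_orthology(cfg: SimConfig, rng: np.random.Generator,
                     truth: GroundTruth, tf_ids: list[str]) -> None:
    """Assign human partners: mostly one-to-one, ~10% of humans expanded."""
    mapped = [g for g in tf_ids if rng.random() < cfg.frac_orthologs]
    n_exp = len(mapped) // 10
    i_human = 0
    i = 0
    while i < len(mapped):
        human = f"hs{i_human:05d}"
        truth.symbol_map[human] = f"TF{i_human:04d}"
        if n_exp > 0 and i + 1 < len(mapped):
            # first n_exp humans take two frog genes each (an expansion)
            pair = [mapped[i], mapped[i + 1]]
            for g in pair:
                truth.ortholog_map[g] = human
            truth.expansions[human] = sorted(pair)
            truth.reciprocal_of[human] = sorted(pair)[0]
            i += 2
            n_exp -= 1
        else:
            truth.ortholog_map[mapped[i]] = human
            truth.reciprocal_of[human] = mapped[i]
            i += 1
        i_human += 1


def _plant_expression_truth(cfg: SimConfig, rng: np.random.Generator,
                            truth: GroundTruth, tf_ids: list[str]) -> None:
    """Plant per-pole enrichment sets and temporal burst labels."""
    n_pole = int(round(cfg.frac_pole_genes * len(tf_ids)))
    if n_pole and len(tf_ids) >= 4 * n_pole:
        dv = rng.choice(tf_ids, size=2 * n_pole, replace=False)
        av = rng.choice(tf_ids, size=2 * n_pole, replace=False)
        for g in dv[:n_pole]:
            truth.pole_truth.setdefault(g, set()).add("dorsal")
        for g in dv[n_pole:]:
            truth.pole_truth.setdefault(g, set()).add("ventral")
        for g in av[:n_pole]:
            truth.pole_truth.setdefault(g, set()).add("animal")
        for g in av[n_pole:]:
            truth.pole_truth.setdefault(g, set()).add("vegetal")
    for g in tf_ids:
        truth.temporal_cluster_truth[g] = int(rng.integers(cfg.n_burst_windows))


def gen_homology_hits(
    truth: GroundTruth, cfg: SimConfig, plant_tie: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """12-column alignment-hit tables, frog->human and human->frog.

    Each mapped frog gene's best forward hit is its planted human partner
    (query coordinates encode the planted ORF frame); the reverse table
    makes exactly one frog gene per human the reciprocal best.  Bitscores
    are strictly ordered so ties never occur unless ``plant_tie`` asks for
    one (an extra forward hit duplicating the top bitscore under a
    lexicographically larger subject, exercising the tie-break rule).
    """
    fwd_rows: list[list] = []
    rev_rows: list[list] = []
    if not truth.ortholog_map:
        return (pd.DataFrame(columns=_BLAST_COLUMNS),
                pd.DataFrame(columns=_BLAST_COLUMNS))
    rng = cfg.rng(2)
    humans = sorted(set(truth.ortholog_map.values()))

    def row(q: str, s: str, qstart0: int, qend0: int, bit: float, evalue: float) -> list:
        aln = qend0 - qstart0
        return [q, s, round(float(rng.uniform(40, 95)), 1), aln // 3, 0, 0,
                qstart0 + 1, qend0, 1, aln // 3, evalue, round(bit, 1)]

    bit_jitter = iter(np.linspace(0.0, 40.0, len(truth.ortholog_map) + 4))
    for gene in sorted(truth.ortholog_map):
        human = truth.ortholog_map[gene]
        tx = truth.transcript_of[gene]
        orf = truth.orf_truth[gene]
        is_reciprocal = truth.reciprocal_of[human] == gene
        top = 300.0 + next(bit_jitter) + (5.0 if is_reciprocal else 0.0)
        fwd_rows.append(row(tx, human, orf["nt_start"], orf["nt_end"], top, 1e-50))
        # one weaker secondary hit to some other human
        other = humans[int(rng.integers(len(humans)))]
        if other != human:
            fwd_rows.append(row(tx, other, orf["nt_start"], orf["nt_end"],
                                top - 150.0, 1e-12))
        if plant_tie:
            fwd_rows.append(row(tx, human + "_tie", orf["nt_start"], orf["nt_end"],
                                top, 1e-50))
            plant_tie = False

    for human in humans:
        gene = truth.reciprocal_of[human]
        rev_rows.append([human, truth.transcript_of[gene], 80.0, 200, 0, 0,
                         1, 200, 1, 600, 1e-60, 320.0])
        for other in truth.expansions.get(human, []):
            if other != gene:
                rev_rows.append([human, truth.transcript_of[other], 75.0, 200, 0, 0,
                                 1, 200, 1, 600, 1e-55, 300.0])
    return (pd.DataFrame(fwd_rows, columns=_BLAST_COLUMNS),
            pd.DataFrame(rev_rows, columns=_BLAST_COLUMNS))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative-binomial draw parameterized by (mean, size)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_counts(
    truth: GroundTruth, cfg: SimConfig
) -> tuple[ExpressionSet, ExpressionSet]:
    """Regional and temporal count matrices with planted structure.

    Regional: every gene has a log-normal base mean; pole-planted genes
    have that mean multiplied by ``cfg.pole_fold`` in their pole's region;
    whole-embryo means average the five regions.  Temporal: TF genes follow
    unimodal bumps centered on their planted burst window over a small
    baseline; non-TF genes are flat.  Counts are NB with size
    ``cfg.nb_dispersion``; per-sample library factors are log-uniform in
    [0.7, 1.3].  Both sets share gene IDs and effective lengths.
    """
    genes = sorted(truth.transcript_of)
    if not genes:
        raise EmptySimulationError("ground truth contains no genes")
    rng = cfg.rng(3)
    n = len(genes)
    base_mean = np.maximum(rng.lognormal(np.log(30.0), 1.2, size=n), 0.5)
    for gi, g in enumerate(genes):  # prespecified means override the draw
        if g in truth.base_mean:
            base_mean[gi] = truth.base_mean[g]
        else:
            truth.base_mean[g] = float(base_mean[gi])
    eff_length = pd.Series(rng.integers(500, 3000, size=n).astype(float), index=genes,
                           name="eff_length")

    # --- regional design
    region_names = list(REGIONS[: cfg.n_regions]) + [WHOLE_EMBRYO]
    pole_region = {p: POLE for p, (POLE, _, _) in _pole_axes_items()}
    region_mean = {r: base_mean.copy() for r in REGIONS[: cfg.n_regions]}
    for gi, g in enumerate(genes):
        for pole in truth.pole_truth.get(g, ()):
            region = pole_region[pole]
            if region in region_mean:
                region_mean[region][gi] *= cfg.pole_fold
    region_mean[WHOLE_EMBRYO] = np.mean(
        [region_mean[r] for r in REGIONS[: cfg.n_regions]], axis=0
    )

    cols, meta_rows, data = [], [], []
    for r in region_names:
        for rep in range(1, cfg.n_replicates + 1):
            lib = float(np.exp(rng.uniform(np.log(0.7), np.log(1.3))))
            cols.append(f"{r}_{rep}")
            meta_rows.append((f"{r}_{rep}", r, rep))
            data.append(_nb_draw(rng, region_mean[r] * lib, cfg.nb_dispersion))
    counts_regional = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    meta_regional = pd.DataFrame(meta_rows, columns=["sample", "region", "replicate"]
                                 ).set_index("sample")
    regional = ExpressionSet(counts=counts_regional, eff_length=eff_length,
                             metadata=meta_regional)

    # --- temporal design (one library per timepoint)
    rng_t = cfg.rng(4)
    t = np.arange(cfg.n_timepoints, dtype=float)
    centers = np.linspace(0.1, 0.9, cfg.n_burst_windows) * (cfg.n_timepoints - 1)
    width = max(cfg.n_timepoints / 12.0, 1.0)
    profiles = np.empty((n, cfg.n_timepoints))
    for gi, g in enumerate(genes):
        label = truth.temporal_cluster_truth.get(g)
        if label is None:
            profiles[gi] = base_mean[gi]
        else:
            bump = np.exp(-0.5 * ((t - centers[label]) / width) ** 2)
            profiles[gi] = base_mean[gi] * (0.03 + bump)
    cols_t, meta_t, data_t = [], [], []
    for ti in range(cfg.n_timepoints):
        lib = float(np.exp(rng_t.uniform(np.log(0.7), np.log(1.3))))
        cols_t.append(f"t{ti:02d}")
        meta_t.append((f"t{ti:02d}", ti, 1))
        data_t.append(_nb_draw(rng_t, profiles[:, ti] * lib, cfg.nb_dispersion))
    counts_temporal = pd.DataFrame(np.column_stack(data_t), index=genes, columns=cols_t)
    meta_temporal = pd.DataFrame(meta_t, columns=["sample", "timepoint", "replicate"]
                                 ).set_index("sample")
    temporal = ExpressionSet(counts=counts_temporal, eff_length=eff_length,
                             metadata=meta_temporal)
    return regional, temporal


def _pole_axes_items():
    from .regional import POLE_AXES
    return POLE_AXES.items()
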