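"""Readers and writers for every format the pipeline touches.

Formats: transcript/genome FASTA; GFF3 gene models (1-based inclusive,
converted to 0-based half-open at this boundary); domain-hit TSV in the
profile-scanner tabular dialect (seq id with a Transeq-style ``_1/_2/_3``
frame suffix, 1-based envelope/alignment coordinates, 0/1 significance
column); 12-column tabular alignment hits (blast outfmt-6 dialect, 1-based
alignment coordinates); counts / effective-length / sample-metadata TSVs;
ground-truth and summary JSON.

Malformed lines are logged and skipped; a file with more than 10% malformed
lines is rejected outright.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .expression import ExpressionSet
from .orf import DomainHit, TfRecord, TranscriptModel
from .orthology import AlignmentHit, NameAssignment

logger = logging.getLogger(__name__)

MAX_MALFORMED_FRACTION = 0.1

DOMAIN_HIT_COLUMNS = [
    "seq_id", "aln_start", "aln_end", "env_start", "env_end",
    "hmm_acc", "hmm_name", "type", "hmm_start", "hmm_end",
    "bit_score", "e_value", "significance",
]

ALIGNMENT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class MalformedFileError(ValueError):
    """Raised when more than 10% of a file's lines are malformed."""


def _check_malformed(path, n_bad: int, n_total: int) -> None:
    if n_bad:
        logger.warning("%s: skipped %d of %d malformed line(s)", path, n_bad, n_total)
    if n_total and n_bad / n_total > MAX_MALFORMED_FRACTION:
        raise MalformedFileError(f"{path}: {n_bad}/{n_total} lines malformed")


# ---------------------------------------------------------------------------
# FASTA / GFF3


def write_transcript_fasta(transcripts: Iterable[TranscriptModel], path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id,
                  description=f"gene={t.gene_id}")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transcript_fasta(path) -> list[TranscriptModel]:
    """Read spliced transcripts; gene IDs come from a ``gene=`` description
    tag when present, else the transcript ID minus a trailing ``.tN``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = None
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        if gene is None:
            gene = rec.id.rsplit(".t", 1)[0]
        out.append(TranscriptModel(transcript_id=rec.id, gene_id=gene,
                                   sequence=str(rec.seq).upper()))
    return out


def write_gff3(transcripts: Sequence[TranscriptModel], genome: dict[str, str],
               gff_path, fasta_path) -> None:
    """Lay transcripts end-to-end on one synthetic contig and write GFF3 +
    genome FASTA (one mRNA with one exon per gene; 1-based inclusive)."""
    contig_parts: list[str] = []
    lines = ["##gff-version 3"]
    pos = 0
    spacer = "N" * 50
    for t in transcripts:
        start = pos + 1  # 1-based
        end = pos + len(t.sequence)
        lines.append("\t".join([
            "chrSim", "tfcatalog", "gene", str(start), str(end), ".", "+", ".",
            f"ID=gene:{t.gene_id}",
        ]))
        lines.append("\t".join([
            "chrSim", "tfcatalog", "mRNA", str(start), str(end), ".", "+", ".",
            f"ID=mrna:{t.transcript_id};Parent=gene:{t.gene_id}",
        ]))
        lines.append("\t".join([
            "chrSim", "tfcatalog", "exon", str(start), str(end), ".", "+", ".",
            f"ID=exon:{t.transcript_id}.1;Parent=mrna:{t.transcript_id}",
        ]))
        contig_parts.append(t.sequence)
        contig_parts.append(spacer)
        pos = end + len(spacer)
    genome["chrSim"] = "".join(contig_parts)
    Path(gff_path).write_text("\n".join(lines) + "\n")
    SeqIO.write([SeqRecord(Seq(genome["chrSim"]), id="chrSim", description="")],
                str(fasta_path), "fasta")


def read_gff3_and_splice(gff_path, genome_fasta_path) -> list[TranscriptModel]:
    """Reconstitute spliced transcript sequences from a GFF3 file.

    Exons of each mRNA are sorted by position and concatenated; minus-strand
    transcripts are reverse-complemented.  GFF3 coordinates (1-based
    inclusive) are converted to 0-based half-open for slicing.  Exons that
    run past their contig raise; exons with a missing parent are skipped
    with a warning.
    """
    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genome = Fasta(str(genome_fasta_path), sequence_always_upper=True)
    out: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = (parents[0].id if parents else mrna.id).removeprefix("gene:")
        exons = sorted(db.children(mrna, featuretype="exon"),
                       key=lambda e: e.start)
        if not exons:
            logger.warning("mRNA %s has no exons; skipped", mrna.id)
            continue
        parts = []
        for exon in exons:
            contig = genome[exon.seqid]
            if exon.end > len(contig):
                raise ValueError(
                    f"exon {exon.id} extends past contig {exon.seqid} "
                    f"({exon.end} > {len(contig)})"
                )
            parts.append(str(contig[exon.start - 1: exon.end]))  # to 0-based half-open
        seq = "".join(parts)
        if mrna.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out.append(TranscriptModel(
            transcript_id=mrna.id.removeprefix("mrna:"),
            gene_id=gene_id,
            sequence=seq,
            source_locus=(None, mrna.seqid, mrna.start - 1, mrna.end, mrna.strand),
        ))
    return out


# ---------------------------------------------------------------------------
# domain hits (profile-scanner tabular dialect)


def _frame_suffix(transcript_id: str, frame: int) -> str:
    return f"{transcript_id}_{frame + 1}"  # Transeq-style frame suffix


def _parse_frame_suffix(seq_id: str) -> tuple[str, int]:
    base, _, suffix = seq_id.rpartition("_")
    frame = int(suffix) - 1
    if not base or frame not in (0, 1, 2):
        raise ValueError(f"cannot parse frame suffix from {seq_id!r}")
    return base, frame


def write_domain_hits(hits: Iterable[DomainHit], path) -> None:
    rows = []
    for h in hits:
        rows.append([
            _frame_suffix(h.transcript_id, h.frame),
            h.env_start + 1, h.env_end,  # 1-based inclusive on disk
            h.env_start + 1, h.env_end,
            h.accession, h.family, "Domain", 1, h.env_end - h.env_start,
            h.bit_score, h.e_value, h.significance,
        ])
    pd.DataFrame(rows, columns=DOMAIN_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_domain_hits(path) -> list[DomainHit]:
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if list(df.columns) != DOMAIN_HIT_COLUMNS:
        if df.shape[1] != len(DOMAIN_HIT_COLUMNS):
            raise MalformedFileError(
                f"{path}: expected {len(DOMAIN_HIT_COLUMNS)} columns, got {df.shape[1]}"
            )
        df.columns = DOMAIN_HIT_COLUMNS
    out, n_bad = [], 0
    for _, row in df.iterrows():
        try:
            tx, frame = _parse_frame_suffix(str(row["seq_id"]))
            out.append(DomainHit(
                transcript_id=tx,
                accession=str(row["hmm_acc"]),
                family=str(row["hmm_name"]),
                env_start=int(row["env_start"]) - 1,
                env_end=int(row["env_end"]),
                frame=frame,
                e_value=float(row["e_value"]),
                significance=int(row["significance"]),
                bit_score=float(row["bit_score"]),
            ))
        except (ValueError, TypeError):
            n_bad += 1
    _check_malformed(path, n_bad, len(df))
    return out


# ---------------------------------------------------------------------------
# 12-column alignment hits


def write_alignment_hits(df: pd.DataFrame, path) -> None:
    df[ALIGNMENT_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_alignment_hits(path, subject_species: str = "human",
                        e_value_max: float = 1e-8) -> list[AlignmentHit]:
    """Read a 12-column alignment-hit file.

    The e-value gate (default 1e-8) is applied here at load time; 1-based
    alignment coordinates become 0-based half-open.  Rows failing to parse
    are skipped with a warning.
    """
    out, n_bad, n_total = [], 0, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_total += 1
            parts = line.split("\t")
            if len(parts) != 12:
                n_bad += 1
                continue
            try:
                evalue, bit = float(parts[10]), float(parts[11])
                qstart, qend = int(parts[6]) - 1, int(parts[7])
            except ValueError:
                n_bad += 1
                continue
            if evalue > e_value_max:
                continue
            out.append(AlignmentHit(
                query_id=parts[0], subject_id=parts[1],
                subject_species=subject_species,
                bit_score=bit, e_value=evalue, qstart=qstart, qend=qend,
            ))
    _check_malformed(path, n_bad, n_total)
    return out


# ---------------------------------------------------------------------------
# expression matrices


def write_expression_set(expr: ExpressionSet, counts_path, lengths_path,
                         metadata_path) -> None:
    expr.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    expr.eff_length.rename("eff_length").rename_axis("gene_id").to_csv(
        lengths_path, sep="\t")
    expr.metadata.rename_axis("sample").to_csv(metadata_path, sep="\t")


def read_expression_set(counts_path, lengths_path, metadata_path) -> ExpressionSet:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"{counts_path}: duplicated gene ID {dup!r}")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")["eff_length"]
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    return ExpressionSet(counts=counts, eff_length=lengths, metadata=metadata)


# ---------------------------------------------------------------------------
# catalog / names / poles tables, JSON


def write_catalog(catalog: Sequence[TfRecord], dubious: Sequence[TfRecord],
                  path) -> None:
    rows = []
    for rec in list(catalog) + list(dubious):
        orf = rec.orf
        rows.append({
            "gene_id": rec.gene_id,
            "status": rec.status,
            "families": ",".join(sorted(rec.dbd_families)),
            "c2h2_only": int(rec.c2h2_only),
            "orf_frame": orf.frame if orf else "",
            "orf_nt_start": orf.nt_start if orf else "",
            "orf_nt_end": orf.nt_end if orf else "",
            "name": getattr(rec.name_assignment, "proposed_name", ""),
            "provenance": ";".join(rec.provenance),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_names(assignments: Sequence[NameAssignment], path) -> None:
    pd.DataFrame([{
        "gene_id": a.gene_id,
        "proposed_name": a.proposed_name,
        "source_subject": a.source_subject,
        "reciprocal": int(a.reciprocal),
        "conflict_with_annotation": int(a.conflict_with_annotation),
        "expansion": int(a.expansion),
    } for a in assignments]).to_csv(path, sep="\t", index=False)


def write_pole_calls(calls, summary: dict, calls_path, summary_path) -> None:
    pd.DataFrame([{
        "gene_id": c.gene_id, "axis": c.axis, "pole": c.pole,
        "fold": c.fold, "tpm_in_pole": c.tpm_in_pole, "ppde": c.ppde,
    } for c in calls]).to_csv(calls_path, sep="\t", index=False)
    write_json(summary, summary_path)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, set):
            return sorted(o)
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def ground_truth_to_json(truth, path) -> None:
    write_json({
        "tf_gene_ids": sorted(truth.tf_gene_ids),
        "c2h2_only_ids": sorted(truth.c2h2_only_ids),
        "orf_truth": truth.orf_truth,
        "ortholog_map": truth.ortholog_map,
        "expansions": truth.expansions,
        "pole_truth": {g: sorted(p) for g, p in truth.pole_truth.items()},
        "temporal_cluster_truth": truth.temporal_cluster_truth,
        "decoy_genes": sorted(truth.decoy_genes),
    }, path)
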