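"""ORF calling, domain-hit filtering and TF classification.

The catalog-construction procedure works on spliced transcript sequences:

1. translate each transcript in the three forward frames;
2. pick the likely coding frame from protein-alignment evidence when
   available (``select_frame``), otherwise consider all three frames;
3. call the open reading frame by simple codon counting — the longest
   ATG-initiated, stop-free codon run in the chosen frame (``find_orf``);
4. keep profile-domain hits that are significant (scanner significance flag
   of 1, or e-value < 0.01), lie in the ORF's frame and inside the called
   ORF, and belong to an accepted DBD family (``filter_hits``);
5. classify each gene: in the catalog iff it retains at least one accepted
   DBD hit; flagged ``c2h2_only`` iff every retained family is a C2H2/H2C2
   zinc finger; demoted to the dubious set by curation rules.

All coordinates are 0-based half-open internally.  Translation is
forward-strand only, matching the assumption that transcript models are
already oriented; a 6-frame mode is deliberately not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .families import DbdFamilyList

logger = logging.getLogger(__name__)

_VALID_ALPHABET = set("ACGTN")


class OrfError(ValueError):
    """Raised when no ORF can be called (e.g. sequence shorter than a codon)."""


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript in forward orientation."""

    transcript_id: str
    gene_id: str
    sequence: str
    annotated_name: Optional[str] = None
    source_locus: Optional[tuple] = None  # (assembly, chrom, start, end, strand)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence.upper()) - _VALID_ALPHABET
        if bad:
            raise ValueError(f"{self.transcript_id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame on one forward frame of a transcript.

    ``protein_start``/``protein_end`` are 0-based half-open on that frame's
    translation; ``nt_start = frame + 3*protein_start``.  ``atg_anchored``
    records whether the ORF starts at an ATG or fell back to the longest
    stop-free stretch (no ATG in frame).
    """

    frame: int
    protein_start: int
    protein_end: int
    nt_start: int
    nt_end: int
    frame_source: str  # "homology" | "longest"
    atg_anchored: bool = True

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")
        if self.protein_end <= self.protein_start:
            raise ValueError("empty ORF")
        if self.nt_start != self.frame + 3 * self.protein_start:
            raise ValueError("nt/protein coordinates inconsistent with frame")
        if self.nt_end - self.nt_start != 3 * (self.protein_end - self.protein_start):
            raise ValueError("nt span must be 3x protein span")


@dataclass(frozen=True)
class DomainHit:
    """One profile-domain match on a translated frame.

    ``env_start``/``env_end`` are 0-based half-open protein coordinates on
    the stated frame's translation.  ``significance`` is the scanner's 0/1
    confidence flag; ``accession`` identifies the Pfam family.
    """

    transcript_id: str
    accession: str
    family: str
    env_start: int
    env_end: int
    frame: int
    e_value: float
    significance: int
    bit_score: float

    def __post_init__(self) -> None:
        if self.env_end <= self.env_start:
            raise ValueError("empty domain envelope")
        if self.e_value < 0:
            raise ValueError("negative e-value")


@dataclass
class TfRecord:
    """Per-gene classification outcome."""

    gene_id: str
    status: str  # "catalog" | "dubious" | "non_tf"
    dbd_families: frozenset[str]  # accessions that passed filtering
    c2h2_only: bool
    orf: Optional[OrfCall] = None
    name_assignment: Optional[object] = None
    provenance: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# translation and ORF calling


def translate_three_frames(sequence: str) -> tuple[str, str, str]:
    """Translate a nucleotide sequence in the three forward frames.

    Standard genetic code; stops render ``*``; codons containing N render
    ``X``; a trailing partial codon is dropped.  The reverse strand is never
    translated.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters {sorted(bad)}")
    out = []
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()) if sub else "")
    return tuple(out)  # type: ignore[return-value]


def _frame_of_hit(qstart0: int) -> int:
    """Forward frame implied by a 0-based alignment query start."""
    return qstart0 % 3


def select_frame(homology_hits: Sequence[Mapping]) -> Optional[int]:
    """Pick the likely translation frame from protein-alignment evidence.

    ``homology_hits`` are mapping-like rows for one transcript with keys
    ``qstart`` (0-based), ``bit_score``, ``e_value`` and ``subject_id``.
    The single best hit wins (highest bit score; ties broken by lowest
    e-value then lexicographically smallest subject ID).  Returns ``None``
    when there are no usable hits.
    """
    usable = []
    for row in homology_hits:
        qstart = row["qstart"]
        if qstart is None or qstart < 0:
            logger.warning("select_frame: malformed query coordinates in %r; row skipped", row)
            continue
        usable.append(row)
    if not usable:
        return None
    best = min(usable, key=lambda r: (-r["bit_score"], r["e_value"], str(r["subject_id"])))
    return _frame_of_hit(best["qstart"])


def _orf_in_protein(protein: str, frame: int, frame_source: str) -> Optional[OrfCall]:
    """Longest ATG-initiated stop-free run in one frame's translation.

    Falls back to the longest stop-free stretch when the frame contains no
    methionine at all.  Returns ``None`` for an empty translation.
    """
    if not protein:
        return None
    best: Optional[tuple[int, int, bool]] = None  # (start, end, anchored)

    def consider(start: int, end: int, anchored: bool) -> None:
        nonlocal best
        if end <= start:
            return
        if best is None or (end - start) > (best[1] - best[0]):
            best = (start, end, anchored)

    # segments between stops; within each, the first M gives the longest
    # ATG-anchored run of that segment
    seg_start = 0
    for i, aa in enumerate(protein + "*"):
        if aa == "*":
            seg = protein[seg_start:i]
            m = seg.find("M")
            if m >= 0:
                consider(seg_start + m, i, True)
            seg_start = i + 1
    if best is None:
        # no ATG anywhere: longest stop-free stretch
        seg_start = 0
        for i, aa in enumerate(protein + "*"):
            if aa == "*":
                consider(seg_start, i, False)
                seg_start = i + 1
        if best is None:
            return None
    start, end, anchored = best
    return OrfCall(
        frame=frame,
        protein_start=start,
        protein_end=end,
        nt_start=frame + 3 * start,
        nt_end=frame + 3 * end,
        frame_source=frame_source,
        atg_anchored=anchored,
    )


def find_orf(sequence: str, frame: Optional[int] = None) -> OrfCall:
    """Call the ORF by simple codon counting.

    With a given ``frame`` (from homology evidence): the longest
    ATG-initiated, stop-free codon run in that frame, terminated by a stop
    or the sequence end.  With ``frame=None``: the longest such ORF across
    the three forward frames (ties: lowest frame index).  If a frame holds
    no ATG, the longest stop-free stretch is used and flagged.
    """
    if len(sequence) < 3:
        raise OrfError(f"sequence of length {len(sequence)} is shorter than one codon")
    proteins = translate_three_frames(sequence)
    if frame is not None:
        call = _orf_in_protein(proteins[frame], frame, "homology")
        if call is None:
            raise OrfError(f"no ORF in frame {frame}")
        return call
    calls = [_orf_in_protein(proteins[f], f, "longest") for f in range(3)]
    calls = [c for c in calls if c is not None]
    if not calls:
        raise OrfError("no ORF in any forward frame")
    # prefer ATG-anchored calls; longest wins, ties to lowest frame
    anchored = [c for c in calls if c.atg_anchored]
    pool = anchored if anchored else calls
    return max(pool, key=lambda c: (c.protein_end - c.protein_start, -c.frame))


# ---------------------------------------------------------------------------
# hit filtering and classification


def filter_hits(
    hits: Iterable[DomainHit],
    orf: OrfCall,
    families: DbdFamilyList,
    e_value_max: float = 0.01,
) -> list[DomainHit]:
    """Keep domain hits supported by the called ORF.

    A hit is kept iff it is significant (scanner flag 1 OR e-value strictly
    below ``e_value_max``), lies in the ORF's frame, its envelope falls
    inside the ORF's protein span, and its family is on the accepted list.
    """
    kept = []
    for h in hits:
        if not (h.significance == 1 or h.e_value < e_value_max):
            continue
        if h.frame != orf.frame:
            continue
        if not (orf.protein_start <= h.env_start and h.env_end <= orf.protein_end):
            continue
        if not families.is_accepted(h.accession):
            continue
        kept.append(h)
    return kept


def classify_gene(
    gene_id: str,
    kept_hits: Sequence[DomainHit],
    families: DbdFamilyList,
    orf: Optional[OrfCall] = None,
    annotated_name: Optional[str] = None,
) -> TfRecord:
    """Classify one gene from its filtered domain hits.

    ``catalog`` iff at least one kept hit; ``c2h2_only`` iff every kept
    family is a C2H2/H2C2 zinc finger; genes matching curation-exclusion
    rules are demoted to ``dubious`` with the rule recorded in provenance.
    """
    fams = frozenset(h.accession for h in kept_hits)
    provenance: list[str] = []
    if not fams:
        status = "non_tf"
        c2h2_only = False
    else:
        status = "catalog"
        c2h2_only = fams <= families.zinc_only
        if families.matches_excluded(gene_id, annotated_name):
            status = "dubious"
            provenance.append("curation:excluded-gene-pattern")
    return TfRecord(
        gene_id=gene_id,
        status=status,
        dbd_families=fams,
        c2h2_only=c2h2_only,
        orf=orf,
        provenance=provenance,
    )


def catalog_partition(total: int, zinc_only: int) -> int:
    """Non-zinc TF count from a catalog total and its C2H2/H2C2-only subset."""
    if not 0 <= zinc_only <= total:
        raise ValueError("zinc_only count must lie in [0, total]")
    return total - zinc_only


def detection_percentage(detected: int, total: int) -> int:
    """Percentage of the catalog detectable, to the nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= detected <= total:
        raise ValueError("detected must lie in [0, total]")
    return round(100 * detected / total)


def build_catalog(
    transcripts: Sequence[TranscriptModel],
    domain_hits: Iterable[DomainHit],
    homology_hits: Optional[Mapping[str, Sequence[Mapping]]] = None,
    families: Optional[DbdFamilyList] = None,
    e_value_max: float = 0.01,
) -> tuple[list[TfRecord], list[TfRecord], dict]:
    """Run the full classification: frame -> ORF -> filter -> classify.

    Parameters
    ----------
    transcripts
        Spliced transcript models (forward orientation).
    domain_hits
        All domain hits, any transcript; hits on transcripts absent from
        ``transcripts`` are logged and skipped.
    homology_hits
        Optional transcript_id -> alignment-hit rows used to pick the
        translation frame; transcripts without rows use the longest-ORF rule.
    families
        Accepted DBD family list; defaults to the package default.

    Returns
    -------
    (catalog, dubious, summary)
        ``catalog`` and ``dubious`` are TfRecord lists; ``summary`` reports
        total, c2h2_only, non_zinc (= total - c2h2_only), dubious and
        non_tf counts.
    """
    from .families import default_families

    if families is None:
        families = default_families()
    homology_hits = homology_hits or {}

    by_transcript: dict[str, list[DomainHit]] = {}
    known_ids = {t.transcript_id for t in transcripts}
    n_skipped = 0
    for h in domain_hits:
        if h.transcript_id not in known_ids:
            n_skipped += 1
            continue
        by_transcript.setdefault(h.transcript_id, []).append(h)
    if n_skipped:
        logger.warning("build_catalog: %d hits on unknown transcripts skipped", n_skipped)

    # classify per gene; a gene's record unions kept hits over its transcripts
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    catalog: list[TfRecord] = []
    dubious: list[TfRecord] = []
    n_non_tf = 0
    for gene_id in sorted(by_gene):
        kept_all: list[DomainHit] = []
        best_orf: Optional[OrfCall] = None
        best_kept = -1
        name = None
        for t in by_gene[gene_id]:
            name = name or t.annotated_name
            frame = select_frame(homology_hits.get(t.transcript_id, ()))
            try:
                orf = find_orf(t.sequence, frame)
            except OrfError:
                continue
            kept = filter_hits(by_transcript.get(t.transcript_id, ()), orf, families, e_value_max)
            kept_all.extend(kept)
            if len(kept) > best_kept:
                best_kept, best_orf = len(kept), orf
        rec = classify_gene(gene_id, kept_all, families, orf=best_orf, annotated_name=name)
        if rec.status == "catalog":
            catalog.append(rec)
        elif rec.status == "dubious":
            dubious.append(rec)
        else:
            n_non_tf += 1

    n_zinc = sum(r.c2h2_only for r in catalog)
    summary = {
        "total": len(catalog),
        "c2h2_only": n_zinc,
        "non_zinc": catalog_partition(len(catalog), n_zinc),
        "dubious": len(dubious),
        "non_tf": n_non_tf,
    }
    return catalog, dubious, summary
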