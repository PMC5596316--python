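"""Name assignment from cross-species best hits.

Candidate gene names come from the closest human protein match; reciprocal
best hits (RBH) — the frog gene is the human protein's best match *and*
vice versa — serve as an orthology proxy.  Frog-specific family expansions
show up as several frog genes sharing one human best match, of which at
most one can be reciprocal.  Mouse hits are carried as corroborating
metadata only; the naming authority is the human match, since frog
nomenclature follows human gene names (proposed symbols are lower-cased).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentHit:
    """One best-HSP pairwise alignment hit (query -> subject)."""

    query_id: str
    subject_id: str
    subject_species: str  # "human" | "mouse"
    bit_score: float
    e_value: float
    qstart: int = 0  # 0-based query alignment start (frame evidence)
    qend: int = 0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("negative e-value")


@dataclass(frozen=True)
class NameAssignment:
    """A proposed gene name derived from the closest human match."""

    gene_id: str
    proposed_name: str
    source_subject: str
    reciprocal: bool
    conflict_with_annotation: bool
    expansion: bool = False


def _hit_rank(h: AlignmentHit) -> tuple:
    # deterministic: bit score desc, e-value asc, subject lexicographic
    return (-h.bit_score, h.e_value, h.subject_id)


def best_hit_per_species(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """At most one best hit per subject species for one query.

    Max bit score wins; ties broken by lowest e-value then lexicographically
    smallest subject ID.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.subject_species)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.subject_species] = h
    return best


def best_hits_table(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """query_id -> single best hit (any species mix should be pre-filtered)."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return best


def reciprocal_best(
    forward: Mapping[str, str],
    reverse: Mapping[str, str],
) -> set[tuple[str, str]]:
    """Reciprocal best-hit pairs.

    ``forward`` maps each query to its best subject; ``reverse`` maps each
    subject to its best query.  ``(q, s)`` is an RBH pair iff
    ``forward[q] == s`` and ``reverse[s] == q``; each ID appears in at most
    one pair by construction.
    """
    return {(q, s) for q, s in forward.items() if reverse.get(s) == q}


def detect_expansions(forward: Mapping[str, str]) -> dict[str, list[str]]:
    """Group queries by shared best subject; keep groups of size >= 2.

    Several frog genes sharing one human best match indicate a frog-side
    family expansion (or a collapsed mammalian locus).
    """
    groups: dict[str, list[str]] = {}
    for q in sorted(forward):
        groups.setdefault(forward[q], []).append(q)
    return {s: qs for s, qs in groups.items() if len(qs) >= 2}


def propose_names(
    gene_best_hit: Mapping[str, AlignmentHit],
    rbh_pairs: set[tuple[str, str]],
    expansions: Mapping[str, Sequence[str]],
    symbol_map: Mapping[str, str],
    annotated_names: Optional[Mapping[str, str]] = None,
) -> list[NameAssignment]:
    """Propose a name per gene from its human best match.

    The proposed name is the human subject's gene symbol, lower-cased per
    frog nomenclature.  A conflict flag is raised when the gene already has
    an annotated name that differs case-insensitively.  Members of expanded
    families are flagged (suffixing is left to the caller).  Genes whose
    subject has no entry in ``symbol_map`` are skipped with a warning.
    """
    annotated_names = annotated_names or {}
    rbh_lookup = dict(rbh_pairs)
    expanded_queries = {q for qs in expansions.values() for q in qs}
    out: list[NameAssignment] = []
    for gene_id in sorted(gene_best_hit):
        hit = gene_best_hit[gene_id]
        symbol = symbol_map.get(hit.subject_id)
        if symbol is None:
            logger.warning("propose_names: no symbol for subject %s (gene %s); skipped",
                           hit.subject_id, gene_id)
            continue
        proposed = symbol.lower()
        annotated = annotated_names.get(gene_id)
        out.append(NameAssignment(
            gene_id=gene_id,
            proposed_name=proposed,
            source_subject=hit.subject_id,
            reciprocal=rbh_lookup.get(gene_id) == hit.subject_id,
            conflict_with_annotation=bool(annotated) and annotated.lower() != proposed,
            expansion=gene_id in expanded_queries,
        ))
    return out
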