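"""DNA-binding-domain (DBD) family lists and curation rules.

A transcription-factor catalog is defined relative to a curated set of Pfam
families judged to confer sequence-specific DNA binding.  The family list is
a *configuration input*: different projects curate different lists.  This
module ships a default list of well-known vertebrate DBD families (a compact
stand-in for a full curated list) and a YAML loader for user-supplied lists.

Two families get special treatment downstream: the C2H2 and H2C2 zinc-finger
families, which are large and fast-evolving.  Genes whose only accepted
domains are C2H2/H2C2 zinc fingers are flagged ``c2h2_only`` so the catalog
can be partitioned into zinc-finger-only and wider-repertoire TFs.

Curation may also *exclude* genes whose domain hits are misleading — e.g.
enzymes carrying degenerate homeobox-like domains that cannot bind DNA.
Exclusions are expressed as glob patterns matched against gene IDs and
annotated names; matching genes are demoted to the "dubious" set rather than
silently dropped.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import yaml

#: Default Pfam DBD families: (accession, name) pairs.  A compact default —
#: real projects supply their own curated list via ``load_families``.
DEFAULT_FAMILIES: tuple[tuple[str, str], ...] = (
    ("PF00046", "Homeodomain"),
    ("PF00096", "zf-C2H2"),
    ("PF13465", "zf-H2C2_2"),
    ("PF00010", "HLH"),
    ("PF00170", "bZIP_1"),
    ("PF00250", "Forkhead"),
    ("PF00105", "zf-C4"),
    ("PF00319", "SRF-TF"),
    ("PF00554", "RHD_DNA_bind"),
    ("PF00907", "T-box"),
    ("PF00751", "DM"),
    ("PF00292", "PAX"),
    ("PF00157", "Pou"),
    ("PF00505", "HMG_box"),
    ("PF02864", "STAT_bind"),
    ("PF00178", "Ets"),
    ("PF03165", "MH1"),
    ("PF00870", "P53"),
    ("PF01381", "HTH_3"),
    ("PF02319", "E2F_TDP"),
)

#: Accessions of the C2H2/H2C2 zinc-finger families.
ZINC_FINGER_ACCESSIONS: frozenset[str] = frozenset({"PF00096", "PF13465"})


@dataclass(frozen=True)
class DbdFamilyList:
    """Accepted DBD families plus curation rules.

    Parameters
    ----------
    accepted
        Pfam accessions of families accepted as sequence-specific DBDs.
    zinc_only
        Subset of ``accepted``: the C2H2/H2C2 zinc-finger accessions.
    excluded_genes
        Glob patterns; genes whose ID or annotated name matches any pattern
        are demoted to the dubious set (curation exceptions such as the
        ceramide synthases, whose homeobox-like domains are degenerate).
    names
        Optional accession -> family-name map for reporting.
    """

    accepted: frozenset[str]
    zinc_only: frozenset[str] = ZINC_FINGER_ACCESSIONS
    excluded_genes: tuple[str, ...] = ()
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accepted:
            raise ValueError("accepted family set must be non-empty")
        if not self.zinc_only <= self.accepted:
            raise ValueError("zinc_only families must be a subset of accepted")

    def is_accepted(self, accession: str) -> bool:
        return accession in self.accepted

    def is_zinc_only(self, accession: str) -> bool:
        return accession in self.zinc_only

    def matches_excluded(self, gene_id: str, annotated_name: str | None = None) -> bool:
        """True if the gene is removed from the catalog by a curation rule."""
        candidates = [gene_id]
        if annotated_name:
            candidates.append(annotated_name)
        return any(
            fnmatch.fnmatchcase(c.lower(), pat.lower())
            for c in candidates
            for pat in self.excluded_genes
        )

    def name_of(self, accession: str) -> str:
        return self.names.get(accession, accession)


def default_families(excluded_genes: tuple[str, ...] = ("cers*",)) -> DbdFamilyList:
    """The package's default family list.

    By default the ceramide-synthase pattern ``cers*`` is excluded: these
    enzymes carry degenerate homeobox domains that lack the residues needed
    for DNA binding, a classic curation exception.
    """
    return DbdFamilyList(
        accepted=frozenset(acc for acc, _ in DEFAULT_FAMILIES),
        zinc_only=ZINC_FINGER_ACCESSIONS,
        excluded_genes=tuple(excluded_genes),
        names=dict(DEFAULT_FAMILIES),
    )


def load_families(path) -> DbdFamilyList:
    """Load a family list from YAML.

    Expected keys: ``accepted`` (list of ``{accession, name}`` or plain
    accessions), optional ``zinc_only`` (list of accessions) and
    ``excluded_genes`` (list of glob patterns).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    names: dict[str, str] = {}
    accepted: list[str] = []
    for entry in doc["accepted"]:
        if isinstance(entry, dict):
            accepted.append(entry["accession"])
            if "name" in entry:
                names[entry["accession"]] = entry["name"]
        else:
            accepted.append(str(entry))
    zinc = frozenset(doc.get("zinc_only", sorted(ZINC_FINGER_ACCESSIONS & set(accepted))))
    return DbdFamilyList(
        accepted=frozenset(accepted),
        zinc_only=zinc,
        excluded_genes=tuple(doc.get("excluded_genes", ())),
        names=names,
    )


def write_families(families: DbdFamilyList, path) -> None:
    """Write a family list to YAML (inverse of :func:`load_families`)."""
    doc = {
        "accepted": [
            {"accession": acc, "name": families.name_of(acc)}
            for acc in sorted(families.accepted)
        ],
        "zinc_only": sorted(families.zinc_only),
        "excluded_genes": list(families.excluded_genes),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
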