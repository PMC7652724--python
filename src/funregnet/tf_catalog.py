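"""Transcription-factor classification from precomputed domain annotations.

A protein is called a TF when at least one of its PFAM or InterPro domain
accessions belongs to the packaged catalog of eukaryotic DNA-binding-domain
families.  PFAM and InterPro evidence are unioned: a hit from either source
suffices.  Proteins matching domains of several families get a deterministic
combination label such as ``Zn2Cys6+C2H2_ZF`` (ordered by the catalog's
canonical family order), and the per-family count matrix counts them once
under each member family while a separate combo table preserves the exact
combinations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "DomainAnnotation",
    "TFFamilyCatalog",
    "TFAssignment",
    "load_catalog",
    "default_catalog",
    "assign_families",
    "family_count_matrix",
    "read_domain_annotations",
]

_PFAM_RE = re.compile(r"^PF\d{5}(\.\d+)?$")
_IPR_RE = re.compile(r"^IPR\d{6}$")


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain call on one protein (PFAM or InterPro accession)."""

    protein_id: str
    accession: str
    source_db: str  # "PFAM" or "InterPro"

    def __post_init__(self):
        if self.source_db == "PFAM" and not _PFAM_RE.match(self.accession):
            raise ValueError(f"{self.accession!r} is not a PFAM accession")
        if self.source_db == "InterPro" and not _IPR_RE.match(self.accession):
            raise ValueError(f"{self.accession!r} is not an InterPro accession")
        if self.source_db not in ("PFAM", "InterPro"):
            raise ValueError(f"unknown source_db {self.source_db!r}")


@dataclass
class TFFamilyCatalog:
    """DNA-binding-domain family catalog: family name -> accession set.

    ``family_order`` fixes the canonical order used to build deterministic
    multi-family combination labels.
    """

    families: dict[str, set[str]]
    family_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.families:
            raise ValueError("catalog is empty")
        if not self.family_order:
            self.family_order = list(self.families)
        seen: dict[str, str] = {}
        for fam, accs in self.families.items():
            for acc in accs:
                if acc in seen:
                    raise ValueError(
                        f"accession {acc} mapped to two families: {seen[acc]} and {fam}"
                    )
                seen[acc] = fam
        self._acc_to_family = seen

    def family_of(self, accession: str) -> str | None:
        return self._acc_to_family.get(accession.split(".")[0])

    def __len__(self) -> int:
        return len(self.families)


@dataclass(frozen=True)
class TFAssignment:
    """A protein classified as a TF with its (canonically ordered) families."""

    protein_id: str
    families: tuple[str, ...]
    combo_label: str


def load_catalog(tsv_path) -> TFFamilyCatalog:
    """Load a two-column (family, accession) TSV into a catalog.

    Comment lines starting with '#' and an optional header row are skipped.
    Duplicate identical rows collapse; the same accession under two
    different families is a hard error.
    """
    families: dict[str, set[str]] = {}
    order: list[str] = []
    with open(tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed catalog row: {line!r}")
            fam, acc = parts
            if fam == "family" and acc == "accession":
                continue
            if fam not in families:
                families[fam] = set()
                order.append(fam)
            families[fam].add(acc)
    return TFFamilyCatalog(families, order)


def default_catalog() -> TFFamilyCatalog:
    """The packaged DNA-binding-domain family catalog."""
    ref = resources.files("funregnet").joinpath("data/tf_family_catalog.tsv")
    with resources.as_file(ref) as path:
        return load_catalog(path)


def read_domain_annotations(tsv_path) -> list[DomainAnnotation]:
    """Read a (protein_id, accession, source_db) TSV of domain calls."""
    df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype=str)
    required = {"protein_id", "accession", "source_db"}
    if not required.issubset(df.columns):
        raise ValueError(f"domain table must have columns {sorted(required)}")
    return [
        DomainAnnotation(r.protein_id, r.accession, r.source_db)
        for r in df.itertuples(index=False)
    ]


def assign_families(
    annotations: list[DomainAnnotation], catalog: TFFamilyCatalog
) -> list[TFAssignment]:
    """Classify proteins as TFs by catalog membership of their domains.

    Returns one assignment per protein with at least one catalog hit;
    proteins without hits are absent.  Unknown accessions are ignored.
    Families are ordered by the catalog's canonical order so combination
    labels are deterministic.
    """
    per_protein: dict[str, set[str]] = {}
    for ann in annotations:
        fam = catalog.family_of(ann.accession)
        if fam is not None:
            per_protein.setdefault(ann.protein_id, set()).add(fam)
    rank = {fam: i for i, fam in enumerate(catalog.family_order)}
    out = []
    for pid in sorted(per_protein):
        fams = tuple(sorted(per_protein[pid], key=lambda f: rank[f]))
        out.append(TFAssignment(pid, fams, "+".join(fams)))
    return out


def family_count_matrix(
    assignments_by_species: dict[str, list[TFAssignment]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally TF families per species.

    Returns ``(matrix, combo_table)``: ``matrix`` has one row per family
    observed in at least one species (a multi-domain protein counts once
    under each of its families); ``combo_table`` tallies the exact
    multi-family combination labels, one row per observed combination.
    """
    if not assignments_by_species:
        raise ValueError("need at least one species")
    fam_counts: dict[str, dict[str, int]] = {}
    combo_counts: dict[str, dict[str, int]] = {}
    for species, assignments in assignments_by_species.items():
        for a in assignments:
            for fam in a.families:
                fam_counts.setdefault(fam, {}).setdefault(species, 0)
                fam_counts[fam][species] += 1
            if len(a.families) > 1:
                combo_counts.setdefault(a.combo_label, {}).setdefault(species, 0)
                combo_counts[a.combo_label][species] += 1
    species_cols = list(assignments_by_species)
    matrix = (
        pd.DataFrame(fam_counts).T.reindex(columns=species_cols).fillna(0).astype(int)
    )
    combo = (
        pd.DataFrame(combo_counts).T.reindex(columns=species_cols).fillna(0).astype(int)
    )
    matrix.index.name = "family"
    combo.index.name = "combination"
    return matrix.sort_index(), combo.sort_index()
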