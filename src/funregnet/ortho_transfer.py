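"""Orthology-based transfer of curated regulatory interactions.

A curated TF->TG interaction from a source species is transferred to the
target species only when orthologs are found for BOTH the TF and the TG.
Many-to-many orthology is expanded as a full cross-product of target
co-orthologs; duplicate inferred pairs are then merged, with provenance
(the set of supporting source species), a consensus effect sign, and a
weight summed over a per-species weight scheme (default 1.0 per species,
so the weight is the number of supporting species).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologPair",
    "SourceInteraction",
    "InferredInteraction",
    "read_proteinortho",
    "read_interactions",
    "transfer_interactions",
    "merge_provenance",
]

EFFECTS = ("positive", "negative", "unknown")


@dataclass(frozen=True)
class OrthologPair:
    """One (source protein, target protein) ortholog pair.

    ``group_id`` ties together all pairs expanded from a single ortholog
    table row (co-ortholog group).
    """

    source_species: str
    source_protein: str
    target_protein: str
    group_id: int


@dataclass(frozen=True)
class SourceInteraction:
    """A curated TF->TG interaction in a source species."""

    source_species: str
    tf_id: str
    tg_id: str
    effect: str = "unknown"

    def __post_init__(self):
        if self.effect not in EFFECTS:
            raise ValueError(f"effect must be one of {EFFECTS}, got {self.effect!r}")


@dataclass(frozen=True)
class InferredInteraction:
    """A TF->TG interaction inferred in the target species.

    ``provenance`` is the set of source species supporting the edge;
    ``weight`` sums the per-species weights; ``tfbs_count`` is filled by
    the promoter-scanning stage (binding-site evidence, not a filter).
    """

    tf_id: str
    tg_id: str
    provenance: frozenset[str]
    effect: str = "unknown"
    weight: float = 1.0
    tfbs_count: int = 0
    has_matrix: bool = True

    def __post_init__(self):
        if not self.provenance:
            raise ValueError("provenance must be non-empty")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.effect not in EFFECTS:
            raise ValueError(f"effect must be one of {EFFECTS}, got {self.effect!r}")


def read_proteinortho(
    tsv_path, target_species: str, source_species_list: list[str]
) -> list[OrthologPair]:
    """Parse an ortholog table in the ProteinOrtho tab-delimited layout.

    Layout: a header row (``# Species  Genes  Alg.-Conn.  <col per proteome>``),
    then one row per ortholog group with comma-separated co-orthologs per
    species column and ``*`` marking absence.  Species columns are matched
    by name prefix (``Anidulans`` matches column ``Anidulans.faa``).
    Each row expands into the cross-product of source x target proteins.
    """
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{tsv_path}: missing ProteinOrtho header row")
        cols = header.lstrip("#").strip().split("\t")

        def find_col(species: str) -> int:
            for i, c in enumerate(cols):
                if c == species or c.split(".")[0] == species:
                    return i
            raise ValueError(f"{tsv_path}: no column for species {species!r} in header {cols}")

        target_col = find_col(target_species)
        source_cols = {sp: find_col(sp) for sp in source_species_list}

        pairs: list[OrthologPair] = []
        seen: set[tuple[str, str, str]] = set()
        for group_id, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tgt_cell = fields[target_col]
            if tgt_cell == "*" or not tgt_cell:
                continue
            targets = [t for t in tgt_cell.split(",") if t]
            for sp, col in source_cols.items():
                cell = fields[col]
                if cell == "*" or not cell:
                    continue
                for src in cell.split(","):
                    if not src:
                        continue
                    for tgt in targets:
                        key = (sp, src, tgt)
                        if key in seen:
                            continue
                        seen.add(key)
                        pairs.append(OrthologPair(sp, src, tgt, group_id))
    return pairs


def read_interactions(
    tsv_path, species: str, gene_list: set[str] | None = None
) -> list[SourceInteraction]:
    """Read a curated interaction TSV (columns ``tf_id``, ``tg_id``, optional
    ``effect``) for one source species.

    Effect values are case-normalized; missing effect defaults to
    ``unknown``.  When ``gene_list`` is given, rows whose TF or TG is not in
    it are dropped with a logged warning (cross-validation against the
    reference gene set).  Duplicate rows collapse to one interaction.
    """
    out: dict[tuple[str, str], SourceInteraction] = {}
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            tf_col = header.index("tf_id")
            tg_col = header.index("tg_id")
        except ValueError:
            raise ValueError(f"{tsv_path}: header must contain tf_id and tg_id columns")
        effect_col = header.index("effect") if "effect" in header else None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tf, tg = fields[tf_col], fields[tg_col]
            effect = "unknown"
            if effect_col is not None and effect_col < len(fields) and fields[effect_col]:
                effect = fields[effect_col].strip().lower()
                if effect not in EFFECTS:
                    raise ValueError(f"{tsv_path}: unknown effect value {fields[effect_col]!r}")
            if gene_list is not None and (tf not in gene_list or tg not in gene_list):
                logger.warning(
                    "%s: interaction %s->%s discarded (id not in reference gene list)",
                    species, tf, tg,
                )
                continue
            key = (tf, tg)
            if key in out:
                continue
            out[key] = SourceInteraction(species, tf, tg, effect)
    return list(out.values())


def transfer_interactions(
    interactions: list[SourceInteraction],
    ortholog_pairs: list[OrthologPair],
    target_species: str | None = None,
) -> list[InferredInteraction]:
    """Transfer interactions to the target species via orthology.

    For each source interaction, emits every (tf_target, tg_target) pair in
    the cross-product of the TF's and the TG's target orthologs; emits
    nothing when either side has no ortholog.  The result still contains one
    edge per (source interaction, target pair); collapse duplicates with
    :func:`merge_provenance`.
    """
    orth: dict[tuple[str, str], set[str]] = {}
    for p in ortholog_pairs:
        orth.setdefault((p.source_species, p.source_protein), set()).add(p.target_protein)
    edges: list[InferredInteraction] = []
    for it in interactions:
        tf_targets = orth.get((it.source_species, it.tf_id))
        tg_targets = orth.get((it.source_species, it.tg_id))
        if not tf_targets or not tg_targets:
            continue
        for tf_t in sorted(tf_targets):
            for tg_t in sorted(tg_targets):
                edges.append(
                    InferredInteraction(
                        tf_id=tf_t,
                        tg_id=tg_t,
                        provenance=frozenset({it.source_species}),
                        effect=it.effect,
                    )
                )
    return edges


def _consensus_effect(signs: set[str]) -> str:
    """Consensus over observed signs: a single sign (possibly alongside
    unknowns) wins; conflicting signs give unknown."""
    signed = signs - {"unknown"}
    if len(signed) == 1:
        return next(iter(signed))
    return "unknown"


def merge_provenance(
    edges: list[InferredInteraction], weight_scheme: dict[str, float] | None = None
) -> list[InferredInteraction]:
    """Collapse identical (tf, tg) pairs into single edges.

    Provenance is the union of supporting species; effect is the common
    sign if all signed sources agree, else ``unknown``; weight sums the
    weight scheme over the provenance set (default 1.0 per species).
    """
    merged: dict[tuple[str, str], InferredInteraction] = {}
    signs: dict[tuple[str, str], set[str]] = {}
    for e in edges:
        key = (e.tf_id, e.tg_id)
        signs.setdefault(key, set()).add(e.effect)
        if key not in merged:
            merged[key] = e
        else:
            prev = merged[key]
            merged[key] = replace(prev, provenance=prev.provenance | e.provenance)
    out: list[InferredInteraction] = []
    for key in sorted(merged):
        e = replace(merged[key], effect=_consensus_effect(signs[key]))
        if weight_scheme is None:
            weight = float(len(e.provenance))
        else:
            missing = e.provenance - weight_scheme.keys()
            if missing:
                raise ValueError(f"weight scheme lacks species {sorted(missing)}")
            for sp, w in weight_scheme.items():
                if w <= 0:
                    raise ValueError(f"weight for {sp} must be positive, got {w}")
            weight = sum(weight_scheme[sp] for sp in e.provenance)
        out.append(replace(e, weight=weight))
    return out
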