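"""Assembly and persistence of the inferred regulatory network.

The canonical on-disk deliverable is a TSV edge table (tf, tg, provenance,
effect, weight, tfbs_count) with a deterministic (tf, tg) sort.  An optional
single-file SQLite store mirrors the six-table relational schema used to
organize the pipeline's data: ``gene``, ``ortho``, ``pwm``, ``regulation``,
``tfbs_prediction`` and ``network_node``, with referential integrity
enforced on insert.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field

from funregnet.ortho_transfer import InferredInteraction

__all__ = [
    "RegulatoryNetwork",
    "build_network",
    "persist",
    "load_store",
    "export_edge_table",
    "import_edge_table",
    "SIX_TABLES",
]

SIX_TABLES = ("gene", "ortho", "pwm", "regulation", "tfbs_prediction", "network_node")

PROVENANCE_SEP = ";"


@dataclass
class RegulatoryNetwork:
    """A directed regulatory network with role-flagged nodes.

    A node is a TF iff it has at least one outgoing edge and a TG iff it has
    at least one incoming edge; (tf, tg) pairs are unique.
    """

    edges: list[InferredInteraction]
    nodes: set[str] = field(default_factory=set)
    tfs: set[str] = field(default_factory=set)
    tgs: set[str] = field(default_factory=set)

    @property
    def n_auto_regulations(self) -> int:
        return sum(1 for e in self.edges if e.tf_id == e.tg_id)

    def effect_tally(self) -> dict[str, int]:
        tally = {"positive": 0, "negative": 0, "unknown": 0}
        for e in self.edges:
            tally[e.effect] += 1
        return tally

    def provenance_category_counts(self) -> dict[int, int]:
        """Edges grouped by the number of supporting source species."""
        out: dict[int, int] = {}
        for e in self.edges:
            k = len(e.provenance)
            out[k] = out.get(k, 0) + 1
        return out


def build_network(edges: list[InferredInteraction]) -> RegulatoryNetwork:
    """Derive node roles from a merged (unique-pair) edge list."""
    seen = set()
    for e in edges:
        key = (e.tf_id, e.tg_id)
        if key in seen:
            raise ValueError(f"duplicate edge {key}; merge edges before building")
        seen.add(key)
    tfs = {e.tf_id for e in edges}
    tgs = {e.tg_id for e in edges}
    return RegulatoryNetwork(edges=list(edges), nodes=tfs | tgs, tfs=tfs, tgs=tgs)


def export_edge_table(network: RegulatoryNetwork, path) -> None:
    """Write the edge table as TSV, sorted by (tf, tg).

    Provenance is a semicolon-joined, lexicographically ordered species
    list.  Re-importing with :func:`import_edge_table` reproduces the
    network exactly.
    """
    with open(path, "w") as fh:
        fh.write("tf\ttg\tprovenance\teffect\tweight\ttfbs_count\thas_matrix\n")
        for e in sorted(network.edges, key=lambda e: (e.tf_id, e.tg_id)):
            prov = PROVENANCE_SEP.join(sorted(e.provenance))
            fh.write(
                f"{e.tf_id}\t{e.tg_id}\t{prov}\t{e.effect}\t{e.weight:g}\t"
                f"{e.tfbs_count}\t{int(e.has_matrix)}\n"
            )


def import_edge_table(path) -> RegulatoryNetwork:
    """Read an edge TSV written by :func:`export_edge_table`."""
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["tf", "tg", "provenance", "effect", "weight", "tfbs_count", "has_matrix"]
        if header != expected:
            raise ValueError(f"{path}: unexpected edge-table header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            edges.append(
                InferredInteraction(
                    tf_id=f[0],
                    tg_id=f[1],
                    provenance=frozenset(f[2].split(PROVENANCE_SEP)),
                    effect=f[3],
                    weight=float(f[4]),
                    tfbs_count=int(f[5]),
                    has_matrix=bool(int(f[6])),
                )
            )
    return build_network(edges)


_SCHEMA = """
CREATE TABLE gene (
    gene_id TEXT PRIMARY KEY,
    contig_id TEXT,
    start INTEGER,
    end INTEGER,
    strand TEXT
);
CREATE TABLE ortho (
    source_species TEXT NOT NULL,
    source_protein TEXT NOT NULL,
    target_protein TEXT NOT NULL REFERENCES gene(gene_id),
    group_id INTEGER,
    PRIMARY KEY (source_species, source_protein, target_protein)
);
CREATE TABLE pwm (
    matrix_id TEXT PRIMARY KEY,
    tf_id TEXT NOT NULL,
    width INTEGER NOT NULL
);
CREATE TABLE regulation (
    source_species TEXT NOT NULL,
    tf_id TEXT NOT NULL,
    tg_id TEXT NOT NULL,
    effect TEXT NOT NULL,
    PRIMARY KEY (source_species, tf_id, tg_id)
);
CREATE TABLE tfbs_prediction (
    gene_id TEXT NOT NULL REFERENCES gene(gene_id),
    matrix_id TEXT NOT NULL REFERENCES pwm(matrix_id),
    offset INTEGER NOT NULL,
    strand TEXT NOT NULL,
    word TEXT NOT NULL,
    score REAL NOT NULL,
    p_value REAL NOT NULL,
    PRIMARY KEY (gene_id, matrix_id, offset, strand)
);
CREATE TABLE network_node (
    tf_id TEXT NOT NULL REFERENCES gene(gene_id),
    tg_id TEXT NOT NULL REFERENCES gene(gene_id),
    provenance TEXT NOT NULL,
    effect TEXT NOT NULL,
    weight REAL NOT NULL,
    tfbs_count INTEGER NOT NULL,
    has_matrix INTEGER NOT NULL,
    PRIMARY KEY (tf_id, tg_id)
);
"""


def persist(
    path,
    genes=None,
    ortho_pairs=None,
    matrices=None,
    source_interactions=None,
    edges=None,
    hits=None,
) -> None:
    """Write a single-file SQLite store with the six-table relational schema.

    Foreign-key violations (a hit or edge referencing an unknown gene, a
    hit referencing an unknown matrix) are hard errors naming the orphan
    id.  Re-loading with :func:`load_store` reproduces the edge table
    exactly.
    """
    genes = genes or []
    ortho_pairs = ortho_pairs or []
    matrices = matrices or []
    source_interactions = source_interactions or []
    edges = edges or []
    hits = hits or []

    gene_ids = {g.gene_id for g in genes}
    matrix_ids = {m.matrix_id for m in matrices}
    for h in hits:
        if gene_ids and h.gene_id not in gene_ids:
            raise ValueError(f"tfbs_prediction references unknown gene {h.gene_id!r}")
        if matrix_ids and h.matrix_id not in matrix_ids:
            raise ValueError(f"tfbs_prediction references unknown matrix {h.matrix_id!r}")
    for e in edges:
        if gene_ids and (e.tf_id not in gene_ids or e.tg_id not in gene_ids):
            orphan = e.tf_id if e.tf_id not in gene_ids else e.tg_id
            raise ValueError(f"network_node references unknown gene {orphan!r}")

    con = sqlite3.connect(str(path))
    try:
        con.executescript(_SCHEMA)
        con.executemany(
            "INSERT INTO gene VALUES (?,?,?,?,?)",
            [(g.gene_id, g.contig_id, g.start, g.end, g.strand) for g in genes],
        )
        con.executemany(
            "INSERT OR IGNORE INTO ortho VALUES (?,?,?,?)",
            [
                (p.source_species, p.source_protein, p.target_protein, p.group_id)
                for p in ortho_pairs
            ],
        )
        con.executemany(
            "INSERT INTO pwm VALUES (?,?,?)",
            [(m.matrix_id, m.tf_id, m.width) for m in matrices],
        )
        con.executemany(
            "INSERT OR IGNORE INTO regulation VALUES (?,?,?,?)",
            [(i.source_species, i.tf_id, i.tg_id, i.effect) for i in source_interactions],
        )
        con.executemany(
            "INSERT OR IGNORE INTO tfbs_prediction VALUES (?,?,?,?,?,?,?)",
            [
                (h.gene_id, h.matrix_id, h.offset, h.strand, h.word, h.score, h.p_value)
                for h in hits
            ],
        )
        con.executemany(
            "INSERT INTO network_node VALUES (?,?,?,?,?,?,?)",
            [
                (
                    e.tf_id,
                    e.tg_id,
                    PROVENANCE_SEP.join(sorted(e.provenance)),
                    e.effect,
                    e.weight,
                    e.tfbs_count,
                    int(e.has_matrix),
                )
                for e in edges
            ],
        )
        con.commit()
    finally:
        con.close()


def load_store(path) -> RegulatoryNetwork:
    """Load the network back from a SQLite store written by :func:`persist`."""
    con = sqlite3.connect(str(path))
    try:
        tables = {
            row[0]
            for row in con.execute("SELECT name FROM sqlite_master WHERE type='table'")
        }
        missing = set(SIX_TABLES) - tables
        if missing:
            raise ValueError(f"store at {path} lacks tables {sorted(missing)}")
        rows = con.execute(
            "SELECT tf_id, tg_id, provenance, effect, weight, tfbs_count, has_matrix "
            "FROM network_node ORDER BY tf_id, tg_id"
        ).fetchall()
    finally:
        con.close()
    edges = [
        InferredInteraction(
            tf_id=r[0],
            tg_id=r[1],
            provenance=frozenset(r[2].split(PROVENANCE_SEP)),
            effect=r[3],
            weight=r[4],
            tfbs_count=r[5],
            has_matrix=bool(r[6]),
        )
        for r in rows
    ]
    return build_network(edges)
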