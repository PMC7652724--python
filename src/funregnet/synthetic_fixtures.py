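"""Seed-reproducible synthetic input bundles with planted ground truth.

The generator emulates every input the pipeline consumes — target genome
FASTA + GFF3, per-species curated interaction TSVs, an ortholog table in the
ProteinOrtho dialect, CIS-BP matrix files, domain and term annotation TSVs —
for a small imaginary target species, with full knowledge of what the
pipeline should infer from them:

* ortholog "concepts" link one gene per source species to 0, 1 or 2 target
  genes (fan-outs exercise the many-to-many cross-product rule);
* curated interactions are drawn between TF concepts and target concepts,
  each supported by one or more source species with an effect sign;
* the expected merged edge set is derived by directly applying the transfer
  rule (both-sides-orthologous cross-product, provenance union, consensus
  sign) to the generated tables;
* each TF's binding motif (near-consensus matrix, 0.97 per-position
  consensus probability) is planted into the promoters of its true targets
  at recorded offsets; the remaining sequence is i.i.d. uniform.

Generation is a pure function of the config (including the seed): the same
config yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from funregnet.ortho_transfer import InferredInteraction

__all__ = ["FixtureConfig", "GroundTruth", "FixtureBundle", "generate_fixture",
           "evaluate_against_truth", "EvaluationReport"]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of a synthetic input bundle.

    ``n_ortho_groups`` is the number of ortholog concepts; the realized
    number of target genes is the number of concepts that receive at least
    one target ortholog (rate ``orthology_rate``, doubled to two co-orthologs
    at rate ``co_ortholog_rate``).  The first ``n_motifs`` concepts are TF
    concepts, each with its own binding motif.
    """

    seed: int = 0
    n_ortho_groups: int = 60
    n_source_species: int = 3
    n_interactions: int = 40
    orthology_rate: float = 0.8
    co_ortholog_rate: float = 0.15
    n_motifs: int = 5
    motif_width: int = 9
    plant_rate: float = 0.9
    promoter_length: int = 1000
    gene_length: int = 300
    effect_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # positive, negative, unknown
    consensus_prob: float = 0.97
    target_species: str = "Ptarget"
    n_terms: int = 6

    def __post_init__(self):
        for name in ("orthology_rate", "co_ortholog_rate", "plant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.effect_mix) - 1.0) > 1e-9:
            raise ValueError("effect_mix must sum to 1")
        if min(self.n_ortho_groups, self.n_source_species, self.n_interactions,
               self.n_motifs, self.motif_width, self.promoter_length) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.motif_width > self.promoter_length:
            raise ValueError("motif wider than the promoter")
        if self.n_motifs > self.n_ortho_groups:
            raise ValueError("need at least as many ortholog groups as motifs")

    def fixture_id(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class GroundTruth:
    """What the pipeline is expected to recover from a bundle."""

    fixture_id: str
    target_genes: list[str]
    expected_edges: dict[tuple[str, str], tuple[frozenset[str], str]]
    planted_hits: list[tuple[str, str, int]]  # (target gene, matrix id, promoter offset)
    matrix_to_tf: dict[str, str]


@dataclass
class FixtureBundle:
    """Paths of the generated files plus the ground truth."""

    directory: str
    genome_fasta: str
    gff3: str
    proteinortho_tsv: str
    interaction_tsvs: dict[str, str]
    matrix_dir: str
    matrix_to_tf_tsv: str
    domains_tsv: str
    terms_tsv: str
    truth: GroundTruth
    source_species: list[str] = field(default_factory=list)


_DEFAULT_SOURCES = ["Anidulans", "Ncrassa", "Scerevisiae"]
#: DNA-binding-domain accessions handed to synthetic TF genes (present in the
#: packaged family catalog) and a non-DBD accession for the rest.
_TF_ACCESSIONS = ["PF00172", "PF00096", "PF00170", "PF00320", "PF00046"]
_NON_TF_ACCESSION = "PF00069"


def _species_names(n: int) -> list[str]:
    names = list(_DEFAULT_SOURCES)
    while len(names) < n:
        names.append(f"Source{len(names) + 1}")
    return names[:n]


def generate_fixture(config: FixtureConfig, out_dir) -> FixtureBundle:
    """Write a complete input bundle under ``out_dir`` and return its paths
    and ground truth.  Deterministic in ``config``."""
    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)
    sources = _species_names(config.n_source_species)
    P, W = config.promoter_length, config.motif_width

    # --- ortholog concepts ------------------------------------------------
    # concept i: one gene per source species, 0/1/2 target co-orthologs
    target_of: list[list[str]] = []
    counter = 0
    for i in range(config.n_ortho_groups):
        if rng.random() < config.orthology_rate:
            k = 2 if rng.random() < config.co_ortholog_rate else 1
            genes = []
            for _ in range(k):
                counter += 1
                # seed-tagged ids make outputs from different fixtures
                # detectable in evaluate_against_truth
                genes.append(f"PT{config.seed % 1000:03d}_{counter:05d}")
            target_of.append(genes)
        else:
            target_of.append([])
    src_gene = {
        (sp, i): f"{sp[:2]}_{i:04d}" for sp in sources for i in range(config.n_ortho_groups)
    }
    target_genes = [g for genes in target_of for g in genes]

    # --- curated interactions --------------------------------------------
    tf_concepts = list(range(config.n_motifs))
    effects = ["positive", "negative", "unknown"]
    interactions: list[tuple[int, int, str, list[str]]] = []
    seen_pairs: set[tuple[int, int]] = set()
    attempts = 0
    while len(interactions) < config.n_interactions and attempts < 50 * config.n_interactions:
        attempts += 1
        tf_c = int(rng.choice(tf_concepts))
        tg_c = int(rng.integers(config.n_ortho_groups))
        if (tf_c, tg_c) in seen_pairs:
            continue
        seen_pairs.add((tf_c, tg_c))
        effect = effects[int(rng.choice(3, p=config.effect_mix))]
        support = [sp for sp in sources if rng.random() < 0.5]
        if not support:
            support = [sources[int(rng.integers(len(sources)))]]
        interactions.append((tf_c, tg_c, effect, support))

    # --- expected merged edges (the transfer rule applied directly) -------
    expected: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for tf_c, tg_c, effect, support in interactions:
        if not target_of[tf_c] or not target_of[tg_c]:
            continue
        for tf_t in target_of[tf_c]:
            for tg_t in target_of[tg_c]:
                prov, signs = expected.setdefault((tf_t, tg_t), (set(), set()))
                prov.update(support)
                signs.add(effect)

    def consensus(signs: set[str]) -> str:
        signed = signs - {"unknown"}
        return next(iter(signed)) if len(signed) == 1 else "unknown"

    expected_edges = {
        pair: (frozenset(prov), consensus(signs))
        for pair, (prov, signs) in expected.items()
    }

    # --- motifs: one matrix per target TF gene ----------------------------
    matrix_dir = os.path.join(str(out_dir), "matrices")
    os.makedirs(matrix_dir, exist_ok=True)
    matrix_to_tf: dict[str, str] = {}
    consensus_of_matrix: dict[str, str] = {}
    m = 0
    other = (1.0 - config.consensus_prob) / 3.0
    for tf_c in tf_concepts:
        word = "".join(BASES[int(b)] for b in rng.integers(4, size=W))
        for tf_t in target_of[tf_c]:
            m += 1
            mid = f"M{m:05d}_2.00"
            matrix_to_tf[mid] = tf_t
            consensus_of_matrix[mid] = word
            with open(os.path.join(matrix_dir, f"{mid}.txt"), "w") as fh:
                fh.write("Pos\tA\tC\tG\tT\n")
                for pos, base in enumerate(word, start=1):
                    row = [other] * 4
                    row[BASES.index(base)] = config.consensus_prob
                    fh.write(f"{pos}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")

    tf_of_matrix_inv: dict[str, str] = {}
    for mid, tf in matrix_to_tf.items():
        tf_of_matrix_inv[tf] = mid

    # --- promoters with planted sites -------------------------------------
    promoter_seq: dict[str, list[str]] = {
        g: list("".join(BASES[int(b)] for b in rng.integers(4, size=P)))
        for g in target_genes
    }
    planted: list[tuple[str, str, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in target_genes}
    for (tf_t, tg_t) in sorted(expected_edges):
        mid = tf_of_matrix_inv.get(tf_t)
        if mid is None or rng.random() >= config.plant_rate:
            continue
        word = consensus_of_matrix[mid]
        for _ in range(20):  # find a non-overlapping slot
            off = int(rng.integers(P - W + 1))
            if all(off + W <= lo or off >= hi for lo, hi in occupied[tg_t]):
                promoter_seq[tg_t][off : off + W] = list(word)
                occupied[tg_t].append((off, off + W))
                planted.append((tg_t, mid, off))
                break

    # --- genome FASTA + GFF3 ----------------------------------------------
    genome_fasta = os.path.join(str(out_dir), "genome.fa")
    gff3 = os.path.join(str(out_dir), "genes.gff3")
    L, spacer = config.gene_length, 50
    genes_per_contig = 20
    with open(genome_fasta, "w") as fa, open(gff3, "w") as gff:
        gff.write("##gff-version 3\n")
        for c_start in range(0, len(target_genes), genes_per_contig):
            contig_genes = target_genes[c_start : c_start + genes_per_contig]
            contig_id = f"ctg{c_start // genes_per_contig + 1}"
            parts: list[str] = []
            pos = 0
            for idx, g in enumerate(contig_genes):
                body = "".join(BASES[int(b)] for b in rng.integers(4, size=L))
                prom = "".join(promoter_seq[g])
                strand = "+" if idx % 2 == 0 else "-"
                if strand == "+":
                    parts.append(prom)
                    parts.append(body)
                    start, end = pos + P + 1, pos + P + L
                else:
                    parts.append(body)
                    parts.append(prom.translate(_COMPLEMENT)[::-1])
                    start, end = pos + 1, pos + L
                gff.write(
                    f"{contig_id}\tsynthetic\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={g}\n"
                )
                parts.append("".join(BASES[int(b)] for b in rng.integers(4, size=spacer)))
                pos += P + L + spacer
            seq = "".join(parts)
            fa.write(f">{contig_id} synthetic\n")
            for i in range(0, len(seq), 80):
                fa.write(seq[i : i + 80] + "\n")

    # --- interaction TSVs per source species -------------------------------
    interaction_tsvs: dict[str, str] = {}
    for sp in sources:
        path = os.path.join(str(out_dir), f"interactions_{sp}.tsv")
        interaction_tsvs[sp] = path
        with open(path, "w") as fh:
            fh.write("tf_id\ttg_id\teffect\n")
            for tf_c, tg_c, effect, support in interactions:
                if sp in support:
                    fh.write(f"{src_gene[(sp, tf_c)]}\t{src_gene[(sp, tg_c)]}\t{effect}\n")

    # --- ProteinOrtho-dialect ortholog table --------------------------------
    proteinortho_tsv = os.path.join(str(out_dir), "orthologs.proteinortho.tsv")
    with open(proteinortho_tsv, "w") as fh:
        cols = ["# Species", "Genes", "Alg.-Conn."]
        cols += [f"{config.target_species}.faa"] + [f"{sp}.faa" for sp in sources]
        fh.write("\t".join(cols) + "\n")
        for i in range(config.n_ortho_groups):
            tgt = ",".join(target_of[i]) if target_of[i] else "*"
            row = [str(1 + len(sources)), str(len(target_of[i]) + len(sources)), "1"]
            row.append(tgt)
            row += [src_gene[(sp, i)] for sp in sources]
            fh.write("\t".join(row) + "\n")

    # --- domain + term annotations ------------------------------------------
    domains_tsv = os.path.join(str(out_dir), "domains.tsv")
    tf_targets = {g for c in tf_concepts for g in target_of[c]}
    with open(domains_tsv, "w") as fh:
        fh.write("protein_id\taccession\tsource_db\n")
        for g in target_genes:
            if g in tf_targets:
                acc = _TF_ACCESSIONS[int(rng.integers(len(_TF_ACCESSIONS)))]
                fh.write(f"{g}\t{acc}\tPFAM\n")
            else:
                fh.write(f"{g}\t{_NON_TF_ACCESSION}\tPFAM\n")

    terms_tsv = os.path.join(str(out_dir), "terms.tsv")
    with open(terms_tsv, "w") as fh:
        fh.write("gene_id\tterm\n")
        for g in target_genes:
            term = f"GO:{int(rng.integers(config.n_terms)) + 1:07d}"
            fh.write(f"{g}\t{term}\n")

    matrix_to_tf_tsv = os.path.join(str(out_dir), "matrix_to_tf.tsv")
    with open(matrix_to_tf_tsv, "w") as fh:
        fh.write("matrix_id\ttf_id\n")
        for mid in sorted(matrix_to_tf):
            fh.write(f"{mid}\t{matrix_to_tf[mid]}\n")

    truth = GroundTruth(
        fixture_id=config.fixture_id(),
        target_genes=target_genes,
        expected_edges=expected_edges,
        planted_hits=planted,
        matrix_to_tf=matrix_to_tf,
    )
    return FixtureBundle(
        directory=str(out_dir),
        genome_fasta=genome_fasta,
        gff3=gff3,
        proteinortho_tsv=proteinortho_tsv,
        interaction_tsvs=interaction_tsvs,
        matrix_dir=matrix_dir,
        matrix_to_tf_tsv=matrix_to_tf_tsv,
        domains_tsv=domains_tsv,
        terms_tsv=terms_tsv,
        truth=truth,
        source_species=sources,
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Pipeline-vs-truth comparison on a fixture."""

    edge_precision: float
    edge_recall: float
    edge_f1: float
    provenance_exact: bool
    effect_exact: bool
    planted_hit_recall: float
    n_planted: int
    n_false_hits: int
    false_hit_rate: float | None
    false_hit_rate_ci: tuple[float, float] | None


def evaluate_against_truth(
    edges: list[InferredInteraction],
    hits,
    truth: GroundTruth,
    n_background_positions: int | None = None,
) -> EvaluationReport:
    """Compare pipeline outputs with the fixture's planted ground truth.

    ``edges`` are the merged inferred interactions; ``hits`` the scan hits.
    A planted site is recovered when a hit matches its (gene, matrix,
    offset) on the promoter's + strand.  Hits elsewhere count as false; when
    ``n_background_positions`` (scanned window-strand count net of planted
    sites) is given, the false-hit rate is reported with a 95% Wilson CI.
    """
    gene_set = set(truth.target_genes)
    for e in edges:
        if e.tf_id not in gene_set or e.tg_id not in gene_set:
            raise ValueError(
                f"edge {e.tf_id}->{e.tg_id} references genes outside fixture "
                f"{truth.fixture_id}: mismatched fixture outputs?"
            )
    got = {(e.tf_id, e.tg_id): (e.provenance, e.effect) for e in edges}
    want = truth.expected_edges
    tp = len(got.keys() & want.keys())
    precision = tp / len(got) if got else 1.0
    recall = tp / len(want) if want else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    common = got.keys() & want.keys()
    provenance_exact = all(got[k][0] == want[k][0] for k in common) and got.keys() == want.keys()
    effect_exact = all(got[k][1] == want[k][1] for k in common) and got.keys() == want.keys()

    planted = set(truth.planted_hits)
    hit_keys = {(h.gene_id, h.matrix_id, h.offset, h.strand) for h in hits}
    recovered = sum(1 for (g, mid, off) in planted if (g, mid, off, "+") in hit_keys)
    hit_recall = recovered / len(planted) if planted else 1.0
    # co-ortholog TFs share a motif, so several matrices legitimately match
    # one planted site: false hits are judged by position, not matrix id
    planted_pos = {(g, off) for (g, _mid, off) in planted}
    false_hits = sum(
        1 for (g, _mid, off, s) in hit_keys if not (s == "+" and (g, off) in planted_pos)
    )
    rate = ci = None
    if n_background_positions:
        from statsmodels.stats.proportion import proportion_confint

        rate = false_hits / n_background_positions
        lo, hi = proportion_confint(false_hits, n_background_positions, method="wilson")
        ci = (float(lo), float(hi))
    return EvaluationReport(
        edge_precision=precision,
        edge_recall=recall,
        edge_f1=f1,
        provenance_exact=provenance_exact,
        effect_exact=effect_exact,
        planted_hit_recall=hit_recall,
        n_planted=len(planted),
        n_false_hits=false_hits,
        false_hit_rate=rate,
        false_hit_rate_ci=ci,
    )
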