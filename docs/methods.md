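# Methods

## Regulatory-interaction transfer by orthology

The central assumption is interolog-style conservation of regulation: if TF
*A* regulates gene *B* in a source species, and the target genome carries
orthologs *A′* of *A* and *B′* of *B*, then *A′*→*B′* is a candidate
regulatory interaction. The transfer rule is strict on both sides — an edge
is created **only** when orthologs exist for both the TF and the TG — and
permissive across fan-outs: when a source gene maps to several target
co-orthologs (one ProteinOrtho row, comma-separated cell), the full
cross-product of TF × TG orthologs is emitted. This is a recall-first choice:
co-ortholog resolution is usually impossible without expression data, and the
per-edge provenance keeps every inference traceable.

Edges inferred independently from several source species are merged by
(tf, tg) key:

* **provenance** = union of supporting species;
* **effect** = consensus over the observed signs: a single sign (possibly
  alongside "unknown"s) wins; conflicting signs give "unknown". The consensus
  is computed over the *set* of signs, not by pairwise folding, which would be
  order-dependent ({+, −, +} must give "unknown", not "+").
* **weight** = Σ over provenance of a per-species weight, default 1.0, so the
  default weight is simply the number of supporting species. Phylogeny-aware
  weights can be supplied as a mapping but no default formula is imposed.

Self-regulating edges (tf = tg after transfer) are retained and tallied as
auto-regulations. Curated input tables are cross-validated against a
reference gene list when one is supplied; rows naming unknown genes are
dropped with a warning rather than failing the run.

## TF classification

A protein is a TF when any of its PFAM or InterPro accessions (precomputed by
hmmscan/InterProScan; this package does not run them) belongs to the packaged
DNA-binding-domain family catalog (`data/tf_family_catalog.tsv`, a curated,
editable two-column table covering the major eukaryotic families; the file's
row order fixes the canonical family order). PFAM and InterPro evidence are
unioned. A protein matching several families is counted once per family in
the family × species count matrix, and once under its exact combination label
(e.g. `Zn2Cys6+C2H2_ZF`, families ordered canonically) in a separate combo
table — both views are needed because totals and combinations answer
different questions.

## Promoters

A promoter is the fixed-length window (default 1000 bp, configurable)
immediately upstream of the annotated gene start, strand-aware: for a
+ strand gene with 1-based start *s*, the 0-based half-open genomic slice
[*s*−1−*L*, *s*−1); for a − strand gene with end *e*, the slice [*e*, *e*+*L*)
reverse-complemented. Windows running off a contig are truncated (never
padded) and flagged. Overlap with neighbouring genes is deliberately not
trimmed — the correct trimming policy is organism- and annotation-dependent,
and untrimmed windows keep the definition simple and reproducible. Genes
annotated without strand are treated as + with a warning.

## PWM scanning with exact p-values

CIS-BP frequency matrices (header `Pos A C G T`; frequency dialect only —
counts matrices are rejected rather than silently rescaled) are converted to
log₂-odds against a 0-order background:

    score(b, i) = log2( (p[i][b] + c·q[b]) / ((1 + c)·q[b]) )

with pseudocount fraction c = 0.01 of the background (configurable; c > 0 is
required when the matrix contains zeros). The background is estimated from
the full scanned promoter set by default (+1 pseudocount per base), or
uniform by flag.

Every cell score is quantized to an integer multiple of the granularity
(default 0.001 bits). The null distribution of the window score is then
computed **exactly on that lattice**: starting from a point mass at 0, the
pmf is convolved position-by-position with the four-outcome distribution
{qscore(b,i) with probability q(b)}; the survival function is the suffix sum.
Because the scanner sums the *same* quantized cells, a window's p-value is an
exact lattice lookup — the only approximation in the whole chain is the
initial cell rounding, bounded by width·granularity/2 bits on the score axis
(9 positions × 0.0005 = 0.0045 bits at the defaults). The support cap
(5·10⁷ lattice points) makes pathological granularity choices fail loudly
with a suggestion to coarsen.

Both strands are scanned; windows containing non-ACGT characters are skipped;
overlapping hits are all reported; hits require p ≤ 1e-4 (the per-site
p-value semantics of RSAT matrix-scan's threshold). Binding-site counts are
attached to edges as evidence — an edge with zero predicted sites is kept,
flagged `has_matrix=False` when its TF has no PWM at all.

Calibration: on i.i.d. background sequence the expected hit count is
2·(L−w+1)·p_threshold per promoter. With a width-10 matrix drawn from a flat
Dirichlet the score distribution is dense enough that the attained threshold
tier sits within ~1% of the nominal 1e-4; the acceptance script verifies the
observed/expected ratio on 10⁶ scanned positions.

## Network store

The canonical deliverable is a sorted TSV edge table
(tf, tg, provenance, effect, weight, tfbs_count, has_matrix) that round-trips
exactly. The pipeline additionally writes a single-file SQLite store with six
tables — `gene`, `ortho`, `pwm`, `regulation`, `tfbs_prediction`,
`network_node` — with referential integrity checked on insert (an edge or hit
naming an unknown gene is a hard error naming the orphan id).

## Topology conventions

Published network summaries rarely state their conventions; this package
fixes them explicitly:

* a self-loop contributes 1 to Kin and 1 to Kout, so ΣK = 2E always;
* **average degree** is 2E/N **truncated** (not rounded) to one decimal —
  the only convention consistent with the published value pairs
  (2·21184/5862 = 7.2276 → 7.2 and 2·16775/5528 = 6.0692 → 6.0);
* hub percentage is 100·Kout_max/N truncated to an integer;
* clustering coefficients are computed on the undirected simple projection
  with self-loops removed; nodes of projected degree < 2 get 0;
* betweenness uses all-pairs shortest paths on the directed graph
  (unnormalized); closeness uses harmonic centrality (well defined when the
  digraph is weakly but not strongly connected), scaled by 1/(N−1);
  eigenvector centrality is computed on the undirected projection and
  normalized to unit maximum;
* components are weak (direction ignored), reported descending by size;
* hub ranking is by out-degree, ties broken lexicographically by id.

## Communities and enrichment

Louvain (greedy two-phase modularity maximization: local moves to the
neighbouring community with the highest positive modularity gain until none
remains, then aggregation of communities into super-nodes, repeated) is run
on the **symmetrized** network — directed edges projected onto an undirected
weighted graph with antiparallel weights summed — because Newman–Girvan
modularity is defined for undirected graphs. Resolution is fixed at 1; the
seed fixes the node-visit order, and community ids are relabelled 0-based in
decreasing size order, so partitions are reproducible. The number of
communities found on a real GRN is seed-dependent and should be treated as
such.

Per-community term enrichment is the one-sided hypergeometric upper tail:
for a community holding n annotated genes, k of them carrying a term of total
size K in a universe of N annotated network nodes, p = P(X ≥ k),
X ~ Hypergeom(N, K, n). Benjamini–Hochberg adjustment is applied across the
full (community × term) family, and the term × community matrix of
−log₁₀(adjusted p) is exported as the heatmap data layer. Terms are flat
labels: ontology-graph propagation, if wanted, must be precomputed into the
annotation table.

## Synthetic fixtures

The generator emulates the complete input contract with planted truth:
ortholog concepts (one gene per source species; a target ortholog with
probability 0.8, doubled to two co-orthologs with probability 0.15), 40
curated interactions between 5 TF concepts and random target concepts with a
0.4/0.3/0.3 positive/negative/unknown sign mix, each supported by a random
non-empty subset of the 3 source species; 1000-bp promoters of i.i.d. uniform
sequence; and per-TF motifs of width 9 with per-position consensus
probability 0.97, planted as exact consensus words at recorded,
non-overlapping offsets in 90% of true-edge promoters. At these settings the
planted sites clear p ≤ 1e-4 deterministically (with 0.97-consensus matrices
the 1-mismatch score tier already exceeds 1e-4 in survival, so exactly the
consensus word is called), which makes recall assertions tight without
flakiness. Expected merged edges are derived inside the generator by applying
the transfer rule directly to the tables it just wrote.

What the fixtures do **not** emulate: realistic genome composition (GC skew,
repeats, isochores), annotation errors, degenerate or variable-width motifs,
binding sites on the − strand of promoters, and promoter/gene overlap of
neighbouring genes. Passing fixture tests therefore demonstrates correctness
of the inference machinery, not performance on real genomes.

## Problem sizes and determinism

Default test and acceptance runs use fixtures of 60 ortholog groups
(~50 target genes, 20–30 edges), 10⁶ scanned null positions for calibration,
exhaustive graph-metric oracles over all labelled digraphs on ≤ 4 nodes
(4096 graphs) plus seeded random 5–6-node samples — enumeration of all
6-node digraphs (2³⁰) is not tractable — and 4×25-node planted partitions
for community recovery. All randomness flows from explicit seeds;
regenerating a fixture or rerunning the pipeline with the same config is
byte-identical, which the test suite asserts on SHA-256 digests.

## Known limitations

* Transfer inherits every bias of the curated sources: a TF with no curated
  targets in any source species is invisible, and promiscuous source TFs
  export their promiscuity (the hub structure largely mirrors the sources).
* Cross-product expansion over co-orthologs can inflate edge counts for
  recently duplicated families.
* The 0-order background ignores promoter composition heterogeneity and CpG
  effects; higher-order Markov backgrounds are out of scope.
* Binding-site evidence is per-site and marginal: no cooperative or
  multi-motif model, no scan-level E-value.
* Louvain community counts on large networks are not seed-stable; only the
  modularity value and gross structure should be compared across runs.
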