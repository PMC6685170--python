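# Methods

## Scope and model

phytonet implements the computational arm of a network-pharmacology study as
a deterministic, file-driven pipeline with five stages: pharmacokinetic
screening, dual-score target filtering, disease-gene intersection,
bipartite/PPI network analysis, and hypergeometric over-representation
analysis (ORA). The underlying model is the standard
"drug–compound–target–disease" network view: a multi-compound drug acts
through the union of its ingredients' protein targets, the therapeutically
relevant subset is the intersection of those targets with disease genes, and
the importance of a target is proxied by its connectivity (degree) in the
compound–target and protein–protein interaction graphs.

All analysis stages are deterministic by contract; the only randomness in
the package lives in the synthetic-data generators.

## Screening

Oral bioavailability (OB, percent) and drug-likeness (DL, unitless in
[0, 1]) are treated as precomputed inputs, because the OB predictor used by
the common compound databases is proprietary and no public descriptor table
defines DL exactly. The screen keeps compounds with OB ≥ 30 and DL ≥ 0.18;
both thresholds are inclusive, which is the natural reading of "≥" cutoffs,
and both are configurable. A whitelist retains named compounds regardless of
score (and tolerates missing scores for them only) — this mirrors the common
practice of rescuing well-attested actives that narrowly fail in-silico
ADME.

When a descriptor table is available, DL can be computed as the Tanimoto
coefficient T(A,B) = (A·B)/(|A|²+|B|²−A·B) against a reference profile (the
mean descriptor vector of an approved-drug library). The implementation
accepts real-valued non-negative vectors — the formula is well defined
there and reduces to the Jaccard index on binary vectors; negative
components are rejected because the coefficient then loses its [0, 1] range,
and the all-zero/all-zero case raises rather than silently returning 0.
Which molecular properties constitute the descriptor vector is deliberately
left to the user; the package fixes only the similarity, not the
featurization.

## Target filtering

An interaction is retained when RF ≥ 0.7 and SVM ≥ 0.8 (inclusive). The
score predictors themselves are out of scope — scores arrive as inputs.
Duplicate (compound, target) pairs collapse to the per-channel maximum
before filtering; with a max-collapse, deduplication and filtering commute,
which the test suite asserts. Candidates with zero retained interactions are
reported as orphans and excluded from the networks; connected + orphans
always partitions the candidate set exactly.

## Disease catalogs

Symbol normalization is trim + uppercase only; no alias or nomenclature
resolution is attempted (an extension point, not a hidden dependency).
Catalogs keep their raw entry count alongside the deduplicated symbol set:
real database exports repeat symbols internally, so the merge report
reconciles `sum(raw) − |union| = duplicates removed` rather than pretending
each source was already a set. Intersection with an empty operand raises (it
signals an upstream failure); a genuinely disjoint intersection returns an
empty list with a warning.

## Networks, degrees, hubs

The bipartite compound–target graph is simple by construction; the degree
handshake (each class's degrees sum to |E|) is asserted on every build. The
mean degree of a node class is |E|/|class|.

The PPI graph keeps edges with combined confidence strictly greater than the
cutoff (default 0.4). Confidence dialect is auto-detected: if any score
exceeds 1, the whole table is treated as STRING-style 0–1000 integers and
divided by 1000 (0.4 ↔ 400). Self-loops are removed, duplicate pairs keep
the maximum confidence, and when a node filter (the common-target list) is
given, filter symbols without any retained edge are reported in two
classes — present in the table but entirely below threshold, versus never
present — because the two have different upstream explanations.

Hub rule: with mean degree m = 2E/N on the simple undirected graph, a hub is
a node of degree strictly greater than 2m. One published description of this
rule labels the *threshold* (2m) an "average degree"; the only arithmetic
consistent with the numbers such studies print is m = 2E/N and cutoff 2m,
which is what the code computes and what the hub report states (mean and
threshold are reported separately). Strict inequality was chosen because
reported hub lists characteristically start just above the threshold.
Hub output is sorted by degree descending with alphabetical tie-break, so it
is deterministic and invariant under node relabeling (property-tested).

Exports are SIF (relation `ct` for compound–target, `pp` for PPI) and
GraphML (node attributes `kind`/`degree`, edge attribute `confidence`), with
nodes and edges sorted so output is byte-stable.

## Over-representation analysis

The test is the exact one-sided hypergeometric tail P(X ≥ k) for
X ~ Hypergeom(N, K, n), computed via `scipy.stats.hypergeom.sf(k−1, N, K, n)`
and cross-checked in the test suite against an independent exhaustive
enumeration of all C(N, n) draws for every parameter combination with
N ≤ 12. DAVID-style EASE modifications are intentionally not reproduced:
the exact variant those servers apply is version-bound and undocumented, so
term counts from web services are treated as database artifacts, not
reproduction targets.

The universe defaults to the union of all genes in the collection
(configurable to a genome background). Query genes outside the universe are
dropped before testing and reported, so n is always consistent with N.
Benjamini–Hochberg q-values (via `statsmodels.stats.multitest.multipletests`)
are computed per collection and reported alongside raw p; the default
reporting filter is raw p < α (strict, α = 0.05) with the top k = 15 terms by
ascending p, ties broken by term id — matching the convention of published
top-term bar charts. Sets smaller than `min_set_size` (default 2) are not
tested.

## Synthetic data: what it emulates and what it does not

The generators produce all five inputs with machine-readable ground truth,
one labeled pseudo-random stream per generator (master seed + CRC32 of the
generator label), so identical specs give byte-identical files and adding a
generator never perturbs the others.

Defaults are sized to the scale of a single-herb screen: 200 compounds with
marginal OB/DL pass rates 0.5 and 0.65 (joint ≈ 0.33), 100 targets, true-edge
density 0.21, an orphan fraction of 0.07, a 1000-symbol disease union
containing 70% of the retained targets, a scale-free PPI over the common
targets with 3 planted hubs and 25% of non-hub confidences below 0.4, and
50-set collections over a 1000-symbol universe.

Specific constructions:

* **Compounds** — OB and DL are two-component uniform mixtures across their
  thresholds, so the expected pass fraction at the default cutoffs equals
  the specified fraction exactly; binary descriptor vectors are attached.
* **Interactions** — true edges draw RF ~ Beta(9, 2) and SVM ~ Beta(12, 2)
  (high modes; the joint probability of clearing both cutoffs is recorded in
  the truth file), decoys draw Beta(2, 5). The truth lists the edges that
  actually clear both cutoffs, so filter recall is computable exactly.
* **Disease catalogs** — exactly round(overlap_frac × |targets|) target
  symbols are placed in the union; a stated fraction of the union is shared
  between the two sources to exercise merge deduplication.
* **PPI** — after assigning confidences, planted hubs are re-wired (adding
  high-confidence edges) until each strictly exceeds twice the mean degree
  of the retained graph; the property is enforced by construction, so hub
  recovery is a wiring check, not a statistical one.
* **Gene sets** — the planted set's query overlap is planted_set_effect
  times the expectation nK/N of a random set of equal size. The default
  effect is 4-fold: strong pathway hits in screens of this kind run
  considerably higher (a 22/68 overlap against an 80-gene set in a
  2000-gene universe is ≈ 8-fold), so 4-fold represents a clearly
  enriched but not extreme term.

What the generators do **not** emulate: real chemistry (no structures, no
correlated descriptors), symbol aliasing and curation noise, PPI topology
beyond degree structure (no clustering/community structure), correlation
between a compound's ADME scores and its target count, and GO's DAG
redundancy. Passing the synthetic suite therefore demonstrates pipeline
correctness — filters, set algebra, graph statistics, exact tail
probabilities, determinism — not robustness to the pathologies of real
curation.

A separate deterministic construction (`phytonet.synthetic_study`) builds
study-shaped tables whose summary statistics match a published single-herb
screen exactly (202 compounds → 65 + 2 whitelisted → 67 candidates → 5
orphans; 163-node/1322-edge bipartite network with pinned degrees 40/35 and
58/55/50; 5730- and 153-entry disease lists deduplicating to 5617; a
70-node/571-edge PPI with ten hubs at degrees 34–44; 68 of 72 targets
mapping into a 99-set pathway collection). Degree sequences are realized by
Havel–Hakimi constructions (bipartite and general), the seed only jitters
scores, and every statistic is recomputed from the tables by the normal
pipeline code paths. Note the published disease-list arithmetic (5730 + 153
with union 5617) is only satisfiable if the raw lists contain internal
duplicates — which is why catalogs carry raw counts — and the fixture
realizes it with 166 internal duplicate lines plus 100 cross-source shared
symbols.

## Numerical and procedural choices

* Thresholds: OB/DL/RF/SVM cutoffs inclusive; PPI confidence and the hub
  rule strict; ORA significance strict (p < α). Each choice follows the
  convention its quantity is reported with in the field.
* Tie-breaks: hubs by (degree desc, symbol asc); enrichment by (p asc,
  term_id asc). All outputs sorted for byte-stable reruns.
* Degenerate inputs raise `InputError` rather than returning empty
  artifacts: empty edge lists for network building, all-zero Tanimoto
  vectors, empty intersection operands, a PPI with no edge above threshold,
  a query with no universe overlap.
* The pipeline report is a pydantic model; its JSON schema ships with the
  package (`report_schema.json`) and the report validates against it in the
  test suite. Output files are content-hashed into the report so identical
  inputs provably give identical runs.
* Problem sizes in the validation suite: the exhaustive hypergeometric
  cross-check covers all (N, K, n, k) with N ≤ 12 (≈ 3.7k cases); planted-hub
  recovery uses 20 seeds at 70 nodes; planted-term recovery uses 200
  replicates at 50 sets over a 1000-symbol universe; graph invariants use
  100 random 25-node graphs.

## Known limitations

* No alias/HGNC resolution: symbol case/whitespace variants merge, true
  synonyms do not.
* Degree is the only centrality, by design parity with the screen the
  pipeline models; betweenness/closeness are out of scope.
* ORA treats gene sets as flat (no GO DAG propagation or redundancy
  trimming) and tests each collection independently.
* OB/DL/RF/SVM predictors are not reimplemented; results are conditional on
  the scores supplied.
* Counts derived from live databases (compound inventories, disease-gene
  totals, pathway-term counts) are snapshot-bound; the package reproduces
  the arithmetic on given tables, not the databases themselves.
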