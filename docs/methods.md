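# Methods

## Ontology model

A trait or function ontology is held as a rooted directed acyclic graph of
terms linked by `is_a` edges. Only `is_a` is honoured: obsolete terms and
non-hierarchical relationships (`part_of`, cross-products) are dropped at
parse time, because every downstream computation here — levels, ancestor
closure, descendant queries — reads the DAG as pure parent layering. Load
time validates the invariants once: no duplicate accessions, no dangling
parents, no cycles, every term reaches a root.

**Levels.** A term's level is 1 plus the length of the *shortest* parent
path to any root; roots are level 1. For multi-parent terms the shortest
path is the only deterministic choice consistent with reading the hierarchy
as layers, and it is stable under stanza reordering in the input file. The
maximum depth is data-driven (the bundled plant-TO-style synthetic layout
uses 6 layers under 9 root trait groups; a cap of 7 is accepted since
published level tables run to 7), enforced only when a cap is passed.

**Information content.** `I(t) = −ln P(X = t)` with `P(X = t)` the
annotation frequency `count(t)/total` from a `TermFrequencyTable`. The log
base is natural (nats) — reported IC values scale accordingly. The counting
basis is deliberately the caller's choice (phenotype descriptions, genes, or
name tokens): the table only promises non-negative counts and a positive
total. A zero count raises rather than returning infinity; smoothing is the
caller's decision, not the library's.

**Semantic similarity.** Two Entity–Quality profiles with class sets
`Cl(P)`, `Cl(R)` score `Σ I over the intersection / Σ I over the union`,
which is symmetric, 1 for identical sets, 0 for disjoint ones, and reduces
to an IC ratio for nested sets. When every union member has IC 0 the ratio
is 0/0 and an explicit error is raised.

## TAS curation

Association summary rows are parsed against a schema mapping canonical
fields to the source's column headers (defaulting to the published
30-column layout: `Marker_name, chr_ref, Marker_location, Pvalue,
indel/snp, MAF`, population metadata, reference keys). Rows with an
unparseable position, p-value, or MAF are rejected *with a per-row report*,
never silently dropped.

Coordinates are 1-based inclusive at I/O (GFF3 convention). A marker at
position x links to a gene `[start, end]` at LD cutoff d iff
`start − d ≤ x ≤ end + d`, closed on both sides with the lower bound clamped
at 1 — "within the flanking window" reads inclusive, and a fixed convention
matters more than the choice. Strand is ignored (no strand rule exists for
LD windows); a marker may link to every gene whose window contains it.
Window lookup uses an interval tree; the test suite keeps an O(n·m)
exhaustive pair scan as the independent oracle.

Records enter curation only if `p ≤` a configurable significance gate
(default 1e-5, overridable per study, reported in the run's provenance
record), since each source study applies its own cutoff. A genome-build
mismatch between records and gene models is a hard error — no lift-over.

Trait labels resolve through a curated dictionary on the normalised string
(lower-case, collapsed whitespace). Unseen labels fall back to a semantic
suggestion: the query's name tokens and each candidate term's name tokens
are treated as class sets scored by the IC-weighted similarity above, using
a token-frequency table; the best candidate is suggested iff its score
reaches the threshold (default 0.4) and is flagged `similarity-suggested`,
never silently merged with curated entries. Tokens the frequency table has
never seen get maximal surprisal `−ln(1/(total+1))`, so novel words count
as highly informative rather than being dropped.

Gene-to-term tables keep one evidence row per (link × term) with study,
marker and p-value provenance; counting uses the deduplicated (gene, term)
view, matching how published relationship counts collapse repeated support
across studies. Direct assignments only are counted; propagation to
ancestor terms is available as an explicit query-time flag
(`query_genes_by_trait(..., descendants=True)`), not baked into the table.
The top-fraction filter keeps `ceil(fraction · n)` smallest p-values per
study and retains all ties at the cutoff — never discarding a record as
significant as one kept.

## Enrichment

For a background of N genes, n annotated to a term, and a query of M
background genes with k annotated, the upper-tail p-value is the sum of
hypergeometric masses from k to min(M, n), each computed via log-gamma
binomials — stable at genome scale and equal (within 1e-12) to the
`1 − Σ_{i<k}` form. `p = 1` when `k = 0`; configurations outside the
support have mass 0 by definition, not by error. No mid-p correction.

Terms with n = 0 in the background are skipped, not reported at p = 1
(standard enrichment-tool convention). The background defaults to the
annotation source's full gene universe; a user-supplied background (e.g.
expressed genes) is intersected in. The enriched flag is raw `p < α`
(α = 0.05 by convention); BH q-values are always computed and reported but
flag only on request, to match how such tables are conventionally printed.
Depletion (lower-tail) and ranked (GSEA-style) tests are out of scope.

Cross-source comparison aligns per-source results keyed by (source, term) —
the same accession in two vocabularies stays two rows — and never fuses
p-values across sources.

## FPR simulation

Per replicate, a gene set of the given size is drawn uniformly without
replacement from the annotation background (the enrichment input universe,
not the genome) and enriched at α. Two estimators are implemented and
tagged in the output, because "rate of significant term enrichment" admits
both readings: the default `per_term` (fraction of tested terms with
p < α, averaged over replicates) and `any_hit` (share of replicates with at
least one flagged term). The per-term rate is provably conservative —
`P(p ≤ α) ≤ α` for a discrete upper-tail test — which the suite asserts at
3 Monte-Carlo standard errors; absolute published FPR curves depend on the
real annotation corpora and are not reproduced here. The default grid is
sizes (20, 40, 60, 80, 100, 200, 500, 1000) × 1000 replicates; tests and
the acceptance script run 500 replicates at sizes 20 and 100 against a
100-gene, 10-term toy source, which bounds the Monte-Carlo error below
~1% while keeping a desk-scale run in seconds. One seed controls the full
grid, with per-size substreams spawned deterministically.

## Co-expression and MCL

Pairwise Pearson correlations (product-moment form; ≥3 samples; constant
vectors are an error) are Fisher-transformed `Z = ½ ln((1+r)/(1−r))`,
clipping |r| ≥ 1 to 1 − 1e-12 with a warning. The edge rule is a minimum
|r| (default 0.7) or top-k neighbours; it is an implementation choice,
labelled as such in outputs, since no canonical cutoff exists. Genes with
any missing sample are dropped with a report.

The transition matrix uses |r| edge weights plus unit self-loops, columns
normalised to 1. Self-loops are standard MCL practice (they prevent
period-2 oscillation) and are documented as an addition beyond the printed
inflation formula. Clustering alternates expansion (matrix
self-multiplication) and inflation (entry-wise power then column
renormalisation — `r = 1` is the identity on stochastic matrices, so
module definition requires `r > 1`; the default inflation is 2.0).
Entries below 1e-5 are pruned and columns renormalised each step;
convergence is declared when the largest entry change falls below 1e-6,
capped at 100 iterations (non-convergence returns the best partition with a
flag). Modules are read off the limit matrix's attractors via union-find
over columns, renumbered by smallest member gene — fully deterministic, and
incapable of merging disconnected components. Gene-set-to-module overlap
reuses the enrichment engine with modules as terms; query genes absent from
the network land in an explicit `unassigned` bucket.

## Synthetic fixtures

The generators emit the exact dialects the readers consume (OBO, GFF3, the
30-column association TSV) and are byte-reproducible from (spec, seed).

* **Ontology**: full branching trees under each root (9 roots × 6 levels ×
  branching 2 by default), with ~10% of non-root terms given a second
  parent one level up — exercising DAG handling without disturbing
  shortest-path levels.
* **Association studies**: one study per trait. Markers tagging a causal
  gene are placed inside the gene body with p-values from a point mass at
  1e-8 (a Beta alternative exists for power-style experiments); null
  markers are uniform along the chromosome with p ~ U(0,1), which
  essentially never passes the 1e-5 gate — so the significance gate's
  behaviour is exactly predictable. The truth table is computed by
  exhaustive enumeration over gate-passing markers × genes × cutoffs,
  including genes that merely neighbour a causal one, making recovery
  exactly decidable (sound and complete).
* **Expression**: each module draws a latent N(0,1) sample profile; member
  genes are `latent + σ·noise` with `σ = sqrt(1/ρ − 1)` so the expected
  within-module correlation is exactly ρ (default 0.8, 4 modules × 25
  genes × 40 samples). Modules share no latent factor.

What the fixtures do *not* emulate: genotype-level LD structure, allele
frequencies, correlated markers, realistic p-value inflation, expression
mean–variance relationships, or the scale of real curated corpora
(~10^5 relationships; the fixtures run at ~10^2). Passing tests therefore
demonstrate correctness of the machinery — window arithmetic, deduplication,
test calibration, clustering — not field performance on real GWAS or
RNA-seq compendia.

## Numerical and design notes

* Log-space binomials throughout enrichment; exhaustive-enumeration and
  scipy cross-checks live in the tests, never in the implementation path.
* Tie-break conventions: enrichment results sort by (p, term_id); top-
  fraction ties at the cutoff are all kept; multi-root category assignment
  picks the lexicographically smallest root.
* All thresholds (LD cutoffs, significance gate, α, edge rule, inflation,
  pruning/convergence tolerances) are configuration, not constants, and are
  recorded in each run's `provenance.json`.
* Known limitations: no OBO 1.4 semantics beyond `is_a`; no lift-over
  between genome builds; no soft-thresholding (WGCNA-style) networks; the
  web-service layer of the original platform is out of scope — the CLI is
  the interface.
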