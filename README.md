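# traitlink

Annotating crop genes with **trait ontology (TO)** terms from
association-mapping results, and analysing the resulting gene-to-trait
tables.

Genome-wide association studies report markers — trait-associated sites
(TAS) — significantly linked to a phenotype. Because marker–gene correlation
decays over the linkage-disequilibrium (LD) distance, a significant marker
implicates every gene whose flanking window of ±d kb contains it
(10/25 kb are typical maize cutoffs, 25/50 kb rice). `traitlink` turns
published association summary tables into evidence-bearing gene→TO-term
tables at multiple LD cutoffs, and provides the downstream analyses that
make such tables useful:

* **Ontology handling** — OBO parsing into a validated rooted DAG,
  hierarchical levels (roots = level 1), information content
  `I(t) = −ln P(X = t)` and Entity–Quality profile similarity
  `sim(P,R) = Σ_{x∈Cl(P)∩Cl(R)} I(x) / Σ_{y∈Cl(P)∪Cl(R)} I(y)`.
* **Enrichment** — one hypergeometric engine for any annotation source
  (TO, GO, pathways, co-expression modules): upper-tail
  `p = 1 − Σ_{i<k} C(M,i)·C(N−M,n−i)/C(N,n)`, computed in log-space,
  with BH q-values reported alongside the raw p < α flag.
* **False-positive-rate simulation** — repeated uniform random gene draws
  through the enrichment engine, estimating the FPR per query size.
* **Co-expression modules** — Pearson r → Fisher Z → thresholded network →
  Markov clustering (MCL: expansion `M←M·M` alternating with inflation
  `(Γ_r M)_pq = M_pq^r / Σ_i M_iq^r`), plus gene-set-to-module overlap.
* **Synthetic fixtures** — generators for toy ontologies, gene models,
  association studies with planted causal genes, and expression matrices
  with planted modules, each with an exhaustive ground-truth table.

## Worked example

Generate a planted fixture, build gene-to-term tables at two LD cutoffs, and
cluster the expression matrix:

```sh
traitlink make-fixtures --seed 1 --out demo/fixtures
traitlink build --obo demo/fixtures/ontology.obo --gff demo/fixtures/genes.gff3 \
    --assoc demo/fixtures/association.tsv --dict demo/fixtures/traits.tsv \
    --ld 10,25 --pcut 1e-5 --out demo/build
traitlink coexpress --expr demo/fixtures/expression.tsv --out demo/coexp
```

prints

```
ld=10kb	genes=6	pairs=6	demo/build/gene_to_term_10kb.tsv
ld=25kb	genes=9	pairs=9	demo/build/gene_to_term_25kb.tsv
genes=100	edges=1183	modules=4	converged=True
```

The 6 unique genes / 6 unique gene-to-term pairs recovered at 10 kb grow to
9/9 at 25 kb — the wider window captures genes neighbouring the planted
causal loci, the same monotone pattern curated TO databases show as the LD
cutoff grows. The recovered pairs equal the generator's truth tables
(`demo/fixtures/truth_10kb.tsv`, `truth_25kb.tsv`) exactly. The clustering
run recovers 4 modules on the 100-gene expression fixture — precisely the
planted ones (`expression_labels.tsv`). Each evidence row keeps its
provenance:

```
gene_id	term_id	ld_level_kb	study_id	marker_name	p_value
Gene0008	TO:0000280	10.0	study01	M00001	1e-08
```

`traitlink enrich`, `simulate-fpr` and `query` complete the surface; every
run drops a `provenance.json` (tool version, parameters, config hash) next
to its outputs.

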