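# nclvkit

Comparative genomics and phyletic profiling for giant DNA virus (NCLDV)
genomes — a tested, reusable re-implementation of the classic analysis
pipeline used to compare a newly sequenced giant-virus genome against
reference proteomes: ortholog detection, ORFan/duplicate classification,
gene-position enrichment statistics, synteny detection, codon-usage bias, and
presence/absence ("phyletic") clustering of taxa by gene-family repertoire.

The package is aimed at virologists and molecular evolution researchers who
have protein FASTA files, tabular similarity-search (BLAST outfmt-6) results,
gene coordinate tables and gene-family (COG/NCVOG) membership tables, and who
want the downstream statistics to be reproducible and unit-tested. Every
stage ships with a truth-known synthetic-data generator, so the whole
pipeline can be validated end to end without downloading anything.

## What it computes

* **Reciprocal best hits (RBH).** For proteomes A and B, `(a, b)` is an
  ortholog pair iff `a`'s best hit in B is `b` and `b`'s best hit in A is
  `a`, both at e-value ≤ 10⁻⁵. "Best" = smallest e-value, ties by larger
  bitscore, then lexicographic subject id (fully deterministic).
* **ORFans.** A protein with no reference-database hit at e ≤ 10⁻⁵ is an
  ORFan; an ORFan with a qualifying hit in an environmental (metagenomic)
  database is a meta-ORFan.
* **Duplicated genes.** Connected components (size ≥ 2) of the
  proteome-vs-itself hit graph at e ≤ 10⁻¹⁰.
* **Positional enrichment.** Genes are TERMINAL when their midpoint lies in
  the first or last *W* nucleotides (default *W* = 50 kb) of the sequenced
  fragment, else CENTRAL. For a gene category the 2×2 table
  (category × region) is tested with a two-sided Fisher exact test: with both
  margins fixed, the terminal-category count *a* is hypergeometric and
  p = Σ P(k) over all k with P(k) ≤ P(a), computed with log-factorials.
  Reported rates are `100·a/(a+c)` (% of terminal genes in the category) and
  `100·b/(b+d)` (% of central genes).
* **Synteny.** Runs of ≥ 2 ortholog pairs consecutive in gene *rank* in both
  genomes, in the same (collinear) or exactly reversed (inverted) order;
  pairs are pre-filtered to high-grade orthologs (worse e-value ≤ 10⁻¹⁰⁰).
* **RSCU.** Relative synonymous codon usage,
  `RSCU_j = x_j / ((1/n_i) Σ_{j'} x_{j'})` within each synonymous family of
  the standard genetic code; genome-level values pool counts across genes.
* **Phyletic clustering.** A binary taxa × family matrix (1 iff the taxon
  has ≥ 1 protein in the family), Euclidean distances between rows
  (√Hamming for 0/1 data), deterministic agglomerative clustering
  (single/complete/average linkage; default complete), Newick export,
  dendrogram cutting at k clusters, and discriminant-family extraction
  (families on which a focal taxon disagrees with a strict majority of a
  reference group).

## Worked example

`examples/02_position_enrichment.py` plants a positional bias (category
probability 50% in the terminal 50 kb windows vs 10% in the centre of a
618 kb fragment with 500 genes) and tests for it:

```
$ python examples/02_position_enrichment.py
contingency table      : a=37 b=45 c=42 d=376
category in terminal   : 46.8% of terminal genes
category in centre     : 10.7% of central genes
odds ratio             : 7.36
two-sided exact p      : 1.25e-12
```

The estimated per-region rates recover the planted 50%/10% probabilities and
the exact test rejects positional independence. The other scripts in
`examples/` demonstrate RBH ortholog recovery, phyletic clustering (planted
4-group structure recovered exactly at 2% flip noise), synteny-block
detection (collinear and inverted runs), and RSCU recovery of a planted 3:1
lysine codon bias.

A thin CLI mirrors the library (`nclvkit simulate | rbh | orfans |
duplicates | families | architecture | synteny | phyletics | rscu |
run-all`); `run-all` drives every stage from a YAML config and writes a
manifest with SHA-256 checksums so identical configs and seeds reproduce
byte-identical outputs.

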