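# Methods

This note documents the statistical procedures implemented in `nclvkit`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical choices
that make every result deterministic.

## Homology classification

All hit-table operations consume the 12-column tabular similarity format.
"Best hit" is defined everywhere as the hit with the smallest e-value, ties
broken by larger bitscore, then by lexicographically smallest subject id.
Similarity searches do not document a tie rule, and binary presence data and
synthetic tables hit exact ties routinely; fixing the order makes every
downstream result invariant to input ordering. Where a tool emits several
HSPs for one query/subject pair, `dedupe_best_hsp` collapses them to the
single best record.

Default e-value cutoffs (all overridable through `ThresholdConfig`):

| parameter | default | used for |
|---|---|---|
| `e_rbh` | 1e-5 | RBH pairing, ORFan calls |
| `e_dup` | 1e-10 | duplicated-gene edges (self-search) |
| `e_family` | 1e-3 | COG/NCVOG family assignment |
| `e_synteny_grade` | 1e-100 | high-grade ortholog subset for synteny |
| `min_aln_len`, `min_pid` | 70 aa, 20% | homolog acceptance filter (strict `>`) |

Cutoffs are applied as `evalue <= e_max`; for continuously distributed
e-values this is indistinguishable from a strict inequality.

Duplicated genes are reported as connected components of the qualifying
self-hit graph rather than as raw hit pairs: components give every gene a
stable duplicated/not-duplicated label regardless of how many in-family hits
the search reports, at the cost of chaining (A–B and B–C merge into one
cluster even if A and C share no direct hit). ORFan labels partition the
protein set: HOMOLOG ≻ META_ORFAN ≻ ORFAN in that precedence.

## Positional enrichment

A gene belongs to the TERMINAL region iff its integer midpoint
`⌊(start+end)/2⌋` lies in `[1, W]` or `(L−W, L]`, with `W` = 50,000 nt by
default on the coordinates of the sequenced fragment. Midpoint
classification gives boundary-spanning genes a single unambiguous region;
the boundary is inclusive on the terminal side. Strand is deliberately
ignored — positional analyses of viral genomes pool both strands.

Enrichment of a category is tested with a two-sided Fisher exact test,
implemented directly: conditioning on both margins of the 2×2 table, the
count `a` is hypergeometric; the two-sided p sums P(k) over every k in the
support with `P(k) ≤ P(a)·(1+1e-12)` (the minimum-likelihood rule; the
relative guard absorbs floating-point ties between symmetric tables).
Probabilities are computed from cached log-factorials (`lgamma`), which is
exact to machine precision for any table this package will meet; the test
suite verifies agreement with an independent hypergeometric-enumeration
oracle for every table with total ≤ 40 and with `scipy.stats.fisher_exact`
on larger ones. The conditional exact test was chosen because the gene
counts per region are small (tens); no multiple-testing correction is
applied across category sets — callers compare few categories and raw
p-values are the convention in this analysis.

Rates are reported per region: `rate_terminal = 100·a/(a+c)` is the
percentage of terminal genes carrying the category, `rate_central =
100·b/(b+d)` the same for central genes. Both are always labelled
explicitly; nothing depends on a printing order. A region containing zero
genes makes the rates undefined and is an error rather than a silent NaN.

## Synteny

Synteny is defined on gene ranks (0-based index in coordinate order), not on
nucleotide positions, matching the notion of "successive ORFs" and making
blocks robust to intergenic-length differences. After filtering pairs to
`max(evalue_ab, evalue_ba) ≤ e_max`, retained pairs are sorted by rank in
genome A and scanned left to right: a run extends while the rank-A step is
≤ `gap+1` and the rank-B step has magnitude ≤ `gap+1` with the sign set by
the run's first step. Runs of length ≥ 2 are blocks, labelled collinear or
inverted. Greedy left-to-right growth makes blocks maximal and
non-overlapping in rank A; when an ascending and a descending run share a
boundary pair, the earlier (left) run claims it. `gap` defaults to 0
(strictly consecutive) but is exposed because visual dot-plot methods
tolerate small insertions. Reversing one genome's gene order swaps
collinear and inverted labels but preserves block membership (tested).

## Phyletic profiling

Presence coding is binary by design: a cell is 1 iff the taxon has at least
one protein assigned to the family; copy number is deliberately discarded
(family tables retain it upstream if ever needed). Euclidean distance
between 0/1 rows — the square root of the Hamming distance — is computed via
the Gram-matrix identity and symmetrized exactly.

Agglomerative clustering repeatedly merges the pair of clusters at minimal
linkage distance (single = min, complete = max, average = size-weighted
mean, maintained by Lance–Williams updates); the merge height is that
distance. Exact ties are resolved by the lexicographically smallest leaf
labels of the candidate clusters, and children of every node are ordered by
smallest leaf label, so the tree is a pure function of the distance matrix
regardless of taxon order (tested by permutation). Complete linkage is the
default — the common default of base hierarchical-clustering tools and the
most conservative about chaining on binary data; single and average are
selectable, and any serialized tree records its linkage implicitly through
its heights. Newick branch lengths are parent height minus child height with
leaves at height 0; serialization uses 17 significant digits so parsing
(via dendropy) reconstructs the tree bit-exactly.

`cut_clusters(tree, k)` removes the k−1 highest merges (ties by height,
then smallest leaf label) by repeatedly replacing the highest current root
with its children — valid for any monotone tree. Discriminant extraction
composes two steps: `restrict_to_group` keeps families present in ≥ 1 group
member; `focal_discriminant` then reports families where a strict majority
(> 50% by default) of the group agrees on a value and the focal taxon holds
the opposite one. Ties (e.g. a 2/2 split) are excluded — the family carries
no group consensus to disagree with. Heatmap export orders rows and columns
by the leaf order of clustering each axis (families are clustered on the
transposed matrix).

## Codon usage

RSCU follows the standard definition: a codon's count divided by the mean
count of its synonymous family under genetic code 1 (fixed; both giant
viruses of interest use the standard code). Stop codons are excluded from
families. Families with zero total count are UNDEFINED (`None`) rather
than 0, distinguishing "amino acid unused" from "codon unused". Genome-level
RSCU pools codon counts across genes and applies the formula once — the
standard convention, and the one under which the family-sum identity
(Σ RSCU = family size) holds exactly for the pooled table. Triplets
containing `N` are skipped and tallied, never guessed.

## Synthetic data: what it emulates and what it does not

The generators plant known truth so that every stage has a recoverable
target; all take an explicit seed and use one local PRNG stream
(`numpy.random.default_rng`), so identical calls are byte-identical.

* **Phyletic profiles** — each of `n_groups` groups owns a distinct core
  block of `⌈core_frac·n_families⌉` families (all 1 within the group);
  every cell is then flipped independently with probability `flip_rate`.
  This reproduces the signal structure that makes domain-level clustering
  work (shared within-group repertoire, independent noise) but not the
  nested, tree-like sharing of real gene content, nor correlated
  gain/loss along lineages. Passing recovery tests therefore show the
  clustering machinery is correct, not that four domains exist in any real
  dataset.
* **Annotated genomes** — gene lengths uniform on 300–600 nt, placed
  uniformly without overlap by rejection sampling (resample on collision,
  error after 1000 consecutive failures for one gene). The defaults keep
  placement feasible at the study scale (500 genes on 618 kb ≈ 36% coding
  density); real giant-virus genomes are far denser (~90% coding) and not
  uniformly organized, so the generator calibrates the *test*, not genome
  architecture. The category flag is Bernoulli with probability
  `p_cat_terminal` or `p_cat_central` by midpoint region — exactly the
  independence structure the Fisher test assumes, which is what makes the
  type-I calibration check meaningful.
* **Hit tables** — planted pairs emit mutual hits with e-values log-uniform
  on [1e-150, 1e-20]; each pair is dropped entirely with probability
  `fn_rate`. Decoys emit one-directional background hits log-uniform on
  [1e-4, 1] — deliberately straddling nothing: they sit above the 1e-5
  cutoff, while true hits sit far below, so threshold logic is exercised
  from both sides. With probability `fp_rate` a decoy additionally emits a
  *mutual* spurious hit on [1e-30, 1e-6]; spurious hits are reciprocal
  because a one-directional hit can never create a false RBH pair, and the
  false-positive pathway is the point of the parameter. Bitscores are a
  noisy monotone function of −log₁₀(e); alignment lengths and identities
  are plausible fillers, not modelled quantities.
* **Coding sequences** — codons drawn i.i.d. from a weight vector over the
  61 sense codons (unspecified codons default to weight 1), giving
  closed-form expected RSCU values; no amino-acid composition, codon
  autocorrelation or GC pressure is modelled.

## Problem sizes and defaults used in validation

The packaged validation runs use: 2×2 exact-test sweep over all tables with
total ≤ 40 (~1.4×10⁵ tables) against an enumeration oracle; 200 seeded hit
tables of ≤ 50 proteins per side (fp = fn = 0.1) against a brute-force RBH
oracle; 1000 null genomes (500 genes, 618 kb, 50 kb windows, category rate
0.2 both regions) for type-I calibration and 200 biased genomes (0.5 vs
0.1) for power; 100 seeded 40-taxa × 200-family matrices (core 0.15,
flip 0.02) for group recovery; 100 random synteny instances of ≤ 30 pairs
against an exhaustive run-enumeration oracle. These sizes make the whole
suite run in well under a minute each on one CPU while keeping Monte-Carlo
standard errors far smaller than the asserted bands.

## Known limitations

* The pipeline consumes similarity-search output; it never runs BLAST, and
  results inherit whatever search sensitivity produced the hit tables.
* Family assignment takes the single best qualifying hit; multi-domain
  proteins genuinely belonging to several families are represented only if
  the input table lists them separately.
* The synteny definition is rank-based and greedy; block boundaries may
  differ from visual dot-plot curation at shared boundary genes.
* Hierarchical clustering is O(n³) in pure Python/NumPy — ample for
  dozens-to-hundreds of taxa, not for thousands.
* The dendrogram carries no support values; bootstrap resampling of
  families is out of scope.
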