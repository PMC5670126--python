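# Methods

This note documents the models, conventions and numerical choices behind
`famdyn`, and what the synthetic-data experiments do and do not demonstrate.

## The analysis model

The object of study is the *gene family* (homolog group): a set of proteins
treated as one evolutionary unit. Families are delineated by three routes
that partition the input proteins:

* **KO groups** — proteins whose database top match carries a KEGG Orthology
  term, keyed by that term. Distinct accessions mapping to the same KO merge.
* **UP groups** — remaining matched proteins, keyed by the shared top-match
  accession. Singleton KO/UP groups are permitted: a group's identity comes
  from its anchor, not its size.
* **OM groups** — database-unmatched proteins, clustered on the all-vs-all
  similarity graph by Markov clustering. Only clusters of ≥ 2 members from
  ≥ 2 source datasets are retained; the dataset rule suppresses
  assembly-specific artifacts that recur within a single dataset.

  The retention rule follows the procedure description (≥ 2 of the original
  datasets). The results narrative elsewhere phrases retention as "more than
  one representative in each lineage"; the two are not equivalent, and this
  package implements the procedural (dataset-based) rule.

Downstream, a family's *presence set* is the set of lineages contributing at
least one member, and every classification is a predicate on that set (see
README for the definitions). Ancestral gain/loss reconstruction is out of
scope — only presence patterns are counted. Node-specific sets follow the
subset definition literally: a family confined to {C,F} is specific to every
ancestor whose descendant set contains both leaves, and the root's total and
specific sets coincide.

## Top-hit assignment

Hits are filtered at E ≤ 10⁻¹⁰. The curated pool (Swiss-Prot) takes
precedence over the supplementary pool (TrEMBL) regardless of score: a weak
curated hit beats a strong uncurated one, mirroring a two-stage search in
which the second database is only consulted on a miss. Within a pool, ties
break by higher bitscore, then lower E-value, then lexicographic accession.
When hits tie exactly on (bitscore, E-value) and disagree on KO, the
majority KO wins, then the lexicographically smallest — the source procedure
is silent on this case, so the rule is fixed for determinism.

## MCL

The similarity graph weights each pair by the mean of −log₁₀E over available
directions (one direction suffices; a pair qualifies when its best E-value
is ≤ 10⁻¹⁰; E = 0 is capped at weight 200). MCL then runs per connected
component: self-loops set to the node's maximum incident weight,
column-normalisation, and iterated expansion (matrix square) / inflation
(elementwise power 1.2, renormalise) / pruning (entries < 10⁻⁵ dropped,
renormalise) until the largest entrywise change is < 10⁻⁸ or 200 iterations
(non-convergence returns the current clustering with a warning). Clusters
are the connected components induced by attractor rows of the limit matrix.
The procedure is deterministic; inflation 1.2 is the recommended setting for
deeply diverged sequences, where aggressive inflation would shatter real
families. The original tool chain's ortholog/in-paralog edge classification
is not reproduced — all qualifying edges enter the graph — and resource
schemes are replaced by the fixed pruning threshold, which is equivalent at
the matrix sizes this package targets (components of tens to hundreds of
nodes).

## Contamination schema

The decision tree for annotated groups, in order: (1) keep if no member has
a bacterial top match; (2) keep if any bacterial-hit member has exon count
≥ 2 (genome-backed evidence of eukaryote gene structure); (3) keep if the
bacterial-hit members span ≥ 2 lineages (independent recurrence is more
consistent with a real, possibly laterally transferred gene than with a
contaminated library); (4) otherwise discard. Missing exon data is treated
as no evidence and falls through; "span ≥ 2 lineages" is evaluated on the
bacterial-hit members themselves, not the whole group. Rule (2) precedes
rule (3) following the narrative order of the source procedure. The schema
applies only to KO/UP groups: OM members have no database match, hence no
bacterial flag. Adding multi-exon evidence can only move a group towards
keep (monotonicity), which the tests assert.

## Codon-usage statistics

Full-length CDS are those starting with ATG (alternative starts excluded
for determinism), ending in TAA/TAG/TGA, with length divisible by three and
no internal stop (added requirement; downstream tools assume translatable
CDS). GC3 counts third positions of *all* codons including start and stop
(configurable), since the conventional EMBOSS behaviour is not documented.

The effective number of codons Nc follows Wright:
Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, where F̄ₖ averages the codon
homozygosity F̂ = (nΣpᵢ² − 1)/(n − 1) over the amino acids of each
degeneracy class (2-fold: 9 amino acids; 3-fold: Ile; 4-fold: 5; 6-fold:
Leu/Ser/Arg as their own class). Amino acids with n < 2 observed codons, or
with F̂ ≤ 0 (possible at small n), are excluded from their class mean; a
missing 3-fold class is imputed as (F̄₂ + F̄₄)/2, Wright's recommendation;
any other missing class falls back to the mean of the defined classes. The
result is clamped to [20, 61] — finite samples of perfectly uniform usage
otherwise exceed 61 slightly. Fewer than 100 sense codons triggers a
low-confidence warning but still returns a value.

## Redundancy removal

The CD-HIT contract is reproduced, not its word-filter heuristics:
sequences are visited longest-first (ties: lexicographic id) and each joins
the first representative it matches at ≥ 90% identity, else founds a
cluster. Identity is defined as identical columns of a global alignment
(match +1, mismatch −1, gap open −1, extend −0.5) divided by the shorter
length; a shared-6-mer prescreen (≥ 30% of the shorter sequence's 6-mers)
skips alignments between clearly unrelated pairs. Deduplication is
idempotent and representatives are always a subset of the input.

## Enrichment

The family is the unit of testing throughout; a family carries a GO term or
Pfam domain when any member protein does, and GO sets are closed under
is_a ancestry (true-path rule; part_of is available behind a flag but off by
default for determinism with minimal ontologies). One-sided p-values are
hypergeometric tails (over: P(X ≥ k); under: P(X ≤ k)).

The elim procedure processes terms in decreasing depth (longest path from a
root; ties by term id). A term significant at elim_alpha = 0.01 (the
conventional default for this method — exposed as configuration, since the
source analysis does not state it) has its currently annotated families
removed from all strict ancestors before they are tested. Raw elim p-values
are reported without FDR adjustment, matching the method's convention; with
elim_alpha = 0 the output reduces exactly to classic per-term Fisher tests,
which the suite verifies. GO tests default to over-representation only;
Pfam domains are tested in both directions with Benjamini–Hochberg
adjustment applied separately per direction, and domains absent from the
background are excluded from the number of tests.

## The synthetic study

The generator emulates the statistical structure the analysis assumes, not
the biology of any real dataset. Families originate at tree nodes — a fixed
count at the root (200) plus Poisson(25) gains per branch, giving ≈ 500
expected families on the default 7-leaf topology (P,(A,(E,(D,(B,(C,F))))))
— and are lost per branch with independent probability 0.2; a family's
presence set is where it survives. Defaults mirror the profile of the
motivating study: 24 datasets over 7 lineages (3/7/7/2/1/2 for clades A–F,
2 for the outgroup), ~40% of families with database matches, 12% of
annotated families carrying a KO term, genome-backed datasets for clades A,
B and F, and 20 single-lineage bacterial contaminants (~9% of annotated
groups). Protein lengths are lognormal (median 300 aa); family members
share a 60% sequence core so that cross-dataset members stay below the 90%
dedup threshold while planted fragment duplicates (10% of proteins) exceed
it. CDS are back-translated with synonymous codons biased towards G/C third
positions at a per-lineage rate drawn from U(0.55, 0.75), giving GC3 and Nc
values in realistic, lineage-distinct ranges. Within-family all-vs-all
E-values are log-uniform on [10⁻³⁰, 10⁻¹⁵]; optional noise edges are drawn
above the clustering cutoff ([10⁻⁸, 10⁻²]) so that the default pipeline is
exactly recoverable. All randomness flows from one integer seed; identical
seeds give byte-identical bundles.

What passing recovery tests shows: the pipeline's stages compose correctly
and invert the generative model under its own assumptions (distinct anchors
per family, no cross-family similarity below the cutoff, contaminants
confined to one lineage). What it does not show: robustness to annotation
noise, shared anchors between real paralogous families, fragmented
assemblies, or genuinely ambiguous contaminants — real-data behaviour must
be argued from the per-stage contracts, not from these simulations. The
per-dataset dropout parameter (default 0) exposes observation failure as a
free parameter rather than fitting any real dataset's quality profile.

## Numerical and engineering choices

* Everything is single-threaded and deterministic; outputs are sorted by id
  before writing, so reruns on the same inputs are byte-identical (asserted
  in the suite).
* Reported ratios use decimal half-up rounding at the printed precision.
* Degenerate inputs fail loudly where they indicate a broken contract
  (empty groups, matrix lineages absent from the tree, missing annotations
  in annotated groups) and softly where absence is informative (no CDS →
  skipped with a logged count; empty QC input → NaN metrics).
* Problem sizes in the suite and drivers (≈ 500 families, ≈ 4,000 proteins,
  graphs of ≤ 50 nodes for MCL oracles, 10⁵-row matrices for the set-algebra
  oracle) were chosen as the smallest scales at which every contract is
  exercised meaningfully.

## Known limitations

* No sequence evolution model: synthetic similarity comes from shared
  cores, so alignment-based identity behaves qualitatively, not
  quantitatively, like real homology.
* The OM dataset-retention rule and the contamination schema are applied as
  stated procedures; where the source narrative is ambiguous (see above)
  the procedural reading is implemented and the alternative documented.
* orthAgogue-style edge typing (ortholog/in-paralog) is not implemented;
  for highly paralogous inputs MCL on the untyped graph may merge families
  that edge typing would separate.
* Fisher tests assume exchangeable families; family size and annotation
  density are not modelled as covariates.
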