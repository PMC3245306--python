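# Methods

## The classification problem

*Azospirillum* are plant-growth-promoting rhizobacteria whose closest
relatives (the rest of the family *Rhodospirillaceae*, order
*Rhodospirillales*) are aquatic. A large share of an *Azospirillum*
genome was acquired horizontally during the transition to soil and the
rhizosphere. `azohgt` labels each protein-coding gene **ancestral**
(vertically inherited) or **hgt** (horizontally transferred), with tiered
confidence, purely from the taxonomic composition of the gene's best
database hits: a vertically inherited gene should find family and order
relatives dominating its top BLAST hits; an acquired gene should find
none of them there.

## Neighborhoods

For each query, hits with E-value above the cutoff (default `1e-4`) are
discarded, hits to the query's own species are removed, and only the
first occurrence of each species is kept, preserving BLAST output order.
The file order is trusted and never re-sorted: the rank-based rules are
defined on the search tool's own ordering, and re-sorting with a
tie-break would silently change calls. Deduplication is at binomial
species granularity (strains of one species collapse), matching a
species-non-redundant reference database.

Each retained species is reduced to one membership letter relative to the
focal lineage: `G` another focal-genus genome, `F` a focal-family genome
outside the genus, `O` a focal-order genome outside the family, `X`
anything else. The classifier is a pure function of this letter sequence.

## Rule table and precedence

With defaults (windows in parentheses):

| verdict | rule |
|---|---|
| unassigned | no hits outside the focal genus |
| ancestral-high | ≥ 6 focal-order species in the top 8; short lists: all but 1, with at least one actually present |
| hgt-high | 0 focal-order species in the genus-removed top 10 |
| ancestral-medium | ≥ 4 focal-family species in the top 8 |
| unassigned (conflict) | hgt-medium and ancestral-low hold simultaneously |
| hgt-medium | 0 focal-order species in the genus-removed top 5 |
| ancestral-low | ≥ 1 focal-family species in the genus-removed top 8 |
| hgt-low | 0 focal-family species in the genus-removed top 8 |

Rules are evaluated top to bottom, so stronger evidence always wins. The
order of that list is a design choice — the rules themselves do not fix an
evaluation order — and three further points were genuinely open:

* **Genes hit only by other focal-genus genomes are unassigned**, and this
  check runs before anything else. Without it, a short all-genus list
  would slip through the ancestral-high short-list clause, contradicting
  the explicit definition of the unassigned class.
* **"All but 1" on short lists** is floored at one focal-order species
  actually present (`max(n−1, 1)`); a literal reading would make a single
  unrelated hit "ancestral with high confidence", which inverts the rule's
  intent — a gene whose only hits are distant taxa is the prototypical
  HGT signature.
* **Other focal-genus genomes count toward the ancestral high/medium
  tallies** (they are bona fide family members, and the two rules that do
  exclude them say so explicitly); `count_focal_genus_in_ancestral=False`
  flips this. Genus exclusion removes genus species *before* windowing
  (`genus_exclusion="prefilter"`), so genus hits cannot consume window
  slots and mask distal evidence; `"inwindow"` keeps the slot-consuming
  semantics for comparison.

Mutual-exclusivity caveat: ancestral-low and hgt-low can never both hold
(they read the same genus-removed window for ≥ 1 vs 0 family species).
The high-tier conditions are provably exclusive for full-length windows
when at most two other focal-genus genomes exist (the reference database
shape), but degenerate short lists can satisfy both, e.g. `[G, G, X]`;
precedence resolves those in favor of the ancestral call. The exhaustive
sweep in the test suite covers every such input.

## Downstream summaries

* **COG enrichment**: per one-letter category, a 2×2 table (in-category
  vs not × ancestral vs hgt) tested with a two-sided Fisher exact test and
  Benjamini–Hochberg FDR across categories. The comparison the original
  analysis presents names no test; Fisher + BH is the standard,
  fully reproducible choice and is recorded in output headers. Genes
  without a COG assignment are excluded but counted, never dropped
  silently.
* **Best-hit taxonomy**: for each HGT gene, the first hit that is neither
  the query's own species nor another focal-genus genome, tallied at the
  order (or class/phylum) level. Without the eligibility rule every
  gene's best hit is another *Azospirillum* and the distribution is
  uninformative. Genes with no eligible hit land in an explicit
  `unresolved` bin.
* **16S clock**: with 1–2% 16S rRNA divergence per 50 Myr, an observed
  divergence `d`% brackets the age as `[d/2, d/1] × 50` Myr — the 2%/50 Myr
  rate is the *fast* bound and therefore yields the *minimum* age. The 8%
  family-level divergence used in the worked example gives 200–400 Myr.

## Proteomics

PSM filtering follows the DTASelect convention: XCorr ≥ 1.8/2.5/3.5 for
charge +1/+2/+3 (inclusive minima; charges above +3 use the +3
threshold), ΔCN ≥ 0.08, at least semi-tryptic status, and ≥ 2 distinct
peptide sequences per protein (modification marks stripped before
counting; shared peptides count for every protein — no parsimony
grouping). The reverse-decoy false-positive rate is
`%FP = 2·rev/(rev+real)`, bounded in [0, 200]. Relative abundance is
`NSAF_k = (SpC_k/L_k) / Σ_n (SpC_n/L_n)` with SpC the protein's total
spectral count and L its length in residues; NSAF sums to 1 by
construction and is invariant to uniform scaling of spectral counts.

## Genome statistics and in-silico PCR

GC content excludes ambiguity codes from both numerator and denominator
(stable under N-padding) and is rounded half-even to two decimals. The
protein-coding fraction is reported both as the per-base union of CDS
intervals and as the raw interval-length sum, because the published
definition of "protein coding regions (%)" is not stated; neither value
is treated as canonical. rRNA *operon* counting requires an operon
clustering definition that is not available, so only raw rRNA gene
counts are reported. In-silico PCR finds exact-match primer sites on both
strands (both primer-role orientations), pairs each forward site with
every compatible downstream reverse site within `max_product` (default
10 kb), and reports 1-based inclusive coordinates with primers included.
Degenerate-base primers and mismatches are out of scope.

## Chemotaxis score tables

CheA sequences scored against class-specific models (F5, F7, F8, F9,
ACF, …) and one all-CheA model are assigned the top-scoring class, or
`Unc` when the generic model *strictly* outscores every class model.
Ties between class models break lexicographically with a warning. Model
construction and searching are out of scope; the module consumes a score
table, which makes the decision rule testable without the sequence
database.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical* structure the classifier
assumes, under the study's database shape: a focal family of 8 genomes
(self + 2 other *Azospirillum* + 5 *Magnetospirillum*/*Rhodospirillum*-
type genomes), 4 further order members, and 30 outside species with HGT
donors concentrated in *Rhizobiales* (0.5) and *Burkholderiales* (0.3)
plus a mixed remainder (0.2), reflecting the observed donor spectrum.
Ancestral genes lead with the non-self family species, each retained
with probability ρ (`family_retention`, default 0.9 — homolog detection
is imperfect but rarely misses several relatives at once), then order
members, then a 12-species outside tail. HGT genes lead with a donor-group
species and 11 further outside species, keeping the top 10 clean of
family/order hits; a family homolog may trail beyond rank 12 (acquired
genes can spread within the order later). Each gene's hit list starts
with a self-hit, and species may repeat (strain-level duplicates), so the
self-exclusion and deduplication steps are exercised on every run.
E-values are a deterministic decreasing function of rank: the rules are
rank-based, so only the cutoff matters.

Defaults of `n_genes=1000` and `hgt_fraction=0.5` size one simulated
genome like the real analysis scale (roughly half of resolvable genes
horizontally acquired). What the generator does **not** emulate: sequence
evolution, realistic score/E-value distributions, truncated hit lists,
taxonomic mislabeling, or the ambiguous neighborhoods that produce
medium/low-confidence and conflict calls in real data (those tiers are
exercised by constructed neighborhoods in the unit tests instead).
Passing recovery tests therefore demonstrates correctness of the decision
machinery under the stated generative model, not classifier accuracy on
real BLAST output.

PSM simulation draws pass/fail labels first and generates field values
consistent with them, occasionally exactly at a threshold to pin the
inclusive boundary; genome simulation plants disjoint CDS intervals of
exactly known coverage and one primer pair at recorded coordinates,
verifying that no accidental second binding site exists.

## Problem sizes and numerical choices

The exhaustive rule-engine check enumerates all membership sequences of
length ≤ 10 over `{G, F, O, X}` (1,398,101 sequences) and demands exact
agreement with an independently written, naively literal transcription of
the rules. Recovery experiments use 20 seeds × 1000 genes per injected
HGT fraction; limit cases use 300 genes. Fractions are exact rational
tallies; the only floating tolerances are 1e-9 on the NSAF sum and
two-decimal rounding on percentage outputs. All randomness flows through
`numpy.random.default_rng` seeded from a single integer, so every table
regenerates byte-identically.

## Known limitations

Real-data reproduction of genome-wide ancestry proportions requires the
original ~650-genome reference database and BLAST runs against it, which
are outside this package's scope (it consumes tabular search output).
The deposited *Azospirillum* EMBL records can be fed to
`read_genome_flatfile`/`compute_stats`/`insilico_pcr` unchanged, but are
not bundled; the genome-statistics path is validated on constructed
records instead. Coordinates of `join` locations collapse to the bounding
interval, so interval-union coding fractions slightly overestimate coding
bases for heavily spliced features (rare in bacteria).
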