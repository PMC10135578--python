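# Methods

## The model

The object of study is the matrisome diseasome: a bipartite graph whose one
side is the matrisome gene catalog (the screening universe) and whose other
side is the set of diseases those genes are associated with; edges are
unique (gene, disease) pairs pooled from several record sources.  All
analyses are deterministic set/count operations over this structure — there
is no statistical model fitted anywhere in the pipeline.  P-values consumed
by the PheWAS branch are produced upstream by association studies; the
pipeline only filters and summarizes them.

Identity conventions drive everything downstream, so they are fixed once:
gene symbols are uppercased and trimmed (no alias or synonym resolution;
two spellings of the same gene are two genes), and disease names are
lowercased, trimmed, and internally whitespace-collapsed (no ontology
mapping; merging across sources is by exact normalized name).  Both are
deliberate simplifications: the merging procedure being reproduced pools
sources by name, and surfacing the convention is more honest than silently
applying a reconciliation the sources never had.  Consequence: counts of
"unique diseases" are upper bounds relative to an ontology-reconciled
merge.

## Record readers

Each of the seven inputs is a header-carrying delimited text file (TSV by
default, UTF-8) in a canonical dialect; a `Dialect` column-mapping adapts
real exports.  Readers return `(records, LoadReport)` and the report obeys
`rows_in = records_out + dropped + rejected` — dropped means unusable
(empty key fields) or duplicate, rejected means invalid (bad p-value,
self-interaction, unknown category).  Because "polymorphism" counts are
ambiguous between table rows and distinct variant identifiers, the variant
reader reports both (`polymorphism_rows`, `unique_variant_ids`) instead of
choosing.  PPI pairs are canonicalized with the lexicographically smaller
symbol first, so (A,B) and (B,A) are one pair.

## Protein-change parsing and the substitution matrix

`parse_protein_change` is a total function with tagged outcomes.  Missense
events are single-residue substitutions in either three-letter
(case-insensitive) or one-letter (uppercase) code, with or without the
`p.` prefix and parentheses.  Synonymous (`=` or ref = alt), frameshift,
deletion, duplication, insertion, extension and stop-gain notations are
`not_missense`; stop gain can be counted as missense via a switch, but is
excluded by default because the substitution matrix is defined over
amino-acid substitutions.  Everything else — cDNA notation, unknown residue
codes, free text — is `unparseable`.  Ambiguity codes other than X are
rejected: the analysis targets standard residues.

The substitution matrix is a 22x22 integer grid (20 standard residues in
alphabetical three-letter order, then Xaa, then Ter) with an identically
zero diagonal; its grand total equals the number of missense records
counted.  Rankings sort descending by count with alphabetical tie-breaks so
reports are reproducible.  The default gene filter for the matrix is the
collagen category of the catalog, with an all-matrisome option — the
spectrum of interest is the collagen helix, where the Gly-X-Y constraint
concentrates pathogenic substitutions on glycine.

The triplet-position helper is the closed form
`slot = ((position − helix_start + offset) mod 3) + 1`.  The glycine slot
defaults to 1 (glycine written first in the Gly-X-Y motif) but is
configurable to 3, since the motif is sometimes described with glycine "in
the third position"; the arithmetic is identical up to the offset.

## Disease categorization

Categorization is case-insensitive substring matching of term lists A
(connective-tissue), B (common), C (age-related) against the normalized
disease name — no word boundaries, no stemming, so "cancerous" matches
"cancer"; this is the documented cost of implementing plain substring
matching.  A disease keeps every category it matches (labels `A`, `B_C`,
`A_B_C`, ... or `uncategorized`), so label counts partition the input while
per-category marginals count overlaps in every member.  The shipped default
lists cover only the canonical example diseases of each category and are
user-replaceable via a three-array JSON file; any real analysis should
supply its own curated lists.

## Network and clustering

The diseasome graph types its nodes (`gene::`/`disease::` key prefixes) so
one string can never appear on both sides.  Degree tables satisfy the
handshake identity (either side's degree sum equals the edge count), which
the pipeline re-asserts at report time.

Gene clustering on the collagen sub-diseasome uses average-linkage
agglomerative clustering (scipy) on Jaccard *distance* between disease
neighbor sets, cut so clusters merge while linkage distance ≤ 1 − cut
(default cut 0.5, i.e. similarity ≥ 0.5).  Average linkage was chosen over
single linkage for robustness to chaining; the package also ships an
independent brute-force oracle (pairwise Jaccard threshold + connected
components, equivalent to single linkage) used for cross-checking.  On
well-separated instances — within-cluster similarity comfortably above the
cut, across-cluster at or near zero — the two procedures agree exactly,
which is what the oracle tests exploit; on instances with intermediate
similarities they can legitimately differ, and no equivalence is claimed
there.  Determinism is enforced by sorting genes before building the
distance matrix and renumbering cluster ids by first appearance.

## Repurposing join

One candidate per (drug, target gene) whose gene carries at least one
disease association, holding the union of that gene's diseases.  The join
key is the gene symbol; when a SNP-id map is supplied, a drug link carrying
an rs-number only joins if that SNP is among the gene's known variants
(strict mode), preserving SNP-mediated linkage where the data provide it.
Dropped records (drugs without an associated gene, genes without drugs) are
counted, and `drugs_in = candidates + drugs_without_gene_match` holds.

## Synthetic data and what passing tests mean

The generator emits all seven dialects from one seeded `numpy` stream and
writes a manifest of realized counts obtained by re-scanning the emitted
rows — not expectations — so every counting stage can be compared exactly.
Defaults are the package's standard study conditions: 2000 genes with a 25%
matrisome share, 5000 variant rows (70% missense, 50 planted exact
duplicates), 10000 PheWAS hits with log-uniform p over 10^−12..1 plus 25
invalid rows (p > 1) to exercise rejection, 800 diseases, 3000
associations, 500 rare-disease links, 1000 PPI pairs, 200 drug links.  The
matrisome share is inflated relative to the genome-wide ~5% so that each
stage sees hundreds of matrisome records at desk scale; category
proportions mirror the published 1027-gene matrisome composition
(44/195/35 core; 171/238/344 associated).  The planted substitution
distribution puts 0.6 of its mass on glycine references with Gly→Arg (0.25)
ahead of Asp, Ser and Val, then proline and arginine rows — the qualitative
collagen-helix pattern; missense rows land preferentially on collagen
genes so the collagen-filtered matrix carries the spectrum.  Disease names
embed category terms by controlled insertion, making category ground truth
exact by construction.  Variant-per-disease allocation is 1/rank skewed so
a top disease exists by design.

What the generator does not emulate: linkage disequilibrium, allele
frequencies, realistic gene nomenclature, phenotype ontologies, fuzzy
disease-name variation across sources.  Passing the recovery suite
therefore demonstrates that the pipeline's counting, dedup, parsing, and
graph logic is exact — not that the scientific conclusions transfer to any
particular database snapshot, whose counts depend on version and curation.

The fixture tables for the worked examples (the six Stickler and four
Ullrich collagens, the nine plasminogen-targeting drugs, the five-gene
repurposing list) are materialized from published gene/drug lists; the
repurposing fixture's disease names are synthetic placeholders, since the
source prints genes and drugs but not indications.

## Numerical and edge-case choices

* Percentages are rounded half-up to one decimal (`333/1027 → 32.4`), so
  the full catalog is exactly 100.0 and printed values match conventional
  rounding rather than banker's rounding.
* All significance thresholds use strict `<`; this is the single inequality
  convention everywhere.
* p = 0 rows never reach the analysis (reader rejects p outside (0, 1]), so
  −log10 transforms need no clipping.
* Empty inputs are valid everywhere downstream of the catalog: empty tables
  give empty outputs and all-zero reports, not errors.  An *empty catalog*
  is a configuration error, since annotation against nothing is
  meaningless.
* Ties in every ranking break alphabetically (residues by three-letter
  code, hits by (snp, phenotype)), making all outputs order-independent.

## Problem sizes

The test suite runs the full recovery check at the standard study sizes
above (a single generation plus pipeline run takes a few seconds); unit
tests use a ~10x smaller configuration.  The acceptance script regenerates
the study-size dataset from its `--seed` and re-runs everything from
scratch.

## Known limitations

Exact-name disease identity (no ontology), uppercase-only one-letter
protein codes, no DNA/cDNA-level HGVS parsing, no enrichment statistics on
clusters, and no live database clients — inputs are always local files in
the canonical dialects.
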