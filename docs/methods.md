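# Methods

## Model

The package treats fiber degradation capacity as a bond-accounting problem.
A dietary fiber is reduced to the set of glycosidic bond types its
polysaccharide contains; a GH (EC 3.2.1.\*) or PL (EC 4.2.2.\*) enzyme to the
set of bond types it cleaves. The binary interaction matrix *M* marks every
(enzyme, fiber) pair with a non-empty bond-set intersection, and a sample's
inferred fiber degradation profile is the product of its enzyme-abundance
vector with *M*: each fiber column aggregates the abundances of all enzymes
able to attack at least one of its bonds.

Assumptions worth keeping in mind: (1) presence of a cleaving enzyme gene is
taken as capacity — expression, substrate accessibility, and degradation
synergy are not modeled; (2) all bonds of a fiber are weighted equally and a
single shared bond suffices for an interaction; (3) polymerization degree,
side-chain decoration beyond the annotated bonds, and accessory proteins
(esterases, transporters, binding proteins) are out of scope.

### Bond grammar

Bonds serialize canonically as
`⟨anomeric⟩⟨donor_pos⟩-⟨acceptor_pos⟩:⟨donor⟩-⟨acceptor⟩` (e.g.
`b1-4:Glc-Glc`, `a1-2:Ara-Xyl`). Anomeric configuration is `a`/`b`,
positions are single digits, and sugar codes come from a controlled
vocabulary of 16 monosaccharides (Glc, Fru, Gal, Xyl, Ara, Man, Rha, Fuc,
GlcA, GalA, ManA, GulA, GlcNAc, GalNAc, Rib, Api). Equality of bonds is
equality of canonical strings, which makes the interaction matrix testable
by brute force. The grammar is defined here because bond-level annotations
in the literature are tabulated rather than given a formal syntax.

### Packaged catalogs

The default fiber catalog covers 24 dietary fibers (inulin, levan,
beta-glucan, cellulose, xylan, glucomannan, galactomannan, mannan,
arabinoxylan, galactan, arabinan, arabinogalactan, dextran, chitin,
rhamnogalacturonan, pectin, carrageenan, galactoglucomannan, alginate,
xanthan, xyloglucan, laminaran, gellan, resistant starch), each annotated
with its backbone and principal side-chain bonds from standard
polysaccharide structural chemistry; the companion enzyme catalog annotates
43 GH/PL EC numbers with the bonds their reactions cleave. Fiber variants
that share bond content should be collapsed into one row by the curator
(e.g. galactooligosaccharides of different linkage would be one entry);
variants with different bond sets stay distinct. Both catalogs are plain
TSV so users can extend or replace them; enzymes matching no fiber keep an
all-zero matrix row so profile columns always align. Note that xyloglucan
uses abbreviation `XG` since `Xyl` denotes xylan.

## Profiling pipeline

- **Subsampling**: samples are drawn to a fixed depth (default 4×10⁶ reads)
  uniformly without replacement, seed-deterministic; shallower samples are
  flagged discarded. Paired mates are treated as independent reads.
- **Translated search**: production use expects an external translated
  aligner's 12-column tabular output. The built-in matcher (six-frame
  translation, exact peptide seeds of ≥ 10 aa, ungapped extension) is
  fixture-grade plumbing so tests and simulations need no external binary;
  its score is 2 bits per identical residue and its e-value the standard
  search-space heuristic `E = m·n·2^(−bits)`. These constants are
  documented, not calibrated.
- **Best hit**: per read, hits with e-value ≥ 10 are dropped (strict `<`),
  then highest bitscore wins; ties break by lower e-value, then
  lexicographically smallest accession, so assignment is deterministic.
- **EC aggregation**: reads assigned to a protein with exactly one EC
  increment that EC; reads on multi-EC proteins are discarded and reported
  as an ambiguity fraction rather than split arbitrarily.
- **Low-abundance filter**: a feature is removed when its within-sample
  relative abundance is strictly below 1e-4 in at least 90% of samples.
  One rule serves both enzyme profiles and taxon tables (the two published
  phrasings of the sample-fraction condition differ by a strict/non-strict
  boundary; we adopt "fraction-below ≥ 0.9", configurable). Values at
  exactly the threshold count as present. The filter is idempotent and
  never increases a retained value.
- **Copy-number normalization**: gene counts are divided by gene length
  (aa), and the per-sample normalization variable is the **median** of the
  length-corrected abundances of 76 universal single-copy marker families
  (shipped as a COG-ID list; marker sequences are user-supplied). Dividing
  length-corrected enzyme abundances by this variable yields
  copies-per-genome-like units and is invariant to sequencing depth. The
  alternative reading — taking relative abundance before dividing — only
  rescales every sample by a constant and is intentionally not applied;
  length-correcting both sides makes the statistic a copy-number estimate.
  A zero normalization variable marks the sample unusable.
- **Profile flavors**: both raw filtered counts and the normalized profile
  can be exported and carried through the IFDP product; outputs carry a
  units tag (`counts` / `relative` / `musicc`).

## Statistical layer

- **Volcano tests**: per-feature two-sided Mann-Whitney between two groups;
  fold change is log2 of group means with a pseudocount of half the smallest
  nonzero value (the fold-change definition is otherwise unconstrained);
  BH correction by default, Bonferroni where a contrast is one-vs-rest by
  design (country matrices).
- **PERMANOVA**: pseudo-F on Euclidean distances of principal components.
  All components are retained by default, making the distances equal to
  Euclidean distances of the centered profile (a top-k option exists).
  Restricted permutation schemes implement cluster sampling: labels permuted
  across host species (all samples of a species move together; the label
  must be constant within species) or within phylogeny-class strata. The
  unrestricted mode is cross-checked in the tests against scikit-bio's
  PERMANOVA, which serves as an independent oracle, never as the
  implementation. Permutation p-values use the add-one rule
  `(1 + #{F* ≥ F}) / (1 + n_perm)` and are never zero.
- **Random-forest harness**: repeated holdout (default 500 iterations) with
  class-balanced validation sets of ~40% of the data ("balanced" is read as
  equal per-class validation counts; balanced split proportions are the
  exposed alternative via `val_frac`), default scikit-learn forest, per
  iteration seed `seed_base + i`; reports all validation ROC-AUCs and a
  mean ROC curve. `permute_labels=True` reshuffles labels every iteration,
  which is the harness's own chance-level control.
- **Growth agreement**: for each in vitro no-growth call, agreement means
  the clade's capacity ranks lowest or second lowest for that fiber (rank
  ≤ 2 after average-rank tie handling, ties flagged); for growth calls,
  highest or second highest. Significance from independently permuting each
  fiber's capacities across clades (default 2000 shuffles), add-one p.
- **Country contrasts**: per (country, fiber), Welch's unequal-variance
  t-test of that country against all others pooled (the plain t-test is the
  unexposed alternative), Bonferroni over all country × fiber tests;
  countries with fewer than two samples are excluded with a warning. The
  t-statistic matrix feeds average-linkage hierarchical clustering.
- **Ordination**: PCA (deterministic) and t-SNE (seeded, perplexity capped
  at `(n−1)/3` for small cohorts) as thin wrappers for plotting.

## Synthetic data

The simulator emulates the structure of multi-sample shotgun cohorts:
synthetic proteins with EC labels, reverse-translated with one fixed codon
per amino acid (degeneracy is irrelevant to translated matching), reads at
uniform positions on both strands with independent per-base substitution
errors (a deliberate simplification of platform error models — no quality
profiles, indels, or paired-end structure), and an exact per-read truth
table. What passing tests show is therefore that the pipeline's accounting
and statistics are correct under clean, known-truth conditions; they do not
certify performance on real reads with platform-specific artifacts,
homology between database proteins, or strain-level variation.

The masked-genome experiment assembles a toy genome around GH/PL coding
sequences, replaces those intervals with random sequence verified to share
no ≥ 10-aa peptide seed with the masked proteins, and contrasts hit counts
from reads simulated off the masked versus intact genome; the ratio
estimates the mapping FDR.

## Problem sizes and numerical choices

Desk-scale defaults, chosen to give comfortable statistical resolution:
planted-composition recovery uses 50k reads (binomial SD ≈ 0.002 on a 0.7
proportion); the single-genome copy-number check 40k reads over one GH gene
plus 10 markers (combined SE ≈ 2%, against a 5% check); the masked-genome
contrast 60k reads per arm on a three-gene toy genome; PERMANOVA
calibration 200 null simulations at 199 permutations per mode (the add-one
p-value is then exactly uniform on multiples of 1/200 under the null, so the
nominal 0.05 level is attainable); the RF harness 500 iterations. The
cluster-permutation null uses 12 species × 4 samples so the species-level
permutation space (C(12,6) = 924 label allocations) is rich enough for
p-value resolution at α = 0.05.

Degenerate inputs fail loudly: empty bond sets, duplicate abbreviations or
ECs, all-zero sample rows (relative abundance undefined), profile ECs
missing from the interaction matrix (catalog incompleteness must be
explicit), zero marker coverage, and growth matrices with no tested entries
all raise; single-label permutation strata and tied ranks warn.

## Known limitations

Bond-set intersection ignores how many bonds are shared and whether an
enzyme can reach them in context; the packaged catalogs are a curated
starting point, not an exhaustive survey of DF chemistry; the built-in
matcher is intentionally naive (exact seeds only) and should not be used
for production mapping; 16S-based profiles are not supported; and
genome-level capacities inherit all caveats of annotation completeness.
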