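# fiberdeg

Inferred fiber degradation profiles from shotgun metagenomes.

Dietary fibers (DFs) — plant polysaccharides such as inulin, arabinoxylan,
pectin, or resistant starch — cannot be digested by host enzymes and are
degraded only by gut microbes. `fiberdeg` quantifies, directly from shotgun
metagenomic reads, how well each microbiome sample can degrade each of a
catalog of dietary fibers, and provides the statistical machinery to compare
these capacity profiles across host groups (diet groups, seasons, countries,
host species). It is aimed at microbiome researchers who want a
mechanism-level functional readout instead of (or alongside) taxonomic and
broad functional profiles.

## The model

Every fiber is annotated with the set of glycosidic bond types it contains,
and every glycoside hydrolase (GH, EC 3.2.1.\*) and polysaccharide lyase
(PL, EC 4.2.2.\*) with the set of bonds it can cleave. Bonds use a canonical
token `⟨anomeric⟩⟨donor_pos⟩-⟨acceptor_pos⟩:⟨donor⟩-⟨acceptor⟩`, e.g.
`b1-4:Glc-Glc` for the β-1,4 glucose linkage of cellulose. Combining the two
catalogs gives a binary interaction matrix

&nbsp;&nbsp;&nbsp;&nbsp;*M*<sub>ij</sub> = 1 ⇔ enzyme *i* cleaves a bond present in fiber *j*.

Reads are aligned against a reference database of GH/PL protein sequences
(translated search, best hit with e-value < 10), hits are aggregated by EC
number into the sample's **functional fiber-specific profile** (FFP; reads
hitting proteins with more than one EC annotation are discarded as
ambiguous), low-abundance enzymes are filtered (< 0.01% relative abundance in
≥ 90% of samples), and the **inferred fiber degradation profile** is the
matrix product

&nbsp;&nbsp;&nbsp;&nbsp;IFDP = FFP · *M*,

i.e. each fiber's capacity aggregates the abundances of all enzymes able to
attack it. Optionally the FFP is first normalized into copy-number-like
units by dividing length-corrected gene abundances by the median
length-corrected abundance of universal single-copy marker genes. The same
product applied to a genome's EC copy counts gives genome-level capacities.

The statistical layer includes Shannon diversity, Mann-Whitney volcano
tests with BH correction, PERMANOVA on principal-component distances with
cluster-restricted permutation schemes (labels permuted at the host-species
level, or within phylogeny classes), a repeated-holdout random-forest
prediction harness (class-balanced 40% validation splits), a rank-agreement
permutation test against in vitro growth assays, and one-vs-rest Welch
t-statistic matrices per country with Bonferroni correction.

## Worked example

```bash
python examples/02_reads_to_ifdp.py
```

simulates 10,000 reads from a two-enzyme community (cellulase EC 3.2.1.4 at
70%, xylanase EC 3.2.1.8 at 30%), re-profiles them with the built-in
translated matcher, and multiplies by the packaged 24-fiber interaction
matrix:

```
planted proportions: 3.2.1.4=0.70, 3.2.1.8=0.30
recovered counts: {'3.2.1.4': 6961, '3.2.1.8': 3039}
recovered proportion of 3.2.1.4: 0.696
ambiguous-hit fraction: 0.0000

fiber degradation capacities (nonzero):
BG     6961.0
Cel    6961.0
Xyl    3039.0
AX     3039.0
Xan    6961.0
XG     6961.0
```

The recovered EC proportion (0.696) matches the planted 0.70 within binomial
noise; the cellulase contributes capacity to every β-1,4-glucan-containing
fiber (cellulose, beta-glucan, xyloglucan, xanthan backbone), the xylanase to
the xylan-backbone fibers. The other example scripts cover the interaction
matrix (`01`), two-group comparisons with volcano tests and PERMANOVA
(`03`), validation against in vitro growth data (`04`), and the
masked-genome false-discovery experiment (`05`).

A thin CLI mirrors the library for shell pipelines:

```bash
fiberdeg build-matrix --out matrix.tsv
fiberdeg simulate --n-reads 10000 --seed 1 --out-prefix sim
fiberdeg map --fastq sim.fastq --db-fasta sim.db.fasta \
    --db-metadata sim.db_meta.tsv --out hits.tsv
fiberdeg profile --alignments hits.tsv --db-fasta sim.db.fasta \
    --db-metadata sim.db_meta.tsv --out ffp.tsv
fiberdeg ifdp --profile ffp.tsv --matrix matrix.tsv --out ifdp.tsv
```

Every subcommand writes a JSON manifest (inputs, parameters, seeds, version)
next to its output. In production, replace the built-in matcher with an
external translated aligner and feed its 12-column tabular output to
`profile`.

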