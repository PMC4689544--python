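# Methods

`pollenpipe` characterizes the taxonomic composition of mixed-species pollen
from *non-overlapping* 2 × 300 bp paired-end reads of the nuclear ribosomal
internal transcribed spacers (ITS).  The amplicon is ~900 bp, so the two
reads interrogate the informative 5' of ITS1 and 3' of ITS2 while skipping
the conserved 5.8S in the middle; a pair is treated as a single unit
throughout.  This note documents the model, the parameters that matter, the
numerical choices, and what the synthetic benchmark does and does not show.

## Read QC

Each mate is processed independently, then gated as a pair:

1. **Primer trimming.** Degenerate fusion primers (modified ITS4 initiating
   read 1, modified ITS5a initiating read 2) are expanded combinatorially
   into explicit variants at load time.  Each variant is aligned locally
   (+1 match / −2 mismatch / −2 indel) against the 5' window of the read
   (1.5× primer length — fusion primers can only occur at the read start).
   A hit scoring ≥ 10 removes the full primer span and everything 5' of it.
   The cut is extended to the primer's full length even when the local
   alignment stops a base or two short on a score tie; without this, reads
   with a sequencing error near the primer 3' end retain residual primer
   bases, and because clustering later selects the *longest* scaffold as
   representative, those few over-long reads would preferentially become
   representatives and inject spurious indel columns into every downstream
   identity computation.
2. **Quality trimming** follows the Mott running-sum rule: each base gets
   weight `limit − 10^(−Q/10)` with `limit = 0.05`, and the retained read
   is the maximal-sum contiguous interval (computed via prefix sums).
   Bases with error probability above 0.05 therefore contribute negatively
   and are shed from the ends.
3. **Pair gates.** Both mates must be ≥ 150 bp with ≤ 3 ambiguous bases;
   failure of either mate drops the pair.
4. **Overlap rejection.** Proper fragments are ~900 bp, so mates must not
   overlap.  A gapless offset scan of read 1 against revcomp(read 2)
   (+1/−2, both innie and outie configurations, minimum overlap 10 bp,
   gated by a shared-11-mer seed check) classifies a pair as an improper
   short fragment when any offset scores ≥ 25.  The merge scheme's −3
   indel penalty is kept in the parameter set for configuration fidelity
   but cannot arise in a gapless scan.

Every dropped pair is logged with a reason code; per-stage read-fate counts
are conserved (`pairs_in = pairs_out + Σ dropped`) and written to the run
manifest.

## Scaffolds and masking

A surviving pair becomes a scaffold: `read1 + 30×N + revcomp(read2)`.  The
30-N linker prevents single reads from aligning across the gap while
letting the pair act as one sequence.  Scaffolds with combined informative
length ≥ 520 bp are eligible to seed clustering (shorter pairs add no
information once a longer representative exists).

3' G homopolymers — a sequencing artifact — are removed by DUST-style
masking: 64-bp half-overlapping windows are scored with the normalized
triplet statistic `10 · Σ c_t(c_t−1)/2 / (T−1)` (≈5 on uniform-random
sequence, >300 on a homopolymer); in windows scoring above 20, every
occurrence of a triplet type seen ≥ 5 times is replaced by N.  G runs of
≥ 12 bp are always masked, guaranteeing the motivating artifact is removed
under any window parameterization.  Masked positions are written as N (not
lowercase) so identity computations exclude them automatically; masking is
idempotent.

## OTU picking

Identity between scaffolds is computed piecewise on the read-1 and read-2
segments by global alignment (edlib), counting only columns where neither
side is N, with the denominator the informative length of the *shorter*
scaffold (the CD-HIT convention; the choice matters only for
unequal-length pairs).

1. **Reference binning (divide and conquer).**  The reference database is
   first pre-clustered at 95%.  Each pair is then assigned to the
   reference cluster of its best concordant mapping: both mates must hit
   the same accession (12-mer prefilter, infix alignment, per-mate
   identity ≥ 0.85) in proper orientation with implied insert ≤ 1100 bp.
   The mapping itself is discarded — it only partitions the clustering
   work.  Pairs with no qualifying mapping are set aside.
2. **Greedy clustering at 97%.**  Within each bin, eligible scaffolds are
   visited in order of decreasing combined length (id as tie-break); each
   joins the first representative it matches at ≥ 97%, else founds a new
   cluster.  A shared-12-mer prefilter skips hopeless comparisons without
   affecting the order (at ≥ 97% identity over ≥ 250 bp segments, a shared
   12-mer always exists by pigeonhole).
3. **Recapture.**  Unbinned pairs whose scaffolds match no existing
   representative at 97% are pooled and clustered the same way; new OTUs
   get ids continuing after the existing set.  Chimeric scaffolds
   typically end up here, forming their own (later unassignable) OTUs.
4. **Consensus.**  Pairs are mapped back to representatives and a
   per-column majority consensus is built (ties fall back to the
   representative's base; zero-coverage columns keep it; linker columns
   stay N).  Columns where most covering reads carry a gap become N, so a
   representative-private insertion cannot penalize later mappings.
5. **Counting map.**  Pairs are mapped once more, against the consensuses.
   An OTU is a concordant candidate when both mates align with pooled
   identity ≥ 97%, ≤ 5 gapped columns in total, and insert ≤ 1100 bp; the
   pair maps to the best such OTU (ties to the smallest otu_id).  When no
   OTU satisfies the pair as a whole but each mate individually matches a
   *different* OTU at ≥ 97%, the pair is *discordant* — the paired-read
   chimera filter — and is excluded from counting while still contributing
   to library size.  The "≤ 5 indel positions" gate counts gapped
   alignment columns (not gap openings), pooled across both mates.
6. **Chimera scores.**  Externally computed per-OTU chimera scores
   (UCHIME-style) can be imported; OTUs scoring ≥ 30 are removed, missing
   scores count as 0.  In practice the paired-read discordance filter is
   the stronger lane, which is why the synthetic benchmark runs without a
   score table.

## Paired-read LCA assignment

Each OTU is represented by its two component reads, which are searched
against the reference collection to produce BLAST-style HSP tables
(tabular outfmt-6; a real BLAST run can be substituted for the simulated
tables).  Per read, only the best HSP per accession and the top 25
accessions by bit score are kept.  Accessions whose taxonomy lineage
contains a configured substring (e.g. "environmental sample") or which are
explicitly excluded are removed before assignment.

For each rank from species up through genus, tribe, family and order, each
HSP's taxid is collapsed to that rank via the taxonomy tree, and each
taxon's combined score is the best mate-1 bit score plus the best mate-2
bit score for that taxon (a taxon with support from only one mate keeps
only that mate's score and thus rarely passes — single-read support is
insufficient by construction).  If exactly one taxon has combined score
> 600 *and* within 3% of the best combined score, the OTU is assigned
there and finer ranks stay unassigned; otherwise the rank is undetermined
and the next coarser rank is tried.  "Within 3%" is relative
(`c ≥ 0.97 · best`), which at the 600-bit threshold equals an 18-bit
margin; "> 600" is strict, "within 3%" inclusive.  Mean percent identity
and mean bit score are averaged with equal weight over the winning taxon's
HSPs from both mates.  A `conflict_flag` (instrumentation only, never used
in assignment) marks OTUs whose mates' best matches are in different
families with each mate ≥ 200 bits — the chimera signature.

Post-hoc curation rules (applied in declared order) can rewrite
assignments (`reassign_taxon`), pool indistinguishable species
(`merge_species`), or exclude HSPs (`exclude_accession`,
`exclude_name_substring`); the defaults include none.

## Quantification

A pair contributes one count to (sample, taxon) only when it mapped
concordantly to a single OTU that carries an assignment; discordant pairs
and pairs on unassigned OTUs enter the library size only; OTUs sharing a
taxon are summed.  Taxa with < 50 counts summed over all samples are
dropped (50 exactly is kept) as mapping noise.  Counts-per-million divide
by per-sample library size.

* **Diversity** is the effective species number `exp(Ĥ)` from the
  Chao-Shen coverage-adjusted Shannon entropy on *raw* counts (order
  q = 1): with n reads and f₁ singletons, coverage `C = 1 − f₁/n`
  (`C = 1 − (n−1)/n` when all taxa are singletons, avoiding zero
  coverage), adjusted abundances `p̃ᵢ = C·xᵢ/n`, and
  `Ĥ = Σ −p̃ᵢ ln p̃ᵢ / (1 − (1 − p̃ᵢ)ⁿ)`.
* **Rarefaction** uses the exact hypergeometric expectation
  `E[S_m] = S − Σᵢ C(n−xᵢ, m)/C(n, m)`, evaluated with log-gamma so
  n ~ 10⁵ does not overflow; it is computed on the species-level plant
  counts.
* **Bray-Curtis** dissimilarity (scipy) compares samples on cpm-scaled
  abundances by default (raw counts available via the API).
* **Checklist concordance** compares non-bryophyte species-level
  assignments against a state flora checklist at species and genus level.
  The packaged checklist encodes the study's 60 species-level plant
  assignments (4 bryophytes); its genus-level concordance is 55/56 ≈ 98%.

## Synthetic data

The generator defines the benchmark conditions; it is not tuned per run.

* A balanced rank-labeled taxonomy (default 5 species / 3 genera /
  2 families / 1 order under a Viridiplantae kingdom node) with one
  ~900 bp reference per species, evolved from a shared root core by
  per-branch substitution fractions — species 0.04, genus 0.06, family
  0.10, order 0.15 — so sibling species sit ~7–8% apart, above the 6%
  separation at which 97% OTUs are provably pure.  Templates begin with a
  concrete expansion of the read-1 primer and end with the reverse
  complement of the read-2 primer, so trimmed pairs land at ≈ 530 bp
  combined, matching the real amplicon geometry.
* Reads: read 1 is the 5' 300 bp of the template, read 2 the reverse
  complement of the 3' 300 bp (non-overlapping by construction); per-base
  substitution errors at 0.001 (platform-typical) with constant matching
  Phred qualities.  With probability 0.02, mate 2 is drawn from a
  different, uniformly chosen species — a template-switch chimera at the
  mate boundary, the detectable kind under the paired-read filter;
  intra-read breakpoints are out of scope.
* HSP tables use a monotone bit-score surrogate,
  `bit = 2·matches − 6·(mismatches + indels)`, calibrated so a perfect
  300 bp mate scores ≈ 600 bits (≈ 2 bits/base), which makes the 600-bit
  LCA threshold meaningful in simulation.  It is *not* Karlin-Altschul
  statistics; the LCA depends only on score ordering and the thresholds.
* Every emitted pair has exactly one ground-truth row; all generators are
  deterministic under their seed.

**What passing the benchmark shows — and does not.**  The synthetic data
exercise the full contract (trimming, scaffolding, binning, clustering,
recapture, discordance filtering, LCA roll-up, counting and the summary
statistics) with known truth.  They do not emulate ITS copy-number
variation, amplification bias, length heterogeneity among taxa, chimeras
with intra-read breakpoints, reference-database gaps or mislabeled
accessions — the phenomena that drive species-level error on real data.
Recovery and purity figures from the benchmark are therefore statements
about algorithmic correctness, not expected field performance.

## Problem sizes and runtimes

The standard benchmark runs 3 samples × 20,000 pairs (end-to-end recovery,
purity, chimera exclusion; ~4 minutes on one CPU) and 2 mixtures × 5
replicates × 2,000 pairs (replicate structure, ~1 minute); the LCA oracle
sweep uses 500 random tables and the rarefaction check a 100,000-draw
Monte-Carlo oracle.  These sizes were chosen as the smallest at which the
binomial noise on the reported rates is negligible relative to the margins
being checked.

## Known limitations

* The binning and mapping steps are contract-equivalent reimplementations
  of short-read mappers (k-mer prefilter + edlib alignment), not
  FM-index search; for very large reference databases an external mapper's
  coordinate-sorted output is the better route (intermediates are plain
  standard formats precisely so stages can be swapped).
* UCHIME scoring is not reimplemented; only threshold application to an
  imported score table is supported.
* The Mott trimmer and the DUST masker follow the standard published
  semantics, not any particular proprietary tool's byte behavior; mdust's
  window/threshold defaults vary by release, so both are configurable.
* Identity denominators (vs-shorter-sequence) and the pooled-across-mates
  97% mapping identity are documented choices; a per-mate identity switch
  exists in `MapParams`.
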