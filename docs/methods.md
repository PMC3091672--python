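# Methods

This note documents the statistical procedures, numerical conventions
and design choices of the package, and what the synthetic-data generator
does and does not emulate.

## Experimental design and data model

A SuperSAGE experiment counts 26-bp transcript-identifier tags: the
3'-most NlaIII site (`CATG`) of an mRNA anchors a tag consisting of the
anchor plus the next 22 nt.  Tags are serialized and printed in their
22-nt form (anchor stripped); internally the anchor is always
re-attached for mapping.  Libraries are sequenced as *ditags* — two tags
joined tail-to-tail, the downstream one reverse-complemented — flanked
by library-identifying linkers, and counted per library into a tag ×
library matrix.  The motivating design has five libraries: control and
low-calcium water at 2 h and 12 h after transfer, and high-calcium water
at 12 h (roles `C2h, LowCa2h, C12h, HighCa12h, LowCa12h`).  Libraries
are pooled RNA, so there is no replicate-level variance model: every
test operates on tag proportions within library totals.

## Quality control and tag extraction

A read passes QC only if exactly one library's linker matches fully at
both ends, the interior contains no linker sequence of any library and
no character outside `ACGT`, and no byte-identical read was already seen
in the same library (later copies are flagged `duplicate`; the first
occurrence is kept).  Duplicate detection is exact, same-orientation
full-sequence identity — the simplest testable reading of
duplicated-ditag removal; cross-orientation deduplication is not
performed.  Passing interiors must be exactly one tag (26 nt) or one
ditag (52 nt); the downstream tag is reverse-complemented back to the
sense strand and both tags must begin with `CATG`, otherwise the read is
rejected and tallied.  Shorter fragments are rejected rather than
salvaged: tags are fixed-length keys and no error correction or
SNP-collapsing is attempted, consistent with the perfect-match
annotation policy below.

Per-library summaries count *unitags* (distinct tags with count ≥ 1)
in the abundance bins 1, 2–4, 5–9, 10–100 and >100 copies (bins
partition the positive integers; "10 to 100" is read as inclusive).
Percentages are rounded half away from zero to one decimal, the
convention of the printed summary tables.

## Differential expression

**Z-test.**  The pairwise test between two libraries is the classical
SAGE two-proportion z-test (Kal et al. style):
`z = (c₁/n₁ − c₂/n₂) / sqrt(p₀(1−p₀)(1/n₁+1/n₂))` with
`p₀ = (c₁+c₂)/(n₁+n₂)`, evaluated two-sided against the standard
normal.  Whether the original analyses were one- or two-sided is not
specified by the sources describing this test family; two-sided is the
conservative choice.  The degenerate case `c₁ = c₂ = 0` is defined as
`z = 0, p = 1`.

**Replicated G-test.**  For a design whose libraries are partitioned
into groups (e.g. control vs challenge), the tag's 2 × L table (tag
count vs all-other-tags count per library) yields the likelihood-ratio
statistic `G_total = 2 Σ O ln(O/E)` (df `L−1`).  Pooling libraries
within groups gives `G_pooled` (df `groups−1`, the between-group
effect); the within-group tables give `G_heterogeneity`
(df `L−groups`, replicate inconsistency).  Because all three are
likelihood-ratio statistics of nested partitions of the same table, the
identity `G_total = G_pooled + G_heterogeneity` holds to machine
precision and is asserted in the tests.  No Williams or continuity
correction is applied.  Zero tag counts are replaced by the
zero-substitution constant (below) before expected frequencies are
formed, consistently in all three components, which preserves the
identity exactly.

The four designs over the five roles are: (1) control vs low-calcium
pooling both time points per group; (2) 2 h vs 12 h pooling treatment
with control within each time; (3) the three 12 h libraries as three
singleton groups; (4) control 12 h vs the two challenged 12 h libraries.
A design "passes all rules" when `G_total` and `G_pooled` are
significant and `G_heterogeneity` is not (groups behave consistently);
"intrinsic" significance means `G_total` alone.  The exact decision-rule
set of the original G-test software is not published; this decomposition
is the standard replicated-goodness-of-fit reading and is isolated
behind explicit result flags (`pass_all_rules`, `pass_intrinsic`,
`fail_homogeneity`) so an alternative rule set can be swapped in.

**Four classes.**  At α = 0.05 per test:

1. *global low-calcium effect*: design 1 passes all rules and the
   pooled control-vs-low-calcium Z-test is significant (the per-class
   Z-test is pooled over time points because the class is defined as
   time-independent);
2. *time-dependent low-calcium effect*: designs 1 and 2 pass intrinsically,
   design 1 fails some other rule, design 2 fails homogeneity, and a
   per-time-point Z-test confirms the effect at 2 h or 12 h;
3. *high-calcium effect at 12 h*: design 3 passes all rules and the
   control-vs-high-calcium 12 h Z-test is significant;
4. *global challenge effect at 12 h*: design 4 passes all rules and a
   control-vs-challenge 12 h Z-test is significant.

A tag is *retained* when it falls in at least one class **and** at least
one per-challenge expression ratio reaches 2-fold.  No multiple-testing
correction is applied across tags: stringency comes from the conjunction
of tests plus the fold filter (FDR control appears only in GO
enrichment).  Under the full synthetic null at study-scale depths the
classifier retains ≈ 0.4 % of tags.

**Zero substitution and fold change.**  Zero counts are replaced by the
constant **0.345** (the value estimated by the original G-test software;
its quoted ±0.03 standard error is metadata only and never enters any
computation; the constant is configurable).  The expression ratio is the
raw count ratio `R = treatment'/control'` after substitution — library
sizes are deliberately not normalised out, matching the published fold
values — and the reported fold is the nearest integer (half away from
zero) of `max(R, 1/R)`.  This reproduces all sixty checkable published
fold entries, including every zero-substitution case, e.g.
`(0, 38) → 110` and `(21, 0) → 61`.

**Gene-level aggregation and platform concordance.**  Tag counts of
tags annotated to the same gene are summed per library (the cumulative
SuperSAGE signal used when validating against qPCR); Pearson correlation
between log₂ fold changes of the two platforms quantifies concordance.

## Annotation

At 26/26 stringency a BLASTN search restricted to perfect matches is
equivalent, by definition, to exact substring search; the package
therefore uses an exact k-mer index over each reference collection
(both strands; reference positions containing ambiguity codes never
match), which makes mapping bit-reproducible and is verified against a
naive substring-scan oracle.  The reduced 24/24 mode matches the
5'-most 24 nt, i.e. trims from the 3' end — sequencing errors and SNPs
are assumed distal to the anchor; the sources do not specify which 24
of 26 nt were kept.  Coordinates are 0-based half-open internally.

For genomic hits, the 1000 bp 5' of the tag site is extracted
strand-aware (reverse-complemented for minus-strand hits, truncated at
sequence boundaries with the actual length recorded) and identified by
the stable id `chrom:start-end:strand`, which is also the lookup key of
genome-derived rows in the protein-mapping table.

Protein identity comes from a precomputed BLASTX-style table (translated
search itself is out of scope and consumed as an input contract): the
first dataset in the order curated cDNA > predicted cDNA > genome
fragment with a row at E < 1e-5 wins; ties break by lowest E, then
lexicographic protein id (the original tie-break among equally good
matches is unpublished; this one is deterministic).  GO terms transfer
only from rows at E < 1e-10.  A tag is `annotated_protein`,
`anonymous_dna` (DNA hit, no qualifying protein) or `unannotated`.
Antisense flags are raised when the tag-to-DNA strand and the
DNA-to-protein orientation disagree — an inverted match to a sense cDNA
or a direct match to an antisense cDNA.  Tags hitting more than one
distinct genomic location are annotated but flagged ambiguous and
excluded from gene-level aggregation.

## Clustering

Tags are clustered by expression pattern within an analysis-specific
library subset: the *LowCa analysis* uses the four control/low-calcium
libraries and drops retained tags significant only for the high-calcium
challenge or with all-zero counts over those libraries; the *12 h
analysis* uses the three 12 h libraries and drops tags all-zero there.
Profiles are normalised so each tag's values sum to 100 %.

`TransChisqKMeans` is a scikit-learn-style estimator (`fit`,
`predict`, `labels_`, `cluster_centers_`, `inertia_`).  The divergence
of a tag with count vector x (total n, profile p = x/n) from a centroid
with profile shape m is the Pearson chi-square statistic of x against
expected counts n·m, computed as `n (Σⱼ pⱼ²/mⱼ − 1)`; centroid shapes
are floored at 1e-10 and renormalised so the divergence stays finite.
Centroids are updated as the mean of member profiles (consistent with
plotted mean ± SEM cluster patterns); initialisation samples K distinct
profiles without replacement; assignment ties break to the lowest
cluster index; empty clusters are re-seeded with the farthest point.
The published chi-square clustering algorithm's exact objective is not
reproduced in the motivating article, so the divergence sits behind a
pluggable `metric` parameter with plain Euclidean distance on
normalised profiles as the documented alternative.

The number of clusters is selected by the Gap statistic:
`Gap(K) = E*[log W_K(ref)] − log W_K(data)` with reference datasets
drawn uniformly over the per-feature range of the data (floored at a
small positive value so the divergence stays defined), and the standard
one-standard-error rule (smallest K with `Gap(K) ≥ Gap(K+1) −
s_{K+1}`).  Degenerate data with zero dispersion selects K = 1.  On six
well-separated planted patterns (~1,200 tags, five libraries) the
partition itself is recovered essentially perfectly (ARI = 1); the
selected K concentrates on 6 with occasional one-off selections at 5
or 7, the known finite-sample variability of the one-standard-error
rule under a Monte Carlo reference.

## GO enrichment

The background for a tag list is every tag expressed (count ≥ 1) in the
control libraries of the relevant time scope (2 h + 12 h for the LowCa
analysis, 12 h only for the 12 h analysis), carrying the GO sets built
from E < 1e-10 protein rows.  The counting unit is the tag, not the
gene, and terms are tested exactly as annotated — no GO-graph ancestor
propagation, matching direct term retrieval from hits.  Each term
present in the list or background is tested with a pooled one-tailed
two-proportion z-test toward enrichment (an exact binomial variant at
the background rate is available behind `method="binom"`; the two agree
within 10 % relative p where the normal approximation is valid —
background much larger than the list and expected term counts well away
from 0).  Benjamini–Hochberg adjustment spans all terms of one run, and
a term is enriched at adjusted p < 0.01 with the list proportion above
the background proportion.

## Synthetic data

The generator is the package's test bed and defines the study
conditions:

* **Scale.**  Five libraries with the observed depths (65,378; 87,388;
  67,996; 60,142; 63,471 tags).  Transcript abundances follow a
  discretised log-normal law (shape σ = 2.6 over 600,000 transcripts),
  calibrated so that at these depths a library shows ≈ 68 % singleton
  unitags and ≈ 39 % unitags-per-tag — the published regime.  Counts
  are multinomial draws per library, so column totals equal the
  configured depths exactly.
* **Planted differential expression.**  A configurable fraction
  (default 0.2 %) of transcripts is planted as DE in one of the four
  classes (default mix 40/20/20/20) with folds drawn from a
  configurable range and random direction; class-2 effects hit exactly
  one randomly chosen time point.  Planted baselines are drawn
  log-uniformly over expected counts of roughly 7–140 at study depth —
  the count range spanned by the strongest published regulated tags —
  so a planted fold is in principle observable; detection power, not
  the generator, then determines recovery.
* **References.**  Every mappable transcript becomes a cDNA-like
  sequence ending in its 26-nt tag (the tag's `CATG` is the 3'-most
  anchor); antisense transcripts are stored reverse-complemented so
  their tag maps to the minus strand of a sense cDNA.  Transcripts are
  split between curated-cDNA, predicted-cDNA and genome-only placement
  (default 45/20/35), and the genome embeds every cDNA between random
  flanks, exercising the dataset hierarchy; a configurable 35 % of
  transcripts are unmappable (absent from all collections) and 57 % of
  mappable ones carry a protein row with log-uniform E-values and GO
  terms from a synthetic vocabulary.  All genes are emitted on the plus
  strand of their stored sequence; antisense arises from minus-strand
  tag hits.
* **Reads.**  Clean reads are `linker + tagA + revcomp(tagB) + linker`
  with tags paired uniformly within a library; an odd leftover tag is
  emitted as a single-tag read so every count is conserved.  Pairings
  are repaired (by partner swaps) so that no two clean ditags are
  byte-identical and no interior accidentally contains a linker —
  otherwise QC would deduplicate or reject genuine counts; exact
  round-tripping therefore requires tag diversity sufficient for
  distinct pairings, which holds at the scales used in the tests.
  Corrupted reads are appended on top at configured rates — duplicated
  ditags (default 0.55), truncated leading linkers (0.12), internal
  linker insertions (0.05) and ambiguous bases (0.05), chosen so that
  ≈ 57 % of reads survive QC, the published extraction yield — each
  flagged with the QC class that should reject it.  Per-base
  substitution errors (default 0.001) model residual miscalls; with all
  rates zero, extraction reproduces the generating matrix exactly.
* **Not emulated.**  Flowgram/quality-score structure, PCR amplification
  bias, indels, homopolymer errors, SNP haplotypes, alternative
  polyadenylation and genuine GO-term correlation structure.  Passing
  tests on this generator therefore demonstrate correctness of the
  statistical machinery and bookkeeping under the stated sampling
  model, not robustness to every artefact of real pyrosequencing data.

Reference generation loops per transcript and is intended for
configurations of a few thousand transcripts; count-matrix generation is
vectorised and runs at the full 600,000-transcript default in seconds.

## Problem sizes used in the test suite

Exact worked-example checks run on the printed count pairs themselves.
Stochastic checks scale the simulations to keep the suite fast while
preserving the regime of interest: classifier calibration runs on the
full default null (≈ 75,000 observed tags at study depths); planted-DE
recovery uses five seeds of 5,000 transcripts at 70,000-tag depth;
annotation truth-agreement uses 400 transcripts with references;
clustering recovery uses twenty seeds of ~1,200 planted profiles; the
read round trip uses 20,000 transcripts at 8,000-tag depth.

## Known limitations

* The G-test decision-rule set and the chi-square clustering objective
  are documented interpretations of unpublished software; both are
  isolated behind flags/parameters so alternatives can be swapped in.
* The two-proportion z-tests are asymptotic; at singleton-level counts
  their size is slightly conservative (empirically 0.045–0.05 at
  α = 0.05 across the abundance range).
* Gap-statistic selection inherits Monte Carlo variability from the
  uniform reference; one-off selections adjacent to the true K occur.
* The annotation index holds every reference k-mer in memory; it is
  sized for cDNA collections and synthetic genomes, not multi-gigabase
  assemblies.
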