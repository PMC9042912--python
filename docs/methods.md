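# Methods

## The attribution procedure

The unit of analysis is the called peak (open chromatin region, OCR),
held in 0-based half-open coordinates. Two peaks overlap when they
share at least `min_overlap` bases on the same chromosome (default 1,
the bedtools convention; the original analyses' overlap fraction is
not recoverable, so the minimum is configurable). Peaks are unstranded
throughout.

Pre-processing per condition: (i) the IDR filter keeps peaks with
IDR ≤ 0.05, boundary inclusive; (ii) replicate reproducibility keeps
peaks of replicate 1 supported by ≥1 overlapping peak of replicate 2,
widening each kept peak to the extreme start/stop over itself and its
supporters (for >2 replicates the operation folds left); (iii) the
redundancy filter drops exact duplicates and merges any mutually
overlapping peaks within a set into their union span. "Redundant" is
not defined beyond the coordinate-adjustment rule, so the merge is
applied to *all* intra-set overlaps; this yields a well-defined
non-overlapping master list and makes the filter idempotent.

Level 1 forms the four symmetric differences A, B, X, Y under the
overlap relation (see README). "Unique peaks between" two sets is read
as the *symmetric* difference, both directions kept with provenance:
the phrasing is directionless, and only this reading makes the level-2
overlap of A with B capture TCR-driven changes in both IL-2
backgrounds. Level 2 produces:

* TCR-controlled OCRs: peaks of A overlapping B plus peaks of B
  overlapping A, merged and redundancy-filtered;
* IL-2-controlled OCRs: the same on X and Y;
* synergy OCRs: A ⊖ B and X ⊖ Y, one list per branch.

Synergy is deliberately computed per branch. On clean data the two
branches list the same loci (presence pattern (1,0,0,0): open only
with strong TCR and intact IL-2); their gene-set agreement (Jaccard
plus both directional fractions) is reported as the *branch
consistency* diagnostic. When both branches are empty the consistency
is defined as 1 with a warning.

Category percentages are reported against two labelled denominators —
the branch total (conserved + unique within that comparison branch)
and the grand master total (TCR + IL-2 + that row's synergy branch) —
because neither denominator is canonical.

## Annotation

Feature classes use precedence promoter > exonic > intronic >
intergenic. The promoter window is ±h around the TSS (default
h = 3000), closed at both ends: internally [tss − h, tss + h + 1), so
a peak starting exactly at tss + h is promoter and one ending exactly
at tss − h is not. The TSS of a minus-strand gene is `end − 1` (the
last covered base under half-open coordinates). Gene assignment always
minimises |peak.start − TSS| among the genes satisfying the winning
class — distance from the peak *start* is the stated rule for
intergenic peaks and is applied uniformly; a summit-based variant is
not used because summits are optional in the inputs. Equidistant ties
break to the lexicographically smaller gene_id (deterministic and
seed-free). Reported distances are signed and strand-adjusted so
upstream is negative.

## Enrichment statistics

Over-representation of a query gene list in a term with K of N
universe genes, n drawn and k hits, is the upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n) (scipy's survival function),
with fold (k/n)/(K/N). The BH family is every term with ≥1 universe
gene; rows are reported for terms with ≥1 hit. The universe defaults
to all genes of the annotation. "No significant term" is an ordinary,
reported outcome. The default significance threshold is q ≤ 0.05.

## Motif scanning

Sites are scored as Σᵢ log2(pᵢ(letter)/bg(letter)). Motif
probabilities are regularised with pseudocount 0.01 ((p + c)/(1 + 4c))
to avoid −∞ scores; the background defaults to uniform 0.25.

Exact p-values use a dynamic program over a discretised score lattice:
per-position log-odds are rounded to multiples of the resolution
(default 1e-3 bits) and the null distribution of the lattice sum under
the i.i.d. background is convolved position by position. A float score
is mapped onto the lattice with a slack of one lattice unit per motif
position, making the reported p-value conservative and exact up to a
discretisation tolerance of about (2w + 1)·resolution in score — the
test suite brackets the DP against exhaustive k-mer enumeration at
exactly that tolerance.

Both strands are scanned; reverse-strand sites are scored with the
reverse-complement matrix and share the forward null distribution,
which is exact whenever the background is strand-symmetric (the
uniform default is). Windows containing letters outside ACGT are
skipped. Overlapping peaks are merged to their extreme coordinates
before scanning. The default hit threshold is p ≤ 1e-4, the
convention of FIMO-style scanners.

Per-category enrichment treats a peak as "having" a motif when ≥1 hit
overlaps it (presence/absence, the known-motif convention), and tests
category peaks against a background peak set with the hypergeometric
upper tail; BH runs across the whole motif × category matrix. The
signed cell statistic is log2 of lightly smoothed hit rates,
((k+0.5)/(n+1)) / ((k_bg+0.5)/(n_bg+1)). Categories with zero peaks
yield NaN cells with a warning, never fabricated values.

The TF-segregation step runs PCA (numpy SVD) on the column-centred
categories × motifs enrichment matrix; with three categories the
centred matrix has rank ≤ 2, so the default rank-2 reconstruction is
exact and each motif's assigned category is the argmax of its centred
enrichment. The reported linear-model heatmap this step stands in for
is not reconstructable from its description; PCA plus max-loading
assignment is this package's documented choice.

## Similarity

"Overlapping peaks across conditions" is read in the strictest sense:
consensus regions are overlap-connected components of the pooled peaks
that contain ≥1 peak from *every* sample, merged to their union span —
this guarantees every sample has a defined score per consensus peak.
Per-peak sample scores are user-supplied (read quantification is out
of scope); similarity is the Pearson correlation, and the network edge
length is 1 − r. Constant score vectors are an error naming the
sample.

## The synthetic generator

The generator emulates the study design, not the sequencing process:
uniform i.i.d. genomes, non-overlapping multi-exon genes on both
strands, and planted peak loci following the four presence patterns
over (WT-N4, MUT-N4, WT-T4, MUT-T4): constitutive (1,1,1,1), TCR
(1,1,0,0), IL-2 (1,0,1,0), synergy (1,0,0,0). Defaults are the
package's study conditions: 300/100/50/200 loci per category, 300-bp
peaks, two replicates, Normal(0, 20 bp) boundary jitter, 10% noise
peaks (each appearing in a single random replicate, half of them with
IDR > 0.05), planted IDR ≤ 0.05, 30% of loci centred on gene TSSs,
2 × 1 Mb genome. Loci are placed on a shuffled slot grid that
guarantees pairwise separation ≥ 1 kb, so noiseless attribution is
exact by construction — that exactness is what the recovery tests
assert. Motif planting writes the consensus sequence at a random
offset inside chosen peaks at per-category rates, recording every
insertion.

What the generator does *not* emulate — read-level noise, fragment
size structure, GC and mappability bias, peak-width heterogeneity,
correlated replicate failure, overlapping regulatory elements —
bounds what passing tests show: they demonstrate the *procedure* is
implemented exactly and is robust to boundary jitter and sporadic
noise peaks, not that the biological conclusions would survive
realistic ATAC noise.

Determinism: every output is a pure function of (parameters, seed).
Placement and each condition/replicate emission draw from independent
`default_rng([seed, stream, ...])` streams so single files regenerate
stably.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full default
synthetic study (650 planted loci plus noise, 2 Mb genome), 100-
instance randomized oracle comparisons with up to 1,000 intervals per
side, exhaustive hypergeometric enumeration to N = 12, exhaustive
k-mer enumeration to width 5, and 100-replicate null simulations for
the enrichment matrix — sizes chosen so the whole suite completes in
well under a minute of CPU while still exercising every code path at
non-trivial scale. Score-table orientation is peaks × samples on disk,
samples × peaks in memory. All randomized tests are seeded; hypothesis
properties run derandomised.

## Known limitations

* The attribution is presence/absence set algebra; it does not model
  read counts, so quantitative accessibility shifts inside shared
  peaks are invisible (count-based differential testing is an explicit
  non-goal).
* The IDR filter consumes precomputed IDR annotations (an 11th
  narrowPeak column); the IDR mixture model itself is not implemented.
* Motif enrichment uses presence/absence per peak and a user-chosen
  background peak set; genome-wide scan multiplicity (q-values over
  positions) is not modelled.
* Reverse-strand p-values assume a strand-symmetric background.
* The gene annotation build is user input; promoter classification
  inherits whatever TSS set the GTF provides.
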