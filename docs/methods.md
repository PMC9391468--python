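# Methods

This note records the models, the numerical choices, what the synthetic
data does and does not emulate, and the known limitations. All defaults
named here are the package defaults; every one is exposed in
`PipelineConfig` or `SimConfig`.

## Active-region processing

Peak calls are half-open 0-based intervals carrying a fold change and an
FDR q-value. The processing order is fixed: per-sample enrichment filter
(fold change ≥ 3 inclusive, q < 10⁻⁴ strict), RNA-activity gate (mean
coverage over the peak ≥ 0.001, inclusive; bases absent from the
coverage track count as zero — a switch averages covered bases only,
since summary tools differ here), replicate pooling with union-merge
(bookended intervals coalesce), removal of calls shorter than 6 bp,
20 bp flank padding with chromosome clipping, and exon subtraction last.
The length filter is applied once, before padding; fragments created by
exon subtraction are kept regardless of length. Pseudostates are
interval intersections of the pooled per-mark sets (7 = H3K4me1∩H3K36me3,
9 = H3K4me1∩H3K27ac, 10 = H3K4me3∩H3K27ac∩H3K4me1, 11 = H3K4me3∩H3K4me1,
12 = H3K4me3∩H3K27ac) and are built per cell type only when every member
mark is available.

## Motif discovery

The discovery model is ZOOPS: each sequence contains at most one motif
occurrence, on either strand, with site rate γ estimated by EM. The
background is a first-order Markov model fitted with pseudocount 1 and
both strands pooled (so it is reverse-complement symmetric); window
background probabilities condition within the window and use the
marginal for the first base.

Candidate seeds are all 6-mers ranked by background-corrected
enrichment of their two-strand occurrence counts. Each top candidate is
initialized from its *exact occurrences*: the observed flanking ±3
columns around exact seed matches form the starting matrix (width 12).
This matters on enhancer-scale sequences: a 6-mer core alone is not
informative enough for EM to escape diffuse composition optima, while
exact-match flanks are dominated by true sites and carry the outer
columns from the start. The few best-initialized candidates get a short
EM; the winner is refined to convergence (tolerance 10⁻⁴ on the
objective, cap 120 iterations), then width-selected within [6, 30]:
edge columns below 0.25 bits are trimmed, and flanking columns above
0.25 bits (estimated from responsibility-weighted site counts) are
appended, re-running a short EM per width. The EM objective is the ZOOPS
log likelihood plus the Dirichlet smoothing term of the M-step
(pseudocount 0.01/cell); it is asserted non-decreasing every iteration.
Found sites (responsibility > 0.5) are masked with N and the search
repeats up to `nmotifs` times. Exported matrices receive pseudocount
0.1 per cell so log-odds scanning never sees a zero.

**Empirical E-values.** The sequence set is split in half; EM and width
selection see only the training half. The exported motif's objective
(site rate profiled out by bounded 1-D optimization) is evaluated on the
held-out half and on 50 dinucleotide-preserving (Altschul–Erikson)
shuffles of it; the E-value is the empirical p,
(1 + #{null ≥ observed})/51. Because the held-out half played no part in
selection, no width multiplier is applied there (the multiplier remains
available in `score_evalue` for in-sample use). Consequences: the
E-value floor is 1/51 ≈ 0.0196, so the printed Bonferroni bounds of the
original protocol (e.g. 2.94 × 10⁻⁵) are not reachable on this scale —
they referred to analytic E-values. Floor ties are ordered by the null
z-score. The pipeline carries motifs with E ≤ 0.02 (i.e. stronger than
every shuffle null) into the scanning stage; weaker motifs are EM
artifacts whose noisy log-odds matrices would pollute the allelic
statistics.

Motif–library comparison is a simplified alignment: best Pearson
correlation of overlapping probability columns over all offsets and both
orientations (minimum overlap max(4, min widths/2)), p-values by 1000
column-order permutations of the query, Benjamini–Hochberg q-values
across the library.

## Variant scanning

Variants are normalized to minimal form (shared prefix/suffix trimmed;
insertions have empty REF, deletions empty ALT). REF/ALT sequences share
their ±30 bp flanks as identical strings by construction, so any allelic
difference necessarily involves the allele. Scanning uses base-2
log-odds against an order-0 background fitted to the dataset's
active-region sequences. P-values are exact: the log-odds matrix is
discretized onto a 1000-step integer grid spanning its score range and
the null distribution of the window score is obtained by per-position
convolution; windows are scored on the same integer grid, so the
reported p equals the exact tail probability of the reported score.
Windows containing N are skipped; ties prefer the forward strand, then
the smallest offset; a sequence shorter than the motif scores −∞ with
p = 1. Both strands are scanned (the background's reverse-complement
symmetry makes one DP table valid for both).

## E_diff and the reporting rule

Per dataset, eligible pairs (min(P_REF, P_ALT) < 0.05, strict) provide
the empirical distribution of raw differences in p-value and in score;
z = (mean − observed)/sd with the sample sd (n−1), and
E_diff = 2(1 − Φ(|z|)), significant below 0.01/n_datasets. Datasets with
fewer than 3 eligible pairs are skipped. Differences are computed on raw
p-values and scores; a −log₁₀ p variant exists for sensitivity analyses
but is not the default.

A variant is *reported* only when its pair also has significant motif
overlap: best-hit p below 0.01/n_motifs/n_variants (6.81 × 10⁻⁷ at the
original protocol's 253 motifs × 58 variants). This conjunction is part
of the protocol, and it is load-bearing: E_diff alone is anticonservative
on zero-inflated difference distributions. Most neutral pairs have
d = 0 exactly (identical flanks, best hit outside the allele), so the
pooled sd is small and any pair whose weak chance match shifts —
typically a neutral indel — flags itself. Measured on 20 all-neutral
synthetic worlds, E_diff(Sc) alone flags 4.6% of pairs at α = 0.01; with
the overlap gate the reported fraction is 0.35%.

**Saturation.** The z denominator includes the true effects themselves.
With a fraction f of pairs carrying real effects of RMS size d, the
attainable |z| is capped near 1/√f · (d_i/d); at f = 0.1 the cap is
≈ 3.2, while the 0.01 bound needs |z| > 2.58, so effects below ~0.8 of
the RMS effect size are undetectable by construction. This is why the
synthetic end-to-end sensitivity plateaus near 0.7–0.9 (median 0.7–0.8
over seeds) and why, in the original study's terms, only the strongest
(indel) variants reach score significance.

## TRAP affinity

Published TRAP constants: λ = 0.7, ln R₀ = 0.584·w − 5.66. Mismatch
energy is summed per window, occupancies over both strands. Empirical
p-values score ≥ 100 background-model sequences of matched length (the
human-promoter background of the original server is unavailable
offline; the order-0 model fitted to the analyzed sequences stands in —
recorded here deliberately). The allelic comparison is the absolute
log₁₀ p difference, reported to 2 decimals, ranked descending with
percentile = rank/total × 100. DeepBind is intentionally out of scope
(trained network weights).

## Synthetic data

The generator emulates the statistical structure of thymocyte histone
ChIP-seq inputs, not their biology: i.i.d. genome at GC 0.41, exons on a
jittered grid covering 10%, 200 enhancers of 200–600 bp placed clear of
exons and of each other (placement margin 90 bp so jittered, padded
peaks never fuse — peak counts stay per-enhancer countable), one planted
12 bp PWM at 1.5 bits/column with sites *sampled* from the PWM (so site
strength varies realistically) in 70% of enhancers, two replicate peak
calls per enhancer with ±20 bp edge jitter, gamma(2, 3) fold changes,
10% of calls drawn to fail the q filter, 5% of enhancers RNA-silent,
coverage 5×/0 inside/outside active enhancers. One cell type × one
histone mark by default (the pseudostate path is exercised by tests with
multi-mark configs).

Variants: 100, of which 10% are disruptive — by default creator
insertions (a central consensus base is dropped in the genome and the
ALT allele restores it) and site-destroying deletions (length ≥ half the
site), alternating. A substitution at the site's most informative
consensus column is available as a third type but excluded from the
default mix: it changes a 12-column site by only ~5 bits, leaves the
match intact on both alleles, and the score statistic is documented to
be insensitive to such dents — labelling them "disruptive" would assert
detectability the method does not claim. Neutral variants (80% SNV,
20% short indel) are placed ≥ 40 bp from planted sites. Everything is
deterministic given the seed, down to the emitted bytes.

A green end-to-end test therefore establishes that the pipeline
recovers planted motifs and flags match-destroying/creating indels at
the stated rates on data with this structure; it does not establish
performance on real ChIP-seq (no read-level noise, no LD, no diploid
genomes, no peak-caller artifacts).

## Known limitations

- Empirical discovery E-values are resolution-limited by the 50-shuffle
  null; analytic MEME E-values are not reproduced.
- Table-scale numerics of the original study (its FIMO score scale, its
  extreme E_diff values) require the original genome-scale data and
  motif matrices and are out of reach by design; acceptance is by
  synthetic recovery properties.
- The E_diff saturation bound above is a property of the statistic, not
  of this implementation; sensitivity targets above ~0.8 at 10%
  contamination are structurally unreachable when effect sizes vary.
- The TRAP null background is not promoter-matched.
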