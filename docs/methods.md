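# Methods

## The biological problem

CodY is the master nutritional regulator of Firmicutes: a GAF
(ligand-sensing) domain coupled to a winged helix-turn-helix (wHTH)
DNA-binding domain, repressing target genes through a 15-bp palindromic
operator, the CodY box `AATTTTCWGAAAATT`. CodY is the only characterised
protein carrying both domains, so their co-occurrence on one protein is a
usable search criterion for CodY-like regulators outside Firmicutes — in
particular in the Gram-negative phylum Synergistetes, where candidate
binding sites take the form of a *spaced dyad*: a short AT-rich arm, an
unconstrained spacer of `d` bases, and the arm's (near) reverse
complement, written `ARM-N_d-rc(ARM)`. This package implements the full
in-silico chain — domain screen, promoter extraction, dyad discovery,
genome-wide scanning, functional enrichment — together with generators
for synthetic inputs that carry known ground truth.

## Domain screen

HMMER3 per-domain tables (`domtblout`) are parsed positionally; the
screen requires at least one hit to each of two Pfam accessions (defaults
`PF06018` for GAF and `PF08222` for the CodY wHTH) with per-domain
*independent* e-value strictly below `evalue_max` (default `1e-3`). The
independent e-value is used because the criterion is domain *presence*;
the conditional e-value would be inappropriately optimistic for
multi-domain matches. Multiple hits per domain collapse to the lowest
e-value (ties by higher bit score); domain order on the protein and
envelope overlap are not constrained. The screen is monotone in the
threshold, which the tests verify against a brute-force double loop.

## Promoters and operons

Coordinates are 0-based half-open internally; GFF3 is converted on read.
Operons are called with a distance heuristic: consecutive same-contig,
same-strand genes with intergenic gap ≤ `operon_max_gap` (default 50 bp)
are co-transcribed; the leader is the leftmost gene of a `+` operon and
the rightmost of a `-` operon. This deliberately replaces
transcription-unit predictors that need expression data or external
services; only the leader's promoter anchor is needed downstream, and the
threshold is configurable. The promoter of a leader `[s, e)` is
`[max(0, s - window), s)` on `+` and the reverse complement of
`[e, min(L, e + window))` on `-`, with `window` defaulting to 400 bp (the
conventional window for CodY-box work). Clipping at the nearest annotated
gene boundary is on for genome-wide scans and off for fixed-window
single-locus extraction; a window of zero length yields a flagged empty
promoter, not an error. A hit in a shared divergent intergenic region is
credited to both flanking leaders.

## Dyad discovery

### Enumeration

Candidate arms are all `arm_len`-mers (default 6) with A/T fraction
≥ `min_at_fraction` (default 5/6 — "AT-rich" must be quantified somehow,
and 5/6 admits arms like `ATTTTC` while excluding GC-rich words; 448
words at the defaults). For each arm `w` and spacer
`d ∈ [spacer_min, spacer_max]` with `2·arm_len + d ≥ min_motif_span`
(defaults 0–30 and 15, so `d ≥ 3`), the enumeration counts promoters
containing `w + N_d + w'` on either strand, where `w'` is any word within
`palindrome_mismatch_max` Hamming distance of `rc(w)`.

The mismatch tolerance defaults to **2**: the observed genus dyads
include `AATATT/AAAATA`, whose right arm is two mismatches from a perfect
palindrome (`rc(AATATT) = AATATT`), so a tolerance of 1 would be unable
to represent a reported binding site. The cost of the looser tolerance
is shift degeneracy (below).

### Significance

Support `k` out of `n` promoters is scored against an order-0 background
estimated from pooled promoter base frequencies. The per-position site
probability is `p_site = P(w) · P(within mm of rc(w))`, where the second
factor sums the background probabilities of the whole mismatch
neighbourhood by a small dynamic programme — the null must mirror the
counting rule, otherwise every p-value would be anti-conservative by
roughly the neighbourhood size (~150× at mm = 2). With `S` valid start
positions in a promoter of the median length, the per-promoter null
probability is `p0 = 1 − (1 − p_site)^(2S)`, and the reported p-value is
the binomial upper tail `P[X ≥ k | n, p0]`, Bonferroni-multiplied by the
number of (word, spacer) hypotheses and clamped at 1. Ranking is total
and documented: ascending p, then descending support, then lexicographic
(word, spacer). On background-only sets the fraction of hypotheses
reaching Bonferroni p < 0.05 stays below 0.05 (calibration test).

### ZOOPS-EM refinement

The enumerated seed is refined under a zero-or-one-occurrence-per-sequence
model: each promoter either has no site (probability `1 − γ`) or one site
at a uniform offset and strand with spacer length weighted by a learned
distribution `λ_d`. Arm columns follow 4×6 position frequency matrices
with a symmetric Dirichlet pseudocount (0.1); spacer and flanking bases
follow the fixed background. The optimised objective is the penalised
(MAP) log-likelihood, which is provably non-decreasing per iteration —
the implementation raises rather than silently continuing if numerics
ever violate that. Convergence at `em_tolerance = 1e-6` or
`em_max_iter = 200`; everything is deterministic given the seed model, so
repeated runs are bit-identical.

### Multi-start selection

With mm = 2 and homopolymer-like arms, shifted alignments of a planted
dyad (e.g. `d+2` for `AATATT-N21-AAAATA`) can reach full support in the
enumeration, and the longer span's smaller `S` gives them marginally
smaller p-values; an EM started there converges to that local optimum.
`discover_dyads` therefore refines the top five enumerated models and
returns the one with the highest final objective — the true alignment
scores all 12 arm columns as informative where the shifted one scores 10,
so likelihood separates them cleanly. This is ordinary multi-start EM as
used by mainstream motif discovery tools.

### Consensus

Per matrix column, bases with frequency ≥ `include_threshold` (default
0.3) map to the IUPAC code of the set (single base → letter, {C,G} → S,
{A,T} → W, …); the empty set and the full set both map to N. The full
consensus string is left arm + `N`×spacer (point estimate = argmax
`λ_d`) + right arm. A MEME-minimal export flattens the dyad into one
position-probability matrix with background-frequency spacer columns for
interoperability.

## Scanning

IUPAC scanning counts class violations per window with a mismatch budget
on both strands; spaced patterns share one budget across the two arms and
never constrain spacer bases. The canonical box is scanned with
`max_mismatch = 1` by default — the observed Synergistetes box variant
`AATTTTCTTAAAATT` differs from `AATTTTCWGAAAATT` at exactly one position
(position 9, G↔T), so a 0-mismatch scan would miss a site the literature
treats as the canonical box. Six-base arms default to 0 mismatches.

PWM scanning uses log2 odds against the background, discretised at
`score_scale = 1000`; the exact null distribution of the discretised
score is obtained by convolving per-column distributions (dynamic
programme), so every reported p-value `P[score ≥ s]` is exact for the
discretised matrix, and hits satisfy `p ≤ 1e-4` by default (the
conventional FIMO threshold). Windows containing N are skipped. Tests
verify the table against exhaustive enumeration of all 4^6 words and the
scanner against brute-force window rescoring.

Classification assigns each promoter to canonical-only / extended-only /
both / none (a partition, verified as such). The regulon-size percentage
uses all annotated genes as the denominator, and a motif on a leader's
promoter credits every gene of its operon ("leaders-only" is available
as an alternative). No multiple-testing correction is applied at the
classification step; classification needs only motif existence.

## Enrichment

A gene counts toward its functional category (caller-supplied table;
COG-style letters expected but not enforced; unannotated genes pool under
`-`) iff its operon leader's promoter is motif-positive. Cell scores are
exactly `log2(N + 1)`; the TSV matrix (sorted axes, 6-decimal cells) is
the tested artifact, and the heatmap image is a convenience rendering.
No enrichment *test* is computed — the score is a display transform of
counts, by design.

## Synthetic data

Backgrounds draw bases independently with `P(G) = P(C) = gc/2`,
`P(A) = P(T) = (1 − gc)/2`. The default GC is 55.95%, the genomic GC of
*Cloacibacillus evryensis* DSM 19522, the organism whose CodY-like
protein anchors the experimental work this package models; discovery
benchmarks use GC 0.50 with 20 promoters of 400 bp and plant fraction
1.0, matching the all-sequences-share-the-motif situation of a
genus-level alignment. Planting instantiates degenerate IUPAC arm
positions independently per promoter (emulating the variability a
sequence logo summarises), draws the spacer from the promoters' own base
composition, and writes the instance at a seeded random offset and strand,
recording a full truth table. The order-0 background is the simplest
model consistent with a GC-only characterisation; real promoters have
dinucleotide bias, repeats and compositional heterogeneity, so passing
recovery tests here demonstrates correctness of the machinery, not
expected sensitivity on real genomes.

Synthetic genomes alternate promoter blocks and gene blocks on one
forward-strand contig (intra-operon gaps 20 bp ≤ threshold; the 400-bp
promoter blocks separate operons by far more), so the operon caller must
recover exactly the constructed operons and each promoter block is
exactly its leader's upstream window. Domain-table fixtures write valid
positionally-correct rows with e-values placed on either side of (or
exactly at) the threshold. Probe variants reproduce the six-probe
arm-substitution series: wild type; first/middle/last arm → `CCCCCC`;
all arms → `GGGGGG`; all arms → seeded random hexamers each containing at
least one G or C (the substitution base for the middle-arm variant is not
dictated by the modelled experiment; `CCCCCC` was chosen for symmetry
with the 5′-arm variant).

## Problem sizes and determinism

Discovery benchmarks use 20 promoters × 400 bp per set and a handful of
seed replicates per genus dyad; EM fixtures in the property suites use
6–8 promoters of 80–150 bp with narrowed spacer ranges. These sizes make
every statistic exact or well-separated (planted support 20/20 against
null expectations below 10⁻²) while keeping the whole suite fast. All
randomness flows through explicit integer seeds into
`numpy.random.default_rng`; there is no global random state, and every
generator and the pipeline are byte-identical under repeated seeds.

## Known limitations

* The operon heuristic ignores terminators, expression and intergenic
  RNAs; it is an anchor-finding device, not a transcription-unit model.
* The binomial null treats promoters as independent and ignores overlaps
  of candidate sites within a promoter; Bonferroni over ~12,500
  hypotheses is conservative in aggregate.
* EM refines a single motif; co-occurring distinct motifs in one promoter
  set compete for the same latent site.
* The PWM p-values are exact for the *discretised* score; at
  `score_scale = 1000` the discretisation error is negligible relative to
  any sensible threshold.
* Degenerate IUPAC letters in input sequences are treated as N (unknown)
  everywhere except IUPAC pattern matching itself.
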