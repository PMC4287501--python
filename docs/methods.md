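# Methods

## Scope and model

`metaregulome` implements a de novo TFBS discovery protocol for promoter
collections built from long metagenomic reads. Its statistical core is a
word-pair overrepresentation model: a candidate binding site is a
palindromic dimer W₁·Nˢ·W₂, with W₁ a 3–5 nt word over {A,C,G,T}, W₂ the
reverse complement of W₁, and a spacer of s ∈ [0, 30] unconstrained bases.
This mirrors the biology of homodimeric prokaryotic transcription factors,
which preferentially bind inverted repeats. The full pattern is its own
reverse complement, so a scan of the stored strand is strand-complete; the
package relies on this invariant rather than scanning both strands.

The background model treats the two words as independently placed. With
n(W) the total (overlapping) occurrence count of word W over the pooled
promoter set and L_eff(L) = Σ_r max(0, L(r) − L + 1) the number of
positions where a length-L pattern can start, the expected dimer count is

    n_exp(D) = (n(W₁) / L_eff(|W|)) · (n(W₂) / L_eff(|W|)) · L_eff(D).

This frequency-product form is the package's own reconstruction of the
expectation; it is validated in the test suite by simulation: on i.i.d.
uniform promoters, the summed observed count over all dimers of one
geometry is Binomial(L_eff(D), 4^-|W|), and the summed expectation must sit
within three standard errors of it. A `simple` alternative,
n(W₁)·n(W₂)/L_eff(D), is exposed for sensitivity analysis only; it does not
match the simulated null and is not the default.

Significance is the upper Poisson tail P(X ≥ n(D) | n_exp), computed
through the regularized incomplete gamma (scipy's survival function), with
P ≡ 1 for n(D) = 0. A dimer is called when P < 1/N_motif. N_motif is read
as the number of candidate dimers observed at least once ("positive
motifs"), making the threshold data-dependent but reproducible; counting
all 41,664 candidates instead is available via `n_motif_rule="all"`.

## Promoter identification

Filters, in order, with their defaults: read length ≥ 800 nt; best protein
hit per read with alignment length ≥ 150 aa (inclusive) and identity
strictly > 50%; ≥ 300 nt of non-coding sequence upstream of the hit on the
gene strand; extraction of exactly 300 nt adjacent to the coding start,
reverse-complemented for minus-frame hits so every promoter reads 5'→3'
into its gene. When a read carries several passing hits, the highest
bitscore wins (ties: lowest start coordinate, then subject id) and the
upstream window must not overlap any other passing hit's interval — this
is what operationalizes "non-coding" and discards operon-internal genes.
Eukaryotic/ncRNA/CRISPR removal is consumed as external id lists; the
package does not re-implement those annotators.

De-redundancy is greedy incremental clustering at 98% identity: promoters
are visited in a deterministic order (descending non-N count, then id) and
each joins the first representative it matches at or above the cutoff.
Identity between the fixed-length promoters is computed column-wise without
gaps, so k substitutions over 300 nt give exactly (300−k)/300; a
minimum-edit-distance global alignment (edlib, matches/columns over the
extended CIGAR) is the fallback for unequal lengths. The ungapped
definition was chosen because gapped optima are not unique in the quantity
matches/columns — a minimum-edit alignment can convert substitutions into
indel pairs and shift the ratio — whereas the ungapped value is exact,
reproducible and the natural metric for same-length windows.

## Numerical and algorithmic choices

- Promoters are encoded once as int8 arrays (A=0…T=3, N=−1); w-mer codes
  are rolling base-4 integers with N-contaminated positions masked. Scoring
  all 41,664 candidates takes one joint (code_i, code_{i+offset}) histogram
  per (|W|, spacer) geometry — 93 bincounts over the pooled set — after
  which every dimer's n(D) is a table lookup. A 500 × 300 nt set scores in
  under a second on one CPU.
- Word counts never match across promoter boundaries: the pooled code
  array is padded with 64 invalid entries between promoters, longer than
  the largest motif (40 nt).
- Overlapping sites are all retained, for the same or different motifs; no
  masking is applied. N positions never match; there is no wildcard
  matching inside W₁/W₂.
- L_eff uses raw promoter lengths; positions made unmatchable by interior
  Ns are still counted, a slight overestimate of placements accepted for
  fidelity to the formula.
- Exact enrichment tests use the hypergeometric tail (one-sided,
  enrichment) within an environment and the two-sided exact test between
  environments; Bonferroni is applied per (group × hierarchy level)
  family. Kruskal–Wallis uses midrank tie correction with the chi-square
  asymptotic p; all-identical observations return H = 0, p = 1 by
  convention. Spearman's rho is Pearson on midranks with the
  t-approximation; constant vectors are rejected as undefined.
- Top-k% bins take the smallest descending-count prefix holding
  ⌈k·n/100⌉ promoters, extended across ties at the boundary count, so
  membership is a function of the counts alone and bins nest in k. Coarse
  low/medium/high bins use count tertiles with boundary ties assigned to
  the lower bin.
- Candidate order, cluster order, tie-breaks and all generators are
  deterministic; every random routine takes an explicit seed and no
  global RNG state is used.

## Synthetic data: what it emulates and what it does not

The generators produce (a) i.i.d. background promoters with a configurable
GC fraction, (b) planted palindromic dimers — instance spacers are drawn at
random so only the flanks carry signal, as in the motif model, (c) boundary
-case reads with a consistent mock protein-alignment table whose pass/fail
outcome under every extraction filter is known by construction (799/800 nt,
149/150 aa, 50.0/50.1% identity, minus-frame hits, an operon-like overlap,
a bitscore tie-break, and a near-duplicate trio at 5 and 10 mismatches
bracketing the 98% cutoff), and (d) function annotations with constructed
enrichment. Default study conditions are 500 promoters × 300 nt and the
planted dimer TGACA·N⁸·TGTCA in 30% of promoters, one copy each.

The fixtures deliberately do not model phylogenetic composition, codon
structure, sequencing error, GC heterogeneity between organisms, or real
TF motif degeneracy (planted instances are exact). Passing tests therefore
demonstrate correctness of the counting, statistics and bookkeeping under
the stated model — not that the Poisson background is adequate for real
metagenomes, where compositional heterogeneity inflates word-count
variance.

## Validation design

The randomization control shuffles each promoter within consecutive 20-nt
windows (permute-within-window, preserving local composition exactly),
reruns the complete discovery on the shuffled set — recomputing N_motif
and alpha there, unless `reuse_alpha` is set — and compares the two
per-promoter count distributions with a two-sided Mann–Whitney U test.

A limitation worth stating: under a pure null, the 1/N_motif rule still
admits on the order of one spurious motif per run (it is a Bonferroni-type
threshold), and whichever of the two runs draws it produces a sparse
nonzero count vector that the rank test can flag. The composed
real-vs-shuffled test is therefore anti-conservative under the null and
should be read as a power/effect-size display, not a calibrated hypothesis
test; the discovery stage itself is calibrated (≲ 0.01% of candidates
called on signal-free data). The test suite asserts exactly this
mechanism.

Known-motif matching uses IUPAC consensus strings compiled to character
classes, scanned on both strands of each predicted site (or whole
promoters); a fully degenerate consensus position also matches N in the
target, partially degenerate codes match only resolved bases. PWM scanning
is out of scope.

## Problem sizes

Defaults were chosen so a full test run (unit + property + end-to-end,
including the exhaustive 41,664-pattern oracle comparison on 50 promoters
and the 500-promoter discovery runs) completes in well under a minute on a
single CPU, and the acceptance script in a few seconds. Larger inputs scale
linearly in total promoter bases for scoring and quadratically in cluster
count for de-redundancy.

## Known limitations

- The Poisson background ignores overlap dependence of self-overlapping
  words and between-promoter composition heterogeneity; p-values for
  repeat-like dimers (e.g. A-rich words) are optimistic on real data.
- One promoter per read (best hit); reads carrying several genes yield at
  most one promoter.
- Word counting is single-strand; dimer counts are strand-invariant by
  palindromy, but n(W) of a non-palindromic word differs from its
  complement's count, which the expectation absorbs by using both n(W₁)
  and n(W₂).
- Greedy 98% clustering is order-dependent by design (the order is fixed
  and documented); it is a representative-selection scheme, not an optimal
  clustering.
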