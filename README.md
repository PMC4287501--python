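# metaregulome

De novo discovery of palindromic transcription-factor binding sites (TFBS)
in promoter collections extracted from long metagenomic reads, with the
downstream statistics needed to compare the "regulatory potential" of
environmental samples.

## Who this is for

Microbial ecologists and regulatory genomicists who have long (Sanger-grade,
≥ 800 nt) metagenomic reads plus tabular protein-alignment hits for them,
and who want to ask: which upstream regions look like promoters, which
inverted-repeat motifs are statistically overrepresented in them, and which
gene functions sit under the most heavily regulated promoters. Everything is
usable from Python; a thin `metaregulome` command mirrors the stages for
shell pipelines.

## The method

**Promoter identification.** Reads shorter than 800 nt are discarded. A read
is kept when a protein hit covers ≥ 150 aligned amino acids at > 50%
identity, and when at least 300 nt of non-coding sequence lies upstream of
the coding region (this avoids operon-internal genes). The 300 nt adjacent
to the coding start are extracted, oriented 5'→3' into the gene, collapsed
at 98% sequence identity, and purged with externally produced exclusion
lists (eukaryotic reads, ncRNA, secondary coding regions, CRISPR arrays).

**Motif model.** A candidate TFBS is a palindromic dimer
*W*₁·Nˢ·*W*₂ with *W*₁ a 3–5 nt word, *W*₂ = reverse complement of *W*₁
and spacer *s* ∈ [0, 30] — 41,664 candidates in all. Because each pattern
is its own reverse complement, one strand scan finds every instance. For a
dimer *D* the observed copy number *n*(*D*) over the pooled promoters is
compared against

    n_exp(D) = (n(W₁)/L_eff(|W|)) · (n(W₂)/L_eff(|W|)) · L_eff(D),

where *n*(*W*) is the total occurrence count of word *W* and
*L*_eff(*L*) = Σ_r max(0, *L*(r) − *L* + 1) the number of positions a
length-*L* pattern can occupy. Significance is the upper Poisson tail
P(X ≥ n(D) | n_exp), called at P < 1/*N*_motif with *N*_motif the number of
candidate dimers observed at least once.

**Downstream statistics.** Per-promoter counts of distinct significant
motifs rank promoters into top-k% bins (k = 1, 5, 10, 20, 30, 40);
functional enrichment per bin uses one-sided exact tests with Bonferroni
correction, environments are compared with two-sided exact tests and
Kruskal–Wallis on known-TFBS densities D(x) = sites/(N·300 bp), and the
control rediscovers motifs on 20-nt-window-shuffled promoters (composition
preserved, motifs destroyed).

## Worked example

```python
from metaregulome import (PalindromicDimer, discover_motifs,
                          generate_background_promoters, plant_dimer)

promoters = generate_background_promoters(500, length=300, seed=7)
planted, truth = plant_dimer(promoters, PalindromicDimer("TGACA", 8),
                             fraction=0.3, seed=11)
result = discover_motifs(planted)
print(result.motifs.nsmallest(3, "p_value")[
    ["name", "pattern", "n_obs", "n_exp", "p_value"]])
```

prints (see `examples/02_discover_motifs.py` for the full script):

```
     name            pattern  n_obs     n_exp       p_value
8 5 TGACA TGACANNNNNNNNTGTCA    150  0.513700 4.245185e-307
 8 4 GACA   GACANNNNNNNNTGTC    150  2.957649 4.066356e-194
10 4 TGAC TGACNNNNNNNNNNGTCA    151  3.568362 8.862015e-184
```

The dimer planted in 150 of 500 promoters is recovered with 150 observed
copies against an expectation of 0.51, at a Poisson tail far below
alpha = 1/N_motif ≈ 7.8 × 10⁻⁵; the runners-up are its own sub-words, which
necessarily co-occur with it. Motif names follow the `"<spacer> <|W|> <W₁>"`
convention, so `8 5 TGACA` expands to `TGACANNNNNNNNTGTCA`.

The other examples walk through promoter extraction from reads
(`examples/01`), the window-shuffle control (`examples/03`) and functional
enrichment of top-density bins (`examples/04`).

## Command line

```bash
metaregulome simulate --seed 5 --outdir sim            # synthetic reads + truth
metaregulome extract  --reads sim/reads.fasta --alignments sim/alignments.tsv --outdir ext
metaregulome discover --promoters ext/promoters.fasta --outdir disc
metaregulome validate --promoters ext/promoters.fasta --seed 5 --outdir val
metaregulome stats    --counts disc/promoter_counts.tsv --annotations ann.tsv --outdir st
```

Every output table begins with comment headers recording the tool version,
the full effective configuration, input checksums and seeds.

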