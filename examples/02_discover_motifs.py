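"""De novo palindromic-dimer discovery with a planted ground-truth motif.

Generates 500 random 300-nt promoters, plants the dimer TGACA-N8-TGTCA in
30% of them, scores all 41,664 candidate dimers and prints the top hits.
"""

from metaregulome import (
    PalindromicDimer,
    discover_motifs,
    generate_background_promoters,
    plant_dimer,
)

promoters = generate_background_promoters(500, length=300, seed=7)
dimer = PalindromicDimer(w1="TGACA", spacer=8)
planted, truth = plant_dimer(promoters, dimer, fraction=0.3, seed=11)
print(f"planted {truth.n_sites} copies of {dimer.pattern} "
      f"into {len(truth.planted_ids)}/500 promoters\n")

result = discover_motifs(planted)
print(f"candidates scored : {len(result.motifs)}")
print(f"N_motif (observed): {result.n_motif}")
print(f"alpha = 1/N_motif : {result.alpha:.3e}")
print(f"significant motifs: {int(result.motifs['significant'].sum())}\n")

top = result.motifs.nsmallest(5, "p_value")
print(top[["name", "pattern", "n_obs", "n_exp", "p_value", "significant"]].to_string(index=False))
print()
print(
    "n_obs is the observed copy number of each dimer over the pooled set,\n"
    "n_exp its expectation from the two word frequencies, and the p-value\n"
    "the upper Poisson tail; the planted dimer should rank first by far.\n"
    f"Mean TFBS per promoter (distinct significant motifs): "
    f"{result.promoter_counts.mean():.2f}"
)
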