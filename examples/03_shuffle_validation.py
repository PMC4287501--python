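"""The randomization control: rediscovery on 20-nt-window-shuffled promoters.

Shuffling within 20-nt windows preserves local nucleotide composition but
destroys dimer instances; real promoters with planted signal should carry
far more predicted sites than their shuffled counterparts. Predicted sites
are then matched against a small known-motif consensus library.
"""

from metaregulome import (
    KnownMotif,
    PalindromicDimer,
    generate_background_promoters,
    plant_dimer,
    scan_known_motifs,
    shuffled_rediscovery,
)

promoters = generate_background_promoters(300, length=300, seed=19)
planted, _ = plant_dimer(promoters, PalindromicDimer("TGACA", 8), fraction=0.3, seed=23)

result = shuffled_rediscovery(planted, seed=29, window_size=20)
print(f"mean TFBS/promoter, real     : {result.real_counts.mean():.2f}")
print(f"mean TFBS/promoter, shuffled : {result.shuffled_counts.mean():.2f}")
print(f"Mann-Whitney U               : {result.u_statistic:.0f}")
print(f"two-sided p                  : {result.p_value:.3g}")
print()

library = [KnownMotif("CRP-like", "TGTGANNNNNNTCACA"),
           KnownMotif("planted", "TGACANNNNNNNNTGTCA")]
scan = scan_known_motifs(result.real.sites, library, mode="sites")
print(f"predicted sites scanned      : {len(scan.per_item)}")
print(f"fraction with a known match  : {scan.fraction_with_match:.2%}")
print()
print(
    "A p-value far below 0.01 says the predicted-site load of real\n"
    "promoters cannot be explained by their nucleotide composition alone;\n"
    "the known-motif fraction says how many de novo sites coincide with a\n"
    "described regulator consensus."
)
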