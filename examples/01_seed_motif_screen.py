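"""Screen the two canonical cardiac miRNAs for inverse complementarity to m6A motifs.

The m6A consensus is RRACH (R = A/G, H = A/C/U), strongest form GGACH. A
miRNA whose seed-complementary target-site sequence contains the motif can
have its binding site methylated. miR-133a-3p's site sequence is GGACCAA,
which carries the GGACH instance GGACC; miR-499-5p's site (AGUCUUA) carries
neither motif.
"""

from m6amir import MatureMiRNA, normalize_sequence, screen_catalogue, summarize_screen

mirnas = [
    MatureMiRNA("mmu-miR-133a-3p", normalize_sequence("UUUGGUCCCCUUCAACCAGCUG", seq_id="a")),
    MatureMiRNA("mmu-miR-499-5p", normalize_sequence("UUAAGACUUGCAGUGAUGUUU", seq_id="b")),
]
results = screen_catalogue(mirnas)
for r in results:
    hits = ", ".join(f"{h.matched_text}@{h.start}" for h in r.hits) or "-"
    print(f"{r.mirna_name}: seed {r.seed} -> site {r.site_sequence} "
          f"[{r.match_class}] motif hits: {hits}")
print(summarize_screen(results))
# FULL means the stringent GGACH motif lies inside the seed-complementary
# site; NONE means not even the relaxed RRACH consensus fits.
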