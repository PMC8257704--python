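"""Find seed-match sites in 3'UTRs and classify genes by m6A status.

A gene is an m6A-modified target when it (1) has a canonical seed-match site
for the miRNA, (2) appears in the m6A-RIP gene set, and (3) carries a GGACH
motif in its 3'UTR. The stricter variant also requires the motif to overlap
a site.
"""

from m6amir import (
    MatureMiRNA,
    NucleotideSequence,
    UTRRecord,
    annotate_genes,
    find_target_sites,
    normalize_sequence,
)

mir133a = MatureMiRNA(
    "mmu-miR-133a-3p", normalize_sequence("UUUGGUCCCCUUCAACCAGCUG", seq_id="m")
)
utrs = [
    UTRRecord("Cdc42_like", NucleotideSequence("Cdc42_like", "CUAGGACCAAACUAGCAUGCAU")),
    UTRRecord("no_site", NucleotideSequence("no_site", "ACACACGGACUACACACACACA")),
    UTRRecord("site_no_m6a", NucleotideSequence("site_no_m6a", "CGUGGACCAACGUACGUACGUA")),
]
for u in utrs:
    for s in find_target_sites(u, mir133a, min_site_type="6mer"):
        print(f"{s.gene_id}: {s.site_type} site at [{s.start},{s.end}) "
              f"= {u.sequence.residues[s.start:s.end]}")

m6a_gene_set = {"Cdc42_like", "no_site"}
for a in annotate_genes(utrs, mir133a, m6a_gene_set):
    print(f"{a.gene_id}: target={a.is_target} in_m6a_set={a.m6a_in_gene_set} "
          f"ggach={a.ggach_in_utr} -> m6A-modified target: {a.m6a_modified_target}")
# Only Cdc42_like satisfies the full conjunction: site + gene set + motif.
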