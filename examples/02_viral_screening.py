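"""Screen contigs for viral origin from a gene-annotation hit table.

A contig passes when it is longer than 5 kb, carries at least five genes
with viral-protein-family (VPF) hits, and satisfies one of three
composition criteria on its KO / Pfam / VPF gene fractions.
"""

from viromehost.synthio import SynthConfig, gen_community
from viromehost.vscreen import (TaxHit, compute_n50, lca_assign, screen_table)

comm = gen_community(SynthConfig(n_viruses=15, n_hosts=10, n_samples=2, seed=7))
table = screen_table(comm.annotations, comm.contig_lengths)
viral = table.loc[table["viral"]]

print(f"{len(viral)} of {len(table)} contigs called viral")
print(f"N50 of viral contigs: {compute_n50(list(viral['length']))} bp")
# Host genomes are KO/Pfam-rich with no VPF hits, so they are rejected;
# the planted viral contigs are VPF-rich and all pass.

hits = [TaxHit("c1", ("Viruses", "Caudovirales", "Podoviridae"), 210.0),
        TaxHit("c1", ("Viruses", "Caudovirales", "Siphoviridae"), 205.0)]
print(f"LCA of two near-top family hits: {lca_assign(hits)}")
# The consensus backs off to the deepest rank shared by the retained hits.
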