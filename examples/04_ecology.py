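"""Virome ecology: abundance, diversity, ordination and the core virome.

Relative abundance is length- and depth-normalized coverage, summed over
genus members; Shannon (nats) and Pielou indices summarise each sample;
Bray–Curtis + PCoA ordinates samples; the core set holds genera present
everywhere.
"""

from viromehost.ecol import (bray_curtis_matrix, core_shared_genera, pcoa,
                             pielou, rank_abundance, relative_abundance,
                             shannon)
from viromehost.synthio import SynthConfig, gen_community

comm = gen_community(SynthConfig(n_viruses=30, n_hosts=0, n_samples=5,
                                 spacers_per_host=0, seed=12))
ab = relative_abundance(comm.coverage, comm.contig_lengths,
                        comm.truth.true_genus_of)

for s in ab.columns:
    print(f"{s}: richness={int((ab[s] > 0).sum()):3d}  "
          f"H'={shannon(ab[s]):.3f}  J'={pielou(ab[s]):.3f}")
# H' grows with the number and evenness of genera; J' = 1 would mean a
# perfectly even community.

D = bray_curtis_matrix(ab)
coords, eigvals = pcoa(D.to_numpy(), k=2)
explained = eigvals[:2] / eigvals[eigvals > 0].sum() * 100
print(f"\nPCoA axes explain {explained[0]:.1f}% and {explained[1]:.1f}% "
      f"of Bray-Curtis variance")

counts, core = core_shared_genera(ab > 0)
print(f"core genera (present in all {len(ab.columns)} samples): {len(core)}")
ranked, crossing = rank_abundance(ab.iloc[:, 0], threshold=0.001)
print(f"rank at which {ab.columns[0]} abundance first drops below 0.1%: {crossing}")
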