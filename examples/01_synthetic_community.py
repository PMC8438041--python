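"""Generate a synthetic virome community and inspect its planted truth.

The generator emits viral and host genomes, gene annotations, per-sample
coverage, Hi-C contacts, and a truth bundle recording which virus infects
which host, which genus each virus belongs to, and the planted abundances.
"""

from viromehost.synthio import SynthConfig, gen_community

cfg = SynthConfig(n_viruses=20, n_hosts=10, n_samples=4, seed=42)
comm = gen_community(cfg)

print(f"viruses: {len(comm.viruses)}  hosts: {len(comm.hosts)}  "
      f"samples: {cfg.n_samples}")
print(f"planted virus-host links: {len(comm.truth.true_links)}")
print(f"planted spacers: {len(comm.truth.planted_spacers)} "
      f"({cfg.spacers_per_host} per host, {cfg.subs_per_spacer} substitutions)")
print(f"viral genera planted: {len(set(comm.truth.true_genus_of.values()))}")
print("\nplanted genus abundances (columns sum to 1):")
print(comm.truth.true_abundance.round(3))
# Every row above is a viral genus; zeros mark samples where a non-core
# genus was deliberately left absent, emulating a shared core plus a
# sample-specific variable tail.
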