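"""Synthetic virome communities with planted, machine-readable ground truth.

The generator emits everything the downstream stages consume — viral and host
genome FASTA, a per-gene annotation hit table, per-sample coverage records,
optional error-free short reads, and a Hi-C contact table — together with a
:class:`TruthBundle` recording the planted virus–host links, genus memberships
and abundances, so that every stage can be scored against known truth.

Hosts carry CRISPR arrays whose spacers are substrings sampled from the viral
genomes (optionally with a controlled number of substitutions); per-sample
genus abundances are log-normal with a core subset forced present everywhere;
Hi-C contacts concentrate on true virus–host pairs with uniform background
noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seqs import BASES, random_seq, write_fasta

_SPACER_DETECTABLE = (19, 48)  # detector default spacer-length window

# Codon table is irrelevant for synthetic proteins; amino acids drawn uniformly.
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    """Parameters of a synthetic community.

    All randomness is driven by ``seed``; two runs with equal configs produce
    byte-identical outputs.
    """

    n_viruses: int = 50
    n_hosts: int = 30
    n_samples: int = 6
    virus_len_range: tuple[int, int] = (15_000, 40_000)
    host_len: int = 50_000
    genes_per_kb: float = 1.0
    spacers_per_host: int = 3
    spacer_len_range: tuple[int, int] = (25, 45)
    repeat_len: int = 28
    subs_per_spacer: int = 0
    core_fraction: float = 0.25
    abundance_sigma: float = 1.5
    hic_true_contacts: int = 20
    hic_noise_contacts: int = 50
    reads_per_sample: int = 0
    read_len: int = 150
    dataset_size: int = 1_000_000_000
    archaea_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_viruses", "n_hosts", "n_samples", "spacers_per_host",
                     "subs_per_spacer", "hic_true_contacts", "hic_noise_contacts",
                     "reads_per_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.spacer_len_range
        dlo, dhi = _SPACER_DETECTABLE
        if lo < dlo or hi > dhi or lo > hi:
            raise ValueError(
                f"spacer_len_range {self.spacer_len_range} must lie within "
                f"[{dlo},{dhi}]: planted arrays outside the detector's default "
                "spacer window would be undetectable ground truth"
            )
        if self.host_len <= 0 or self.virus_len_range[0] <= 0:
            raise ValueError("genome lengths must be positive")


@dataclass
class TruthBundle:
    """Planted ground truth for a synthetic community."""

    true_links: set[tuple[str, str, str]]          # (virus_id, host_id, host_genus)
    true_genus_of: dict[str, str]                  # virus_id -> genus label
    true_abundance: pd.DataFrame                   # genus x sample, columns sum to 1
    raw_abundance: pd.DataFrame                    # genus x sample, pre-normalization
    planted_spacers: list[tuple[str, str, str, int]]  # (host, spacer, virus, n_subs)


@dataclass
class SyntheticCommunity:
    config: SynthConfig
    viruses: dict[str, str]
    hosts: dict[str, str]
    host_lineages: pd.DataFrame       # genome_id, lineage (semicolon ranks)
    bin_membership: pd.DataFrame      # genome_id, bin_id
    annotations: pd.DataFrame         # gene_id, contig_id, has_vpf/pfam/ko, bitscore, lineage
    contig_lengths: dict[str, int]
    proteins: dict[str, str]          # gene_id -> aa sequence (viral genes only)
    gene_to_contig: dict[str, str]
    coverage: pd.DataFrame            # contig_id, sample_id, aligned_bases, dataset_size
    reads: dict[str, list[tuple[str, str]]]  # sample -> [(read_id, seq)]
    hic: pd.DataFrame                 # virus_id, bin_id, count
    truth: TruthBundle


def mutate_sequence(seq: str, n_subs: int, seed) -> str:
    """Substitute exactly ``n_subs`` positions, each to a different base."""
    if n_subs > len(seq):
        raise ValueError(f"n_subs={n_subs} exceeds sequence length {len(seq)}")
    if n_subs == 0:
        return seq
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def plant_crispr_array(genome: str, repeat: str, spacers: list[str], position: int) -> str:
    """Insert ``repeat·s1·repeat·s2·…·repeat`` into ``genome`` at ``position``."""
    if len(spacers) < 2:
        raise ValueError("need at least 2 spacers (3 repeat copies) to plant an array")
    if not 0 <= position <= len(genome):
        raise ValueError(f"position {position} out of range for genome of length {len(genome)}")
    array = repeat + "".join(s + repeat for s in spacers)
    return genome[:position] + array + genome[position:]


def _sample_spacer(rng: np.random.Generator, virus_seq: str, length: int) -> str:
    start = int(rng.integers(0, len(virus_seq) - length + 1))
    return virus_seq[start : start + length]


def _lineage(domain: str, idx: int, genus: str) -> str:
    return ";".join([domain, f"p__P{idx % 7}", f"c__C{idx % 5}", f"o__O{idx % 4}",
                     f"f__F{idx % 3}", genus])


def gen_community(cfg: SynthConfig) -> SyntheticCommunity:
    """Generate a full synthetic community; deterministic in ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- viral genomes, planted genera, and per-genus protein pools -------
    viruses: dict[str, str] = {}
    for i in range(cfg.n_viruses):
        length = int(rng.integers(cfg.virus_len_range[0], cfg.virus_len_range[1] + 1))
        viruses[f"vir{i:04d}"] = random_seq(rng, length)
    vir_ids = list(viruses)

    n_genera = max(1, cfg.n_viruses // 3)
    genus_of: dict[str, str] = {}
    for i, vid in enumerate(vir_ids):
        genus_of[vid] = f"VG{int(rng.integers(0, n_genera)):03d}" if n_genera > 1 else "VG000"
    # per-genus shared protein pool; members draw most genes from the pool
    pool: dict[str, list[str]] = {}
    for g in sorted(set(genus_of.values())):
        pool[g] = [
            "".join(np.array(list(_AA))[rng.integers(0, len(_AA), size=int(rng.integers(80, 200)))])
            for _ in range(15)
        ]

    proteins: dict[str, str] = {}
    gene_to_contig: dict[str, str] = {}
    ann_rows = []
    for vid in vir_ids:
        n_genes = max(1, int(round(cfg.genes_per_kb * len(viruses[vid]) / 1000)))
        shared = pool[genus_of[vid]]
        # proteins are emitted for at most 20 genes per contig so that the
        # genus pool dominates each contig's protein-cluster profile; the
        # remaining genes appear in the annotation table only
        n_prot = min(n_genes, 20)
        n_shared = min(len(shared), max(2, int(round(0.8 * n_prot))))
        picks = list(rng.choice(len(shared), size=n_shared, replace=False))
        for j in range(n_genes):
            gid = f"{vid}_g{j:03d}"
            gene_to_contig[gid] = vid
            if j < n_shared:
                proteins[gid] = shared[picks[j]]
            elif j < n_prot:  # private gene, unique to this contig
                proteins[gid] = "".join(
                    np.array(list(_AA))[rng.integers(0, len(_AA), size=int(rng.integers(80, 200)))])
            # viral-like annotation profile: VPF-rich, sparse Pfam/KO
            ann_rows.append(dict(
                gene_id=gid, contig_id=vid,
                has_vpf=int(rng.random() < 0.8),
                has_pfam=int(rng.random() < 0.15),
                has_ko=int(rng.random() < 0.05),
                bitscore=float(np.round(rng.uniform(50, 400), 1)),
                lineage="Viruses;Caudovirales",
            ))

    # --- hosts: lineage, CRISPR arrays planted with viral spacers ---------
    hosts: dict[str, str] = {}
    lineage_rows, bin_rows = [], []
    planted: list[tuple[str, str, str, int]] = []
    true_links: set[tuple[str, str, str]] = set()
    for h in range(cfg.n_hosts):
        hid = f"host{h:03d}"
        genome = random_seq(rng, cfg.host_len)
        domain = "Archaea" if rng.random() < cfg.archaea_fraction else "Bacteria"
        genus = f"g__H{h:03d}"
        lineage_rows.append(dict(genome_id=hid, lineage=_lineage(domain, h, genus)))
        bin_rows.append(dict(genome_id=hid, bin_id=f"bin{h:03d}"))

        if cfg.spacers_per_host >= 2 and cfg.n_viruses > 0:
            repeat = random_seq(rng, cfg.repeat_len)
            spacers, sources = [], []
            for k in range(cfg.spacers_per_host):
                src = vir_ids[int(rng.integers(0, len(vir_ids)))]
                while True:
                    length = int(rng.integers(cfg.spacer_len_range[0],
                                              cfg.spacer_len_range[1] + 1))
                    raw = _sample_spacer(rng, viruses[src], length)
                    n_subs = min(cfg.subs_per_spacer, len(raw))
                    mut = mutate_sequence(raw, n_subs, rng)
                    # detectability guard: the exact-repeat detector extends the
                    # repeat consensus when every spacer starts (or ends) with
                    # the same base; force the first two spacers to differ at
                    # both flanks so planted boundaries are unambiguous.
                    if k != 1 or (mut[0] != spacers[0][0] and mut[-1] != spacers[0][-1]):
                        break
                spacers.append(mut)
                sources.append(src)
                planted.append((hid, mut, src, n_subs))
                true_links.add((src, hid, genus))
            pos = int(rng.integers(1000, cfg.host_len - 1000))
            genome = plant_crispr_array(genome, repeat, spacers, pos)
        hosts[hid] = genome

        # host-like annotation profile (non-viral): KO/Pfam-rich, no VPF
        n_genes = max(1, int(round(cfg.genes_per_kb * len(genome) / 1000)))
        for j in range(n_genes):
            ann_rows.append(dict(
                gene_id=f"{hid}_g{j:03d}", contig_id=hid,
                has_vpf=0,
                has_pfam=int(rng.random() < 0.7),
                has_ko=int(rng.random() < 0.6),
                bitscore=float(np.round(rng.uniform(50, 400), 1)),
                lineage=lineage_rows[-1]["lineage"],
            ))

    # --- abundances: log-normal genus profiles with a forced core ---------
    genera = sorted(set(genus_of.values()))
    samples = [f"S{s + 1}" for s in range(cfg.n_samples)]
    raw = pd.DataFrame(
        np.exp(rng.normal(0.0, cfg.abundance_sigma, size=(len(genera), len(samples)))),
        index=genera, columns=samples)
    if genera and samples:
        n_core = max(1, int(round(cfg.core_fraction * len(genera))))
        core = set(rng.choice(genera, size=min(n_core, len(genera)), replace=False))
        for g in genera:
            if g in core or cfg.n_samples < 2:
                continue
            n_zero = int(rng.integers(1, cfg.n_samples))  # absent from >=1 sample
            for s in rng.choice(samples, size=n_zero, replace=False):
                raw.loc[g, s] = 0.0
    col_sums = raw.sum(axis=0)
    true_ab = raw.div(col_sums.where(col_sums > 0, 1.0), axis=1)

    # split genus abundance among member contigs by log-normal weights
    contig_ab = pd.DataFrame(0.0, index=vir_ids, columns=samples)
    for g in genera:
        members = [v for v in vir_ids if genus_of[v] == g]
        w = np.exp(rng.normal(0.0, 1.0, size=len(members)))
        w = w / w.sum()
        for m, wi in zip(members, w):
            contig_ab.loc[m] = true_ab.loc[g] * wi

    # --- coverage table: aligned_bases proportional to abundance x length -
    cov_rows = []
    depth_scale = 500.0  # mean mapped depth at relative abundance 1
    for vid in vir_ids:
        for s in samples:
            ab = float(contig_ab.loc[vid, s])
            cov_rows.append(dict(
                contig_id=vid, sample_id=s,
                aligned_bases=int(round(ab * len(viruses[vid]) * depth_scale)),
                dataset_size=cfg.dataset_size))

    # --- optional error-free reads per sample ------------------------------
    reads: dict[str, list[tuple[str, str]]] = {}
    if cfg.reads_per_sample > 0 and vir_ids:
        weights = (contig_ab.T * pd.Series({v: len(viruses[v]) for v in vir_ids})).T
        for s in samples:
            w = weights[s].to_numpy(dtype=float)
            if w.sum() == 0:
                w = np.ones(len(vir_ids))
            w = w / w.sum()
            picks = rng.choice(len(vir_ids), size=cfg.reads_per_sample, p=w)
            rlist = []
            for r, ci in enumerate(picks):
                vid = vir_ids[int(ci)]
                seq = viruses[vid]
                L = min(cfg.read_len, len(seq))
                start = int(rng.integers(0, len(seq) - L + 1))
                rlist.append((f"{s}_r{r:06d}", seq[start : start + L]))
            reads[s] = rlist

    # --- Hi-C contacts ------------------------------------------------------
    bin_of = {r["genome_id"]: r["bin_id"] for r in bin_rows}
    contacts: dict[tuple[str, str], int] = {}
    for vid, hid, _ in sorted(true_links):
        key = (vid, bin_of[hid])
        contacts[key] = contacts.get(key, 0) + cfg.hic_true_contacts
    bins = sorted(bin_of.values())
    if bins and vir_ids:
        for _ in range(cfg.hic_noise_contacts):
            key = (vir_ids[int(rng.integers(0, len(vir_ids)))],
                   bins[int(rng.integers(0, len(bins)))])
            contacts[key] = contacts.get(key, 0) + 1
    hic = pd.DataFrame(
        [dict(virus_id=v, bin_id=b, count=c) for (v, b), c in sorted(contacts.items())],
        columns=["virus_id", "bin_id", "count"])

    lengths = {**{v: len(s) for v, s in viruses.items()},
               **{h: len(s) for h, s in hosts.items()}}
    return SyntheticCommunity(
        config=cfg,
        viruses=viruses,
        hosts=hosts,
        host_lineages=pd.DataFrame(lineage_rows, columns=["genome_id", "lineage"]),
        bin_membership=pd.DataFrame(bin_rows, columns=["genome_id", "bin_id"]),
        annotations=pd.DataFrame(ann_rows),
        contig_lengths=lengths,
        proteins=proteins,
        gene_to_contig=gene_to_contig,
        coverage=pd.DataFrame(cov_rows, columns=["contig_id", "sample_id",
                                                 "aligned_bases", "dataset_size"]),
        reads=reads,
        hic=hic,
        truth=TruthBundle(
            true_links=true_links,
            true_genus_of=genus_of,
            true_abundance=true_ab,
            raw_abundance=raw,
            planted_spacers=planted,
        ),
    )


def write_community(comm: SyntheticCommunity, outdir) -> dict[str, str]:
    """Write all community tables/FASTA under ``outdir``; returns path map."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _tsv(name, df):
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)

    write_fasta(out / "viruses.fasta", comm.viruses)
    write_fasta(out / "hosts.fasta", comm.hosts)
    paths["viruses.fasta"] = str(out / "viruses.fasta")
    paths["hosts.fasta"] = str(out / "hosts.fasta")
    _tsv("annotations.tsv", comm.annotations)
    _tsv("coverage.tsv", comm.coverage)
    _tsv("hic_contacts.tsv", comm.hic)
    _tsv("host_lineages.tsv", comm.host_lineages)
    _tsv("bin_membership.tsv", comm.bin_membership)
    _tsv("truth_links.tsv", pd.DataFrame(
        sorted(comm.truth.true_links), columns=["virus_id", "host_id", "host_genus"]))
    _tsv("truth_genus.tsv", pd.DataFrame(
        sorted(comm.truth.true_genus_of.items()), columns=["virus_id", "genus"]))
    _tsv("truth_spacers.tsv", pd.DataFrame(
        comm.truth.planted_spacers,
        columns=["host_id", "spacer", "source_virus", "n_substitutions"]))
    ab = comm.truth.true_abundance.reset_index(names="genus")
    _tsv("truth_abundance.tsv", ab)
    from ._seqs import write_fasta as _wf  # proteins FASTA
    _wf(out / "proteins.faa", comm.proteins)
    paths["proteins.faa"] = str(out / "proteins.faa")
    _tsv("gene_map.tsv", pd.DataFrame(
        sorted(comm.gene_to_contig.items()), columns=["gene_id", "contig_id"]))
    if comm.reads:
        rows = [dict(sample_id=s, read_id=rid, seq=seq)
                for s, rl in comm.reads.items() for rid, seq in rl]
        _tsv("reads.tsv", pd.DataFrame(rows))
    cfg = dataclasses.asdict(comm.config)
    cfg["virus_len_range"] = list(cfg["virus_len_range"])
    cfg["spacer_len_range"] = list(cfg["spacer_len_range"])
    import json

    (out / "config.json").write_text(json.dumps(cfg, indent=1))
    paths["config.json"] = str(out / "config.json")
    return paths
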