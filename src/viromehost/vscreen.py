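"""Viral-contig identification from gene-annotation hit tables.

Two routes are implemented and merged, mirroring common virome practice:

1. A viral-protein-family (VPF) screen: contigs longer than 5 kb with at
   least five VPF-hit genes are retained, then must satisfy composition
   criteria on the fractions of genes with KO / Pfam / VPF hits.
2. A taxonomy route: a lowest-common-ancestor (LCA) consensus over
   per-contig database hits; contigs whose consensus lineage is viral count
   as viral.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MIN_LENGTH_BP = 5000   # strict: contig must be longer than this
MIN_VPF_HITS = 5


@dataclass(frozen=True)
class ContigAnnotation:
    """Per-contig gene-hit counts used by the VPF screen."""

    contig_id: str
    length: int
    n_genes: int
    n_ko: int
    n_pfam: int
    n_vpf: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: length must be positive")
        for name in ("n_ko", "n_pfam", "n_vpf"):
            if getattr(self, name) > self.n_genes:
                raise ValueError(f"{self.contig_id}: {name} exceeds n_genes")


@dataclass(frozen=True)
class TaxHit:
    contig_id: str
    lineage: tuple[str, ...]   # ordered ranks, domain -> species
    bitscore: float

    def __post_init__(self):
        if not self.lineage:
            raise ValueError("lineage must be non-empty")


def screen_vpf(ann: ContigAnnotation, criteria_mode: str = "any") -> bool:
    """Decide whether a contig is viral from its annotation counts.

    Hard gates: length > 5 kb and >= 5 VPF-hit genes. Then three
    composition criteria are evaluated on gene fractions:

    - C1: KO fraction <= 20%, Pfam fraction <= 40%, VPF fraction >= 10%
    - C2: more VPF-hit genes than Pfam-hit genes
    - C3: VPF fraction >= 60%

    ``criteria_mode`` selects whether any one criterion suffices (``"any"``,
    default) or all three must hold (``"all"``).
    """
    if criteria_mode not in ("any", "all"):
        raise ValueError(f"criteria_mode must be 'any' or 'all', got {criteria_mode!r}")
    if ann.length <= MIN_LENGTH_BP or ann.n_vpf < MIN_VPF_HITS or ann.n_genes == 0:
        return False
    n = ann.n_genes
    c1 = ann.n_ko / n <= 0.20 and ann.n_pfam / n <= 0.40 and ann.n_vpf / n >= 0.10
    c2 = ann.n_vpf > ann.n_pfam
    c3 = ann.n_vpf / n >= 0.60
    return (c1 or c2 or c3) if criteria_mode == "any" else (c1 and c2 and c3)


def annotations_from_genes(genes: pd.DataFrame,
                           contig_lengths: dict[str, int]) -> list[ContigAnnotation]:
    """Aggregate a per-gene hit table into per-contig annotation counts.

    ``genes`` needs columns contig_id, has_vpf, has_pfam, has_ko (0/1 flags).
    """
    out = []
    agg = genes.groupby("contig_id").agg(
        n_genes=("contig_id", "size"), n_ko=("has_ko", "sum"),
        n_pfam=("has_pfam", "sum"), n_vpf=("has_vpf", "sum"))
    for cid, row in agg.iterrows():
        out.append(ContigAnnotation(
            contig_id=str(cid), length=int(contig_lengths[str(cid)]),
            n_genes=int(row.n_genes), n_ko=int(row.n_ko),
            n_pfam=int(row.n_pfam), n_vpf=int(row.n_vpf)))
    return out


def lca_assign(hits: list[TaxHit], top_percent: float = 0.10) -> str:
    """Consensus lineage of the near-top-scoring hits of one contig.

    Hits scoring within ``top_percent`` of the maximum bitscore are retained;
    the result is their longest common lineage prefix joined by ';', or
    ``"unassigned"`` when no common prefix exists (or there are no hits).
    """
    if not 0 < top_percent <= 1:
        raise ValueError("top_percent must be in (0, 1]")
    if not hits:
        return "unassigned"
    best = max(h.bitscore for h in hits)
    kept = [h.lineage for h in hits if h.bitscore >= (1 - top_percent) * best]
    prefix = list(kept[0])
    for lin in kept[1:]:
        i = 0
        while i < min(len(prefix), len(lin)) and prefix[i] == lin[i]:
            i += 1
        prefix = prefix[:i]
    return ";".join(prefix) if prefix else "unassigned"


def merge_viral_sets(set_a, set_b) -> list[str]:
    """Union of two viral-contig id sets, deduplicated and sorted."""
    return sorted(set(set_a) | set(set_b))


def compute_n50(lengths) -> int:
    """Largest length L such that contigs of length >= L hold half the bases."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("compute_n50 requires a non-empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for x in lengths:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def screen_table(genes: pd.DataFrame, contig_lengths: dict[str, int],
                 criteria_mode: str = "any") -> pd.DataFrame:
    """Per-contig screening decision log (one row per contig)."""
    rows = []
    for ann in annotations_from_genes(genes, contig_lengths):
        rows.append(dict(
            contig_id=ann.contig_id, length=ann.length, n_genes=ann.n_genes,
            n_ko=ann.n_ko, n_pfam=ann.n_pfam, n_vpf=ann.n_vpf,
            viral=screen_vpf(ann, criteria_mode)))
    return pd.DataFrame(rows, columns=["contig_id", "length", "n_genes",
                                       "n_ko", "n_pfam", "n_vpf", "viral"])
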