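"""Genus-level clustering of viral contigs by shared gene content.

Genes are first grouped into protein clusters (PCs) by greedy centroid
clustering on global identity; pairs of contigs are then scored by the
hypergeometric tail probability of their shared-PC count (the smaller the
probability that the overlap arises by chance, the stronger the edge);
connected components of the significant-edge graph are the viral genera.
A greedy dereplicator collapses near-identical contigs at configurable
identity/coverage thresholds (defaults 90% / 80% of the shorter sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy.special import gammaln, logsumexp

from ._seqs import kmer_index


@dataclass(frozen=True)
class ProteinCluster:
    pc_id: str
    members: tuple[tuple[str, str], ...]   # (contig_id, gene_id)


def _global_identity(a: str, b: str) -> float:
    """Edit-distance identity over the longer sequence (global alignment)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_proteins(proteins: list[tuple[str, str]], contig_of: dict[str, str],
                     id_threshold: float = 0.9) -> list[ProteinCluster]:
    """Greedy centroid clustering of proteins at global identity threshold.

    Proteins are sorted by length (desc, then id for determinism); each joins
    the first existing centroid with identity >= threshold, else founds a new
    cluster whose centroid it becomes.
    """
    if not 0 < id_threshold <= 1:
        raise ValueError("id_threshold must be in (0, 1]")
    order = sorted(proteins, key=lambda p: (-len(p[1]), p[0]))
    centroids: list[str] = []           # centroid sequences
    members: list[list[str]] = []       # gene ids per cluster
    for gid, seq in order:
        for ci, cen in enumerate(centroids):
            if _global_identity(seq, cen) >= id_threshold:
                members[ci].append(gid)
                break
        else:
            centroids.append(seq)
            members.append([gid])
    return [
        ProteinCluster(
            pc_id=f"PC{ci:05d}",
            members=tuple(sorted((contig_of[g], g) for g in mem)))
        for ci, mem in enumerate(members)
    ]


def shared_pc_significance(n_a: int, n_b: int, shared: int, n_total: int) -> float:
    """−log10 P(X >= shared) for X ~ Hypergeometric(n_total, n_a, n_b).

    The tail is evaluated with exact log-factorial arithmetic. A shared count
    of 0 scores 0 (no evidence of relatedness).
    """
    if not (0 <= shared <= min(n_a, n_b) <= n_total) or max(n_a, n_b) > n_total:
        raise ValueError(
            f"invalid counts: shared={shared}, n_a={n_a}, n_b={n_b}, n_total={n_total}")
    if shared == 0:
        return 0.0

    def log_c(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    ks = np.arange(shared, min(n_a, n_b) + 1)
    log_terms = log_c(n_a, ks) + log_c(n_total - n_a, n_b - ks) - log_c(n_total, n_b)
    log_p = min(0.0, float(logsumexp(log_terms)))
    return -log_p / np.log(10.0)


def assign_genera(contig_ids: list[str], pcs: list[ProteinCluster],
                  score_threshold: float = 3.0) -> dict[str, str]:
    """Partition contigs into genera via significant shared-PC edges.

    Edges join contig pairs whose shared-PC hypergeometric score reaches
    ``score_threshold``; genera are connected components of size >= 2,
    labelled by their lexicographically smallest member id. Size-1
    components are labelled ``"singleton"``.
    """
    if score_threshold <= 0:
        raise ValueError("score_threshold must be > 0")
    n_total = len(pcs)
    pcs_of: dict[str, set[str]] = {c: set() for c in contig_ids}
    for pc in pcs:
        for contig, _gene in pc.members:
            if contig in pcs_of:
                pcs_of[contig].add(pc.pc_id)

    parent = {c: c for c in contig_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ids = sorted(contig_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = len(pcs_of[a] & pcs_of[b])
            if shared == 0 or n_total == 0:
                continue
            score = shared_pc_significance(len(pcs_of[a]), len(pcs_of[b]),
                                           shared, n_total)
            if score >= score_threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    comps: dict[str, list[str]] = {}
    for c in ids:
        comps.setdefault(find(c), []).append(c)
    out = {}
    for root, mem in comps.items():
        label = min(mem) if len(mem) >= 2 else "singleton"
        for c in mem:
            out[c] = label
    return out


def dereplicate(contigs: dict[str, str], id_threshold: float = 0.90,
                cov_threshold: float = 0.80, prefilter_k: int = 15):
    """Greedy longest-first dereplication of nucleotide contigs.

    A contig is absorbed by an existing (longer) representative when an
    alignment covers at least ``cov_threshold`` of the shorter sequence at
    ``id_threshold`` identity; candidate representatives are prefiltered by
    a shared exact ``prefilter_k``-mer. Returns (representative ids,
    membership map contig -> representative).
    """
    for t in (id_threshold, cov_threshold):
        if not 0 < t <= 1:
            raise ValueError("thresholds must be in (0, 1]")
    order = sorted(contigs, key=lambda c: (-len(contigs[c]), c))
    reps: list[str] = []
    kmer_owner: dict[str, set[str]] = {}
    membership: dict[str, str] = {}
    for cid in order:
        seq = contigs[cid]
        cand: set[str] = set()
        for i in range(0, max(1, len(seq) - prefilter_k + 1)):
            owners = kmer_owner.get(seq[i : i + prefilter_k])
            if owners:
                cand |= owners
        assigned = None
        for rep in sorted(cand):
            rseq = contigs[rep]
            # infix alignment of the shorter onto the representative: the
            # whole query aligns (coverage 1 >= cov_threshold); identity is
            # edit-distance based over the query length
            res = edlib.align(seq, rseq, mode="HW", task="distance",
                              k=int(len(seq) * (1 - id_threshold)) + 1)
            d = res["editDistance"]
            if d >= 0 and 1.0 - d / len(seq) >= id_threshold:
                assigned = rep
                break
        if assigned is None:
            reps.append(cid)
            membership[cid] = cid
            for i in range(0, max(1, len(seq) - prefilter_k + 1)):
                kmer_owner.setdefault(seq[i : i + prefilter_k], set()).add(cid)
        else:
            membership[cid] = assigned
    return reps, membership
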