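"""Coverage-based abundance, diversity, ordination and core-virome analysis.

Relative abundance follows the aligned-bases convention: per-contig coverage
is aligned bases divided by contig length, normalized by dataset size; a
contig's share is its normalized coverage over the per-sample total, and a
genus's abundance is the sum of its members' shares. Shannon diversity uses
natural logarithms; Pielou evenness divides by ln(S) over detected genera.
Ordination is classical PCoA (metric multidimensional scaling) of the
Bray–Curtis dissimilarity matrix; negative eigenvalues are reported rather
than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis

from ._seqs import kmer_index


@dataclass(frozen=True)
class CoverageRecord:
    contig_id: str
    sample_id: str
    aligned_bases: int
    dataset_size: int

    def __post_init__(self):
        if self.aligned_bases < 0:
            raise ValueError("aligned_bases must be >= 0")
        if self.dataset_size <= 0:
            raise ValueError("dataset_size must be > 0")


def avg_norm_coverage(rec: CoverageRecord, contig_length: int) -> float:
    """(aligned bases / contig length) / dataset size."""
    if contig_length <= 0:
        raise ValueError("contig_length must be > 0")
    return rec.aligned_bases / contig_length / rec.dataset_size


@dataclass(frozen=True)
class ReadHit:
    read_id: str
    contig_id: str
    start: int          # half-open interval on the contig
    end: int
    aligned_len: int


def _best_read_window(read: str, contig: str, diag: int, min_len: int,
                      min_identity: float):
    a0 = max(0, -diag)
    c0 = a0 + diag
    m = min(len(read) - a0, len(contig) - c0)
    if m < min_len:
        return None
    mism = np.frombuffer(read[a0 : a0 + m].encode(), np.uint8) != \
        np.frombuffer(contig[c0 : c0 + m].encode(), np.uint8)
    pref = np.concatenate(([0], np.cumsum(mism)))
    for L in range(m, min_len - 1, -1):     # prefer the longest passing window
        for s in range(0, m - L + 1):
            mm = int(pref[s + L] - pref[s])
            if (L - mm) / L >= min_identity:
                return (L, c0 + s)
    return None


def toy_map_reads(reads: list[tuple[str, str]], contigs: dict[str, str],
                  length_fraction: float = 0.8, similarity: float = 0.9,
                  k: int = 21) -> list[ReadHit]:
    """Exact-seed ungapped read mapper for synthetic (low-error) reads.

    A read counts for a contig when a window of at least ``length_fraction``
    of its length aligns at ``similarity`` identity; the aligned window
    length accumulates into coverage. Seeds are exact ``k``-mers taken at
    three read offsets, so error-free reads are always found and reads more
    divergent than the thresholds are rejected.
    """
    indexes = {cid: kmer_index(seq, k) for cid, seq in contigs.items()}
    hits: list[ReadHit] = []
    for rid, read in reads:
        if len(read) < k:
            continue
        min_len = int(np.ceil(length_fraction * len(read)))
        best = None
        offsets = sorted({0, (len(read) - k) // 2, len(read) - k})
        for cid in sorted(contigs):
            index = indexes[cid]
            diags = {pos - off for off in offsets
                     for pos in index.get(read[off : off + k], ())}
            for d in sorted(diags):
                res = _best_read_window(read, contigs[cid], d, min_len, similarity)
                if res and (best is None or res[0] > best[0]):
                    best = (res[0], cid, res[1])
        if best:
            L, cid, start = best
            hits.append(ReadHit(rid, cid, start, start + L, L))
    return hits


def coverage_from_hits(hits: list[ReadHit], sample_id: str,
                       dataset_size: int) -> list[CoverageRecord]:
    per_contig: dict[str, int] = {}
    for h in hits:
        per_contig[h.contig_id] = per_contig.get(h.contig_id, 0) + h.aligned_len
    return [CoverageRecord(cid, sample_id, ab, dataset_size)
            for cid, ab in sorted(per_contig.items())]


def relative_abundance(coverage: pd.DataFrame, contig_lengths: dict[str, int],
                       genus_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Genus × sample relative-abundance matrix (columns sum to 1).

    ``coverage`` needs columns contig_id, sample_id, aligned_bases,
    dataset_size. Without a genus map each contig is its own entity.
    """
    df = coverage.copy()
    df["norm_cov"] = [
        avg_norm_coverage(
            CoverageRecord(r.contig_id, r.sample_id, int(r.aligned_bases),
                           int(r.dataset_size)),
            contig_lengths[r.contig_id])
        for r in df.itertuples()
    ]
    df["entity"] = [genus_of.get(c, c) if genus_of else c for c in df["contig_id"]]
    mat = df.pivot_table(index="entity", columns="sample_id", values="norm_cov",
                         aggfunc="sum", fill_value=0.0)
    sums = mat.sum(axis=0)
    return mat.div(sums.where(sums > 0, 1.0), axis=1)


def shannon(p) -> float:
    """Shannon diversity H' in nats (zeros dropped)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("abundance vector must sum to 1")
    return float(-(p * np.log(p)).sum())


def pielou(p) -> float:
    """Pielou evenness J' = H'/ln(S); 0 for a single-entity community."""
    p = np.asarray(p, dtype=float)
    s = int((p > 0).sum())
    if s <= 1:
        return 0.0
    return shannon(p) / np.log(s)


def bray_curtis(u, v) -> float:
    return float(_braycurtis(np.asarray(u, float), np.asarray(v, float)))


def bray_curtis_matrix(mat: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis between the columns (samples) of ``mat``."""
    cols = list(mat.columns)
    D = np.zeros((len(cols), len(cols)))
    for i, j in combinations(range(len(cols)), 2):
        D[i, j] = D[j, i] = bray_curtis(mat.iloc[:, i], mat.iloc[:, j])
    return pd.DataFrame(D, index=cols, columns=cols)


def pcoa(D, k: int | None = None):
    """Classical principal-coordinate analysis of a dissimilarity matrix.

    Eigendecomposes the double-centered matrix −½·J·D²·J. Returns
    (coordinates, eigenvalues): coordinates span the top-``k`` positive
    eigenvalues; the full eigenvalue spectrum, including any negative
    values from non-Euclidean dissimilarities, is returned unmodified.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be a square symmetric dissimilarity matrix")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if k is not None:
        coords = coords[:, :k]
    return coords, eigvals


def _horizontal_coverage(intervals: list[tuple[int, int]]) -> int:
    covered = 0
    last = -1
    for s, e in sorted(intervals):
        if e <= last:
            continue
        covered += e - max(s, last)
        last = e
    return covered


def rarefaction(reads: list[tuple[str, str]], contigs: dict[str, str],
                fractions, seed: int = 0, min_reads: int = 1,
                min_horizontal_cov: float = 0.10,
                length_fraction: float = 0.8, similarity: float = 0.9,
                hits: list[ReadHit] | None = None) -> pd.DataFrame:
    """Detected-contig counts under read subsampling (without replacement).

    Reads are mapped once; at each fraction a random subset is drawn and a
    contig counts as detected with at least ``min_reads`` mapped reads and
    horizontal coverage of at least ``min_horizontal_cov`` of its length.
    Precomputed ``hits`` (from :func:`toy_map_reads` on the same reads) can
    be supplied to amortise mapping across repeated subsampling runs.
    """
    rng = np.random.default_rng(seed)
    if hits is None:
        hits = toy_map_reads(reads, contigs, length_fraction, similarity)
    by_read = {h.read_id: h for h in hits}
    read_ids = [rid for rid, _ in reads]
    rows = []
    for f in fractions:
        n = int(round(f * len(read_ids)))
        chosen = rng.choice(read_ids, size=min(n, len(read_ids)), replace=False) \
            if n > 0 else []
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for rid in chosen:
            h = by_read.get(rid)
            if h:
                per_contig.setdefault(h.contig_id, []).append((h.start, h.end))
        detected = sum(
            1 for cid, iv in per_contig.items()
            if len(iv) >= min_reads
            and _horizontal_coverage(iv) >= min_horizontal_cov * len(contigs[cid]))
        rows.append(dict(fraction=float(f), n_reads=int(n), detected=int(detected)))
    return pd.DataFrame(rows, columns=["fraction", "n_reads", "detected"])


def core_shared_genera(presence: pd.DataFrame):
    """Exclusive intersection counts (UpSet semantics) and the core set.

    ``presence`` is a boolean genus × sample frame. Every genus contributes
    to exactly one intersection — the full set of samples it occurs in; the
    core set holds the genera present in all samples.
    """
    samples = tuple(presence.columns)
    counts: dict[frozenset, int] = {}
    core = []
    for genus, row in presence.iterrows():
        present = frozenset(s for s in samples if bool(row[s]))
        if not present:
            continue
        counts[present] = counts.get(present, 0) + 1
        if len(present) == len(samples):
            core.append(genus)
    return counts, sorted(core)


def rank_abundance(p: pd.Series, threshold: float = 0.001):
    """Descending abundance ranking and the first rank below ``threshold``.

    Ties sort by genus label. The crossing rank is 1-based; when no entry
    drops below the threshold it is len(p)+1 (a sentinel past the end).
    """
    s = p.iloc[np.lexsort((p.index.astype(str), -p.to_numpy(dtype=float)))] \
        if len(p) else p
    below = np.nonzero(s.to_numpy() < threshold)[0]
    crossing = int(below[0]) + 1 if below.size else len(s) + 1
    return s, crossing
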