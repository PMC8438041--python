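"""Independent reference implementations used only to check the package.

These deliberately avoid the production code paths: the matcher oracle is a
brute-force scan over every ungapped window, the hypergeometric oracle is
exhaustive subset enumeration with exact rationals, and the screening oracle
restates the decision rule with ``Fraction`` arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_best(spacer: str, contig: str, min_identity: float = 0.97,
                     min_coverage: float = 0.90, max_mismatches: int = 1):
    """Best passing ungapped alignment over every (offset, window) pair.

    Scans both strands, every spacer start, every contig start and every
    window length >= ceil(min_coverage * |spacer|). Returns
    (matching_bases, mismatches, length) of the winner under the order
    "matching bases desc, mismatches asc", or None when nothing passes.
    """
    n = len(spacer)
    m = len(contig)
    min_len = math.ceil(min_coverage * n)
    if min_len > m:
        return None
    cvec = np.frombuffer(contig.encode(), np.uint8)
    best = None
    for q in (spacer, rc(spacer)):
        svec = np.frombuffer(q.encode(), np.uint8)
        mism = (svec[:, None] != cvec[None, :]).astype(np.int32)
        # cumulative mismatches along each diagonal, zero-padded
        P = np.zeros((n + 1, m + 1), dtype=np.int32)
        for i in range(n):
            P[i + 1, 1:] = mism[i] + P[i, :-1]
        for a in range(n):
            for L in range(min_len, n - a + 1):
                if L > m:
                    break
                mm = P[a + L, L:] - P[a, : m - L + 1]
                ok = mm <= max_mismatches
                matches = L - mm
                ok &= matches / L >= min_identity
                if not ok.any():
                    continue
                mb = int(matches[ok].max())
                best_mm = int(mm[ok & (matches == mb)].min())
                cand = (mb, -best_mm, L)
                if best is None or cand[:2] > best[:2]:
                    best = cand
    if best is None:
        return None
    mb, neg_mm, L = best
    return mb, -neg_mm, mb - neg_mm  # matching bases, mismatches, length


def hypergeom_tail_enum(n_a: int, n_b: int, shared: int, n_total: int) -> Fraction:
    """P(|A ∩ B| >= shared) by enumerating every size-n_b subset B."""
    universe = range(n_total)
    a_set = set(range(n_a))
    hits = total = 0
    for b in combinations(universe, n_b):
        total += 1
        if len(a_set.intersection(b)) >= shared:
            hits += 1
    return Fraction(hits, total)


def screen_oracle(length: int, n_genes: int, n_ko: int, n_pfam: int, n_vpf: int,
                  mode: str) -> bool:
    """Viral/not-viral decision restated with exact rational arithmetic."""
    if length <= 5000 or n_vpf < 5 or n_genes == 0:
        return False
    c1 = (Fraction(n_ko, n_genes) <= Fraction(1, 5)
          and Fraction(n_pfam, n_genes) <= Fraction(2, 5)
          and Fraction(n_vpf, n_genes) >= Fraction(1, 10))
    c2 = n_vpf > n_pfam
    c3 = Fraction(n_vpf, n_genes) >= Fraction(3, 5)
    return (c1 or c2 or c3) if mode == "any" else (c1 and c2 and c3)


def lca_oracle(lineages: list[tuple[str, ...]]) -> tuple[str, ...]:
    """Longest common prefix by rank-wise unanimity."""
    out = []
    for ranks in zip(*lineages):
        if len(set(ranks)) != 1:
            break
        out.append(ranks[0])
    return tuple(out)
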