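"""CRISPR-spacer host prediction, benchmarking, and the error model.

The matcher emulates a BLASTn-short search specialised to short spacers:
exact 11-mer seeding on both strands followed by ungapped evaluation of
every candidate diagonal. A hit passes when the alignment reaches the
identity threshold over its own length, covers the required fraction of the
spacer, and stays within the mismatch cap (defaults 97% / 90% / 1, the
operating point at which the reference benchmark reports 93.4% precision
and 22.4% recall). Among passing alignments the one with the most matching
bases wins; ties prefer higher identity, then the + strand, then the
leftmost contig position.

Ungapped semantics keep the matcher exactly equivalent to a brute-force
sliding-window search, which the test suite exploits as an oracle. With the
default thresholds the 11-mer seed is provably lossless: a full-length
1-mismatch hit needs >= 34 aligned bases to reach 97% identity, and any
31-base window with at most one mismatch contains an exact 15-mer run.
When a caller relaxes thresholds far enough that the pigeonhole guarantee
drops below the word size, the matcher transparently falls back to scanning
every diagonal, so benchmark grids remain exact.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._seqs import kmer_index, random_seq, revcomp
from .crisprdb import SpacerRecord


@dataclass(frozen=True)
class MatchThresholds:
    min_identity: float = 0.97
    min_coverage: float = 0.90
    max_mismatches: int = 1
    word_size: int = 11


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    contig_id: str
    length: int            # alignment length, bp
    mismatches: int
    contig_start: int      # 0-based half-open on the + strand of the contig
    contig_end: int
    spacer_start: int
    strand: str            # '+' or '-'
    spacer_len: int

    @property
    def identity(self) -> float:
        return (self.length - self.mismatches) / self.length

    @property
    def coverage(self) -> float:
        return self.length / self.spacer_len

    @property
    def matching_bases(self) -> int:
        return self.length - self.mismatches


@dataclass(frozen=True)
class VirusHostLink:
    contig_id: str
    genome_id: str
    lineage: str
    match: SpacerMatch
    spacer_id: str
    primary: bool = False

    @property
    def genus(self) -> str:
        return self.lineage.split(";")[-1]

    @property
    def domain(self) -> str:
        return self.lineage.split(";")[0]


class BenchmarkResult(NamedTuple):
    min_identity: float
    min_coverage: float
    max_mismatches: int
    precision: float | None    # percent; None when there are no predictions
    recall: float              # percent, correct-genus definition
    recall_any: float          # percent of refs with any prediction
    n_predictions: int


class RoundedValue(NamedTuple):
    """A reported quantity kept unrounded alongside its display rounding."""

    value: float
    rounded: int


def _best_on_diagonal(spacer: str, contig: str, diag: int, thr: MatchThresholds,
                      min_len: int):
    """Best passing ungapped window on one diagonal (contig_pos - spacer_pos).

    Returns (matching_bases, mismatches, length, contig_start, spacer_start)
    or None. Window count per diagonal is bounded by |spacer|^2 so this is
    cheap for spacers <= 48 bp.
    """
    a0 = max(0, -diag)                       # first spacer index on diagonal
    c0 = a0 + diag
    m = min(len(spacer) - a0, len(contig) - c0)
    if m < min_len:
        return None
    mism = np.frombuffer(spacer[a0 : a0 + m].encode(), dtype=np.uint8) != \
        np.frombuffer(contig[c0 : c0 + m].encode(), dtype=np.uint8)
    pref = np.concatenate(([0], np.cumsum(mism)))
    best = None
    n = len(spacer)
    for L in range(m, min_len - 1, -1):
        if best is not None and L < best[0]:
            break  # even a perfect window of this length cannot beat or tie best
        for s in range(0, m - L + 1):
            mm = int(pref[s + L] - pref[s])
            if mm > thr.max_mismatches:
                continue
            if (L - mm) / L < thr.min_identity:
                continue
            cand = (L - mm, -mm, L, c0 + s, a0 + s)
            if best is None or cand[:2] > best[:2]:
                best = cand
    return best


def _match_one_strand(spacer: str, contig: str, thr: MatchThresholds,
                      index: dict[str, list[int]], min_len: int):
    w = thr.word_size
    # mismatches in any passing window are capped both by the explicit cap and
    # by the identity threshold over the longest possible (full-spacer) window
    eff_mm = min(thr.max_mismatches, int(len(spacer) * (1 - thr.min_identity)))
    guaranteed = (min_len - eff_mm) // (eff_mm + 1)
    if guaranteed >= w:
        diags: set[int] = set()
        for i in range(len(spacer) - w + 1):
            for pos in index.get(spacer[i : i + w], ()):
                diags.add(pos - i)
        cand_diags = sorted(diags)
    else:  # relaxed thresholds: seed no longer lossless, scan every diagonal
        cand_diags = range(-(len(spacer) - min_len), len(contig) - min_len + 1)
    best = None
    for d in cand_diags:
        res = _best_on_diagonal(spacer, contig, d, thr, min_len)
        if res is None:
            continue
        key = (res[0], res[1], -res[3])      # matches desc, mm asc, leftmost
        if best is None or key > best[0]:
            best = (key, res)
    return best


def match_spacer(spacer: str, contig: str, thr: MatchThresholds | None = None,
                 spacer_id: str = "spacer", contig_id: str = "contig",
                 _index: dict[str, list[int]] | None = None) -> SpacerMatch | None:
    """Best passing ungapped alignment of a spacer on a contig, both strands."""
    thr = thr or MatchThresholds()
    if len(spacer) < thr.word_size:
        raise ValueError(
            f"spacer {spacer_id!r} shorter than the seed word size {thr.word_size}")
    min_len = math.ceil(thr.min_coverage * len(spacer))
    if min_len > len(contig):
        return None
    index = _index if _index is not None else kmer_index(contig, thr.word_size)

    results = []
    for strand, query in (("+", spacer), ("-", revcomp(spacer))):
        hit = _match_one_strand(query, contig, thr, index, min_len)
        if hit is not None:
            (mb, neg_mm, _negpos), (mb2, _nm, L, cstart, sstart) = hit
            results.append((mb, neg_mm, 0 if strand == "+" else 1, cstart,
                            L, sstart, strand))
    if not results:
        return None
    results.sort(key=lambda r: (-r[0], -r[1], r[2], r[3]))
    mb, neg_mm, _s, cstart, L, sstart, strand = results[0]
    if strand == "-":
        # report spacer_start on the original spacer orientation
        sstart = len(spacer) - (sstart + L)
    return SpacerMatch(
        spacer_id=spacer_id, contig_id=contig_id, length=L, mismatches=-neg_mm,
        contig_start=cstart, contig_end=cstart + L, spacer_start=sstart,
        strand=strand, spacer_len=len(spacer))


def predict_hosts(contigs: dict[str, str], spacer_db: list[SpacerRecord],
                  thr: MatchThresholds | None = None) -> list[VirusHostLink]:
    """Evaluate every spacer against every contig; emit virus→host links.

    Passing matches are collapsed to one link per (contig, host genome),
    keeping the best match per pair; per contig, the globally best hit is
    flagged primary (matching bases desc, identity desc, spacer_id asc).
    """
    thr = thr or MatchThresholds()
    if not spacer_db:
        raise ValueError("spacer database is empty")
    links: list[VirusHostLink] = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        index = kmer_index(seq, thr.word_size)
        per_genome: dict[str, tuple] = {}
        for rec in spacer_db:
            m = match_spacer(rec.sequence, seq, thr, spacer_id=rec.spacer_id,
                             contig_id=cid, _index=index)
            if m is None:
                continue
            key = (-m.matching_bases, -m.identity, rec.spacer_id)
            prev = per_genome.get(rec.genome_id)
            if prev is None or key < prev[0]:
                per_genome[rec.genome_id] = (key, m, rec)
        if not per_genome:
            continue
        ranked = sorted(per_genome.values(), key=lambda t: t[0])
        for rank, (_k, m, rec) in enumerate(ranked):
            links.append(VirusHostLink(
                contig_id=cid, genome_id=rec.genome_id, lineage=rec.lineage,
                match=m, spacer_id=rec.spacer_id, primary=(rank == 0)))
    return links


def benchmark_thresholds(ref_viruses: dict[str, tuple[str, str]],
                         spacer_db: list[SpacerRecord],
                         grid: list[MatchThresholds]) -> list[BenchmarkResult]:
    """Precision/recall of host prediction over a threshold grid.

    ``ref_viruses`` maps virus id -> (sequence, known host genus). Precision
    is the percentage of predicted (virus, genus) links whose genus is the
    known one; recall is the percentage of reference viruses with at least
    one correct-genus prediction (``recall_any`` counts any prediction).
    With zero predictions at a grid point precision is undefined (None).
    """
    if any(not v[1] for v in ref_viruses.values()):
        raise ValueError("every reference virus needs a known host genus")
    contigs = {vid: seq for vid, (seq, _g) in ref_viruses.items()}
    out = []
    for thr in grid:
        links = predict_hosts(contigs, spacer_db, thr) if spacer_db else []
        preds = {(l.contig_id, l.genus) for l in links}
        correct = {(v, g) for v, g in preds if ref_viruses[v][1] == g}
        n_ref = len(ref_viruses)
        recall = 100.0 * len({v for v, _ in correct}) / n_ref if n_ref else 0.0
        recall_any = 100.0 * len({v for v, _ in preds}) / n_ref if n_ref else 0.0
        precision = 100.0 * len(correct) / len(preds) if preds else None
        out.append(BenchmarkResult(thr.min_identity, thr.min_coverage,
                                   thr.max_mismatches, precision, recall,
                                   recall_any, len(preds)))
    return out


def random_null_recall(spacer_db: list[SpacerRecord], n_seqs: int,
                       lengths, thr: MatchThresholds | None = None,
                       seed: int = 0, n_replicates: int = 3,
                       seq_sampler=None) -> float:
    """Fraction of random sequences with >= 1 passing spacer hit (mean over
    replicate random databases); the empirical chance-hit rate.

    ``seq_sampler(rng, length) -> str`` overrides the uniform-random sequence
    source (used in tests with adversarial inputs)."""
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    thr = thr or MatchThresholds()
    rng = np.random.default_rng(seed)
    lengths = list(lengths)
    sampler = seq_sampler or random_seq
    fractions = []
    for _rep in range(n_replicates):
        n_hit = 0
        for i in range(n_seqs):
            L = int(lengths[i % len(lengths)])
            seq = sampler(rng, L)
            index = kmer_index(seq, thr.word_size)
            for rec in spacer_db:
                if match_spacer(rec.sequence, seq, thr, _index=index) is not None:
                    n_hit += 1
                    break
        fractions.append(n_hit / n_seqs)
    return float(np.mean(fractions)) if fractions else 0.0


def recall_rate(n_linked: int, n_total: int) -> float:
    """Percentage of contigs with a predicted host (e.g. 5879 of 50,037 is
    11.7%)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return 100.0 * n_linked / n_total


def erroneous_fraction(random_recall: float, observed_recall: float) -> RoundedValue:
    """Share of observed associations attributable to chance, in percent.

    Both inputs are recall percentages; e.g. a 0.70% chance-hit rate against
    an 11.7% observed recall gives 5.98%, reported as 6%.
    """
    if observed_recall == 0:
        raise ValueError("observed recall is zero; erroneous fraction undefined")
    if random_recall == 0:
        return RoundedValue(0.0, 0)
    v = 100.0 * random_recall / observed_recall
    return RoundedValue(v, round(v))


def false_multidomain_prob(p: float, k: int = 2) -> float:
    """Probability that at least one of ``k`` independent host assignments,
    each with per-assignment error rate ``p``, is false: 1 − (1−p)^k."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - p) ** k


def expected_false_count(n_links: int, p_false: float) -> RoundedValue:
    """Expected number of chance links among ``n_links`` at probability
    ``p_false``; rounded for reporting, unrounded value retained."""
    v = n_links * p_false
    return RoundedValue(v, round(v))


def classify_host_range(links: list[VirusHostLink]) -> dict[str, str]:
    """Per-contig host-range label: specialist / multi-genus / cross-domain."""
    by_contig: dict[str, list[VirusHostLink]] = {}
    for l in links:
        by_contig.setdefault(l.contig_id, []).append(l)
    out = {}
    for cid, ls in by_contig.items():
        genera = {l.genus for l in ls}
        domains = {l.domain for l in ls}
        if len(domains) > 1:
            out[cid] = "cross-domain"
        elif len(genera) > 1:
            out[cid] = "multi-genus"
        else:
            out[cid] = "specialist"
    return out


def host_range_counts(links: list[VirusHostLink]) -> Counter:
    return Counter(classify_host_range(links).values())


def map_functions(links: list[VirusHostLink], function_table: pd.DataFrame,
                  genus_of: dict[str, str] | None = None) -> Counter:
    """Count virus links per host function (MIDAS-style genus → function).

    ``function_table`` has columns ``genus`` and ``function``. Each distinct
    (viral entity, host genus) pair adds 1 to the counter of every function
    of that host genus, so a host with m functions contributes m increments;
    genera absent from the table count under ``"unclassified"``. When
    ``genus_of`` is given, viral contigs are first collapsed to their genus.
    """
    if function_table.duplicated(["genus", "function"]).any():
        raise ValueError("function_table rows must be unique per (genus, function)")
    funcs: dict[str, list[str]] = {}
    for _i, row in function_table.iterrows():
        funcs.setdefault(str(row["genus"]), []).append(str(row["function"]))
    pairs = {((genus_of or {}).get(l.contig_id, l.contig_id), l.genus) for l in links}
    counts: Counter = Counter()
    for _viral, host_genus in sorted(pairs):
        for f in funcs.get(host_genus, ["unclassified"]):
            counts[f] += 1
    return counts


def links_table(links: list[VirusHostLink]) -> pd.DataFrame:
    rows = [dict(contig_id=l.contig_id, genome_id=l.genome_id, genus=l.genus,
                 domain=l.domain, spacer_id=l.spacer_id,
                 identity=l.match.identity, coverage=l.match.coverage,
                 mismatches=l.match.mismatches, contig_start=l.match.contig_start,
                 contig_end=l.match.contig_end, strand=l.match.strand,
                 primary=l.primary) for l in links]
    return pd.DataFrame(rows, columns=[
        "contig_id", "genome_id", "genus", "domain", "spacer_id", "identity",
        "coverage", "mismatches", "contig_start", "contig_end", "strand", "primary"])
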