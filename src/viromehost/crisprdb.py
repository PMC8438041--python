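"""CRISPR repeat–spacer array detection and spacer-database construction.

The detector emulates a CRISPR Recognition Tool style scan with its default
parameters: arrays of at least 3 repeat copies, repeat length 19–38 bp,
spacer length 19–48 bp, found by exact k-mer seeding (window 8). Repeats
within an array are required to be exact copies of the consensus
(exact-repeat mode, the default); an optional tolerance flag relaxes the
chain extension to near-exact copies.

Coordinates are 0-based half-open; slicing the genome at a spacer's
coordinates reproduces the spacer sequence.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from ._seqs import kmer_index


@dataclass(frozen=True)
class CrtParams:
    """Detector parameters (defaults follow the published CRT defaults)."""

    min_repeats: int = 3
    min_repeat_len: int = 19
    max_repeat_len: int = 38
    min_spacer_len: int = 19
    max_spacer_len: int = 48
    seed_window: int = 8
    tolerate_mismatch: bool = False   # allow 1 mismatch per repeat copy in chaining


@dataclass
class CrisprArray:
    genome_id: str
    repeat: str
    repeat_positions: list[int]
    spacers: list[tuple[str, int, int]]   # (sequence, start, end) half-open

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_positions)

    @property
    def start(self) -> int:
        return self.repeat_positions[0]

    @property
    def end(self) -> int:
        return self.repeat_positions[-1] + len(self.repeat)


@dataclass(frozen=True)
class SpacerRecord:
    spacer_id: str
    sequence: str
    genome_id: str
    lineage: str          # semicolon-joined ranks, domain first

    @property
    def genus(self) -> str:
        return self.lineage.split(";")[-1]

    @property
    def domain(self) -> str:
        return self.lineage.split(";")[0]


def _lcp(genome: str, i: int, j: int, cap: int) -> int:
    n = 0
    limit = min(cap, len(genome) - j)
    while n < limit and genome[i + n] == genome[j + n]:
        n += 1
    return n


def _near_match(genome: str, pos: int, repeat: str, max_mm: int) -> bool:
    if pos + len(repeat) > len(genome):
        return False
    mm = 0
    for a, b in zip(repeat, genome[pos : pos + len(repeat)]):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False
    return True


def _chain(genome: str, start: int, repeat: str, p: CrtParams) -> list[int]:
    """Extend an array rightwards from ``start`` by locating further repeat
    copies separated by admissible spacer gaps."""
    positions = [start]
    rl = len(repeat)
    while True:
        lo = positions[-1] + rl + p.min_spacer_len
        hi = positions[-1] + rl + p.max_spacer_len
        nxt = genome.find(repeat, lo, hi + rl)
        if nxt < 0 or nxt > hi:
            if p.tolerate_mismatch:
                nxt = next((q for q in range(lo, min(hi, len(genome) - rl) + 1)
                            if _near_match(genome, q, repeat, 1)), -1)
                if nxt < 0:
                    break
            else:
                break
        positions.append(nxt)
    return positions


def find_crispr_arrays(genome: str, params: CrtParams | None = None,
                       genome_id: str = "genome") -> list[CrisprArray]:
    """Detect CRISPR arrays left-to-right; non-overlapping; empty list if none."""
    p = params or CrtParams()
    w = p.seed_window
    if len(genome) < p.min_repeats * p.min_repeat_len + (p.min_repeats - 1) * p.min_spacer_len:
        return []
    index = kmer_index(genome, w)
    min_d = p.min_repeat_len + p.min_spacer_len
    max_d = p.max_repeat_len + p.max_spacer_len
    arrays: list[CrisprArray] = []
    i = 0
    end = len(genome) - w
    while i <= end:
        occ = index.get(genome[i : i + w])
        found = None
        if occ and len(occ) > 1:
            lo = bisect_left(occ, i + min_d)
            hi = bisect_right(occ, i + max_d)
            for j in occ[lo:hi]:
                d = j - i
                # candidate repeat: common prefix at both copies, capped so the
                # first gap stays a legal spacer
                rl = _lcp(genome, i, j, cap=min(p.max_repeat_len, d - p.min_spacer_len))
                if rl < p.min_repeat_len:
                    continue
                if not (p.min_spacer_len <= d - rl <= p.max_spacer_len):
                    continue
                repeat = genome[i : i + rl]
                positions = _chain(genome, i, repeat, p)
                if len(positions) >= p.min_repeats:
                    found = (repeat, positions)
                    break
            if found:
                repeat, positions = found
                rl = len(repeat)
                spacers = [
                    (genome[a + rl : b], a + rl, b)
                    for a, b in zip(positions, positions[1:])
                ]
                arrays.append(CrisprArray(genome_id=genome_id, repeat=repeat,
                                          repeat_positions=positions, spacers=spacers))
                i = positions[-1] + rl
                continue
        i += 1
    return arrays


def build_spacer_db(genomes: dict[str, str], lineages: dict[str, str],
                    params: CrtParams | None = None) -> list[SpacerRecord]:
    """Detect arrays in every genome and emit one record per unique spacer.

    Spacer sequences are deduplicated within a genome but deliberately kept
    when the same sequence occurs in different genomes, so that multi-host
    and cross-domain queries remain answerable.
    """
    records: list[SpacerRecord] = []
    for gid in sorted(genomes):
        if gid not in lineages:
            raise ValueError(f"genome {gid!r} has no lineage row")
        seen: set[str] = set()
        n = 0
        for arr in find_crispr_arrays(genomes[gid], params, genome_id=gid):
            for seq, _s, _e in arr.spacers:
                if seq in seen:
                    continue
                seen.add(seq)
                records.append(SpacerRecord(
                    spacer_id=f"{gid}_sp{n:03d}", sequence=seq,
                    genome_id=gid, lineage=lineages[gid]))
                n += 1
    return records
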