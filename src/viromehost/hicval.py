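"""Hi-C contact deconvolution and CRISPR-vs-Hi-C consistency.

Proximity-ligation contacts between a viral contig and host genome bins are
collapsed into virus→bin links by a dominance rule; CRISPR-predicted links
are then scored against the Hi-C links: a link whose virus is absent from
the Hi-C set is *undetected*, otherwise it is *same* or *different*
depending on whether the CRISPR bin is among the virus's Hi-C bins.
Precision is same/(same+different) in percent, over detected links only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ComparisonSummary:
    n_crispr_links: int
    n_detected: int
    n_same: int
    n_different: int
    precision: int | None     # integer percent; None when nothing detected

    def __post_init__(self):
        assert self.n_same + self.n_different == self.n_detected <= self.n_crispr_links


def deconvolve(contacts: pd.DataFrame, min_count: int = 5,
               dominance_ratio: float = 2.0) -> dict[str, list[str]]:
    """Virus → host-bin links from a (virus_id, bin_id, count) contact table.

    For each virus, bins with at least ``min_count`` contacts and within
    ``dominance_ratio`` of the top count are assigned (co-assignment when
    several qualify); a virus whose top bin misses the floor is unassigned.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if dominance_ratio < 1:
        raise ValueError("dominance_ratio must be >= 1")
    links: dict[str, list[str]] = {}
    for virus, grp in contacts.groupby("virus_id"):
        counts = grp.groupby("bin_id")["count"].sum().sort_values(ascending=False)
        top = int(counts.iloc[0])
        if top < min_count:
            continue
        kept = [str(b) for b, c in counts.items()
                if c >= min_count and c * dominance_ratio >= top]
        links[str(virus)] = sorted(kept)
    return links


def compare_with_crispr(crispr_links: list[tuple[str, str]],
                        hic_links: dict[str, list[str]]) -> ComparisonSummary:
    """Score CRISPR (virus, bin) links against Hi-C virus → bins links."""
    same = different = undetected = 0
    for virus, bin_id in crispr_links:
        bins = hic_links.get(virus)
        if bins is None:
            undetected += 1
        elif bin_id in bins:
            same += 1
        else:
            different += 1
    detected = same + different
    precision = round(100 * same / detected) if detected else None
    return ComparisonSummary(
        n_crispr_links=len(crispr_links), n_detected=detected,
        n_same=same, n_different=different, precision=precision)


def crispr_links_to_bins(links, bin_membership: pd.DataFrame) -> list[tuple[str, str]]:
    """Map CRISPR (contig, host genome) links to (contig, bin) pairs through
    a genome → bin membership table; deduplicated, sorted."""
    bin_of = dict(zip(bin_membership["genome_id"].astype(str),
                      bin_membership["bin_id"].astype(str)))
    pairs = {(l.contig_id, bin_of[l.genome_id]) for l in links
             if l.genome_id in bin_of}
    return sorted(pairs)
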