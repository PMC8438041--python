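# Methods

This note records what each stage computes, the assumptions behind it, the
defaults that matter, and what the synthetic data does and does not emulate.

## Synthetic communities (`synthio`)

The generator builds a community whose every downstream answer is known in
advance. Viral genomes are uniform-random ACGT sequences, 15–40 kb by
default (matching the scale of a virome assembly whose N50 exceeds 20 kb);
host genomes default to 50 kb — a desk-scale stand-in for a chromosome
region that keeps CRISPR scanning and spacer matching fast without changing
any of the logic being tested. All randomness flows from one
`numpy.random.default_rng(seed)`, so equal configs give byte-identical
outputs.

**Planted structure.**

- *Genera*: each virus is assigned to one of ~`n_viruses/3` genera; a
  genus owns a pool of 15 synthetic proteins and each member contig draws
  ~80% of its emitted proteins from that pool, the rest being private.
  Proteins are emitted for at most 20 genes per contig so the shared pool
  dominates each contig's protein-cluster profile; remaining genes appear
  only in the annotation table. Cross-genus contigs share nothing, so the
  planted partition is the unique correct clustering answer.
- *CRISPR arrays*: each host receives one array of `spacers_per_host`
  (default 3) spacers, each a substring sampled from a random virus
  (optionally mutated with exactly `subs_per_spacer` substitutions),
  interleaved with identical copies of a random repeat (default 28 bp).
  Spacer lengths are confined to 25–45 bp, inside the detector's 19–48 bp
  window; configs outside [19, 48] are rejected because the planted truth
  would be undetectable.
- *Boundary guard*: an exact-repeat detector extends a repeat consensus by
  one base whenever **all** repeat copies are followed (or preceded) by the
  same base — which happens by chance with probability (1/4)^(k−1) per
  array end. The generator therefore resamples the second spacer's source
  window until the first two spacers differ at both flanks, making planted
  boundaries unambiguous. This is a property of the truth definition, not
  of the detector.
- *Abundances*: genus × sample values are log-normal (σ = 1.5 by default, a
  spread that yields the steep rank–abundance profiles typical of viromes);
  a `core_fraction` (default 0.25) of genera is forced present in every
  sample and the rest are zeroed in a random nonempty subset of samples,
  reproducing a shared core plus a sample-specific tail. Columns are
  normalized to 1. Coverage tables set aligned bases proportional to
  abundance × contig length, so the abundance estimator is exact up to
  integer rounding; optional error-free 150 bp reads exercise the mapping
  route instead.
- *Hi-C*: every true virus–host pair receives `hic_true_contacts` (default
  20) contacts on the host's bin; `hic_noise_contacts` (default 50) single
  contacts are scattered uniformly over random (virus, bin) pairs.

**What the generator does not emulate**: sequencing error, assembly
fragmentation and chimerism, phylogenetic sequence similarity between
related genomes, GC/k-mer composition bias, uneven Hi-C crosslinking
efficiency, and CRISPR repeat degeneracy. Passing tests therefore
demonstrate algorithmic correctness against defined truth, not robustness
to every artefact of real libraries.

## Viral screening (`vscreen`)

Hard gates first: length strictly greater than 5000 bp and at least 5
VPF-hit genes. Then three composition criteria (KO ≤ 20% / Pfam ≤ 40% /
VPF ≥ 10%; VPF count > Pfam count; VPF ≥ 60%) are combined disjunctively by
default — they describe alternative evidence routes — with a
`criteria_mode="all"` switch for the conjunctive reading; both modes are
verified against an exact-rational truth-table oracle. Boundary semantics
follow the printed comparators exactly (≤, ≥ inclusive; "longer than 5 kb"
exclusive). The LCA route keeps hits within `top_percent` (default 0.10) of
the best bitscore and returns their longest common lineage prefix,
`"unassigned"` when no rank is unanimous.

## Genus clustering (`genus_net`)

Protein clusters come from greedy centroid clustering (length-sorted,
global edit-distance identity via edlib, identity over the longer
sequence). Contig pairs are scored by −log10 of the hypergeometric tail
P(X ≥ shared) for their shared-cluster count, computed with exact
log-gamma arithmetic; genera are connected components of edges scoring at
least `score_threshold` (default 3, i.e. P ≤ 10⁻³), labelled by their
smallest member id, singletons labelled `"singleton"`. Connected components
replace overlapping cohesive clustering deliberately: they are
deterministic, order-independent and exactly testable against the planted
partition. Dereplication is greedy longest-first: a contig is absorbed when
an infix alignment onto a longer representative reaches 90% identity over
the shorter sequence (threshold configurable; an exact shared 15-mer is
required before any alignment is attempted, keeping random pairs cheap).

## CRISPR detection (`crisprdb`)

The scan seeds on exact 8-mers recurring at a distance compatible with one
repeat plus one spacer, extends the candidate repeat as the common prefix
of the two copies (capped so the first gap stays a legal spacer), and
chains further exact copies left-to-right while inter-repeat gaps stay
within 19–48 bp. Arrays need ≥ 3 copies; repeats are 19–38 bp. Exact-repeat
mode is the default because it makes the detector a verifiable oracle on
synthetic truth; `tolerate_mismatch=True` relaxes chaining to one mismatch
per copy. Coordinates are 0-based half-open and round-trip by construction.
On pure random sequence the expected false-array count is negligible (an
exact ≥ 19 bp triple repeat at admissible spacings is ~4⁻³⁸-scale per
locus); the suite asserts zero across 20 seeds of 100 kb.

## Spacer matching and host prediction (`hostlink`)

Matching is seeded, ungapped, and two-stranded: exact 11-mer seeds define
candidate diagonals; on each diagonal every window with length ≥
ceil(coverage·|spacer|) is scored, and the best passing window wins
(matching bases desc → identity desc → '+' strand → leftmost). Identity is
computed over the alignment length and coverage over the full spacer
length, so an alignment may trim spacer ends — local-alignment semantics.
Gapped alignment is deliberately out: spacers are short, gaps essentially
never survive a 97% identity bound, and ungapped search admits an exact
brute-force oracle, which the suite runs over hundreds of planted cases.

Seeding is provably lossless at the default thresholds: mismatches are
capped both explicitly (≤ 1) and by the identity bound (a full-spacer
window of length n admits at most ⌊0.03·n⌋), and pigeonholing the minimum
window around its mismatches guarantees an exact run of ≥ 11 bases. When a
caller relaxes thresholds past the guarantee, the matcher switches to
scanning every diagonal so benchmark grids stay exact rather than silently
losing sensitivity.

`predict_hosts` collapses passing matches to one link per (contig, host
genome), flags each contig's globally best hit as primary (a deterministic
stand-in for a best-hit-only search), and carries the host lineage for
genus/domain queries. Benchmarking reports precision as the percentage of
correct-genus predictions and recall as the percentage of reference viruses
with a correct-genus prediction (an any-prediction recall is reported
alongside, since either reading is defensible); precision is *missing*, not
zero, when a grid point yields no predictions. The random null draws
replicate databases of random sequences and reports the mean fraction with
any passing hit.

Error-model conventions: reported percentages keep their unrounded value
alongside the integer rounding (`RoundedValue`); `erroneous_fraction`
requires a nonzero observed recall; `false_multidomain_prob(p, k) = 1 −
(1−p)^k` treats the k assignments as independent. Host-range labels are
specialist (one genus), multi-genus (several genera, one domain) and
cross-domain (which implies multi-genus). Function mapping double-counts
deliberately: a host genus with m annotated functions adds 1 to each of the
m counters per linked viral entity, and unknown genera fall into
`"unclassified"`.

## Ecology (`ecol`)

Normalized coverage is (aligned bases / contig length) / dataset size;
shares within a sample sum to 1 and genus abundance is the member sum.
Shannon H′ uses natural logarithms (the base is a convention; nats are
stated explicitly everywhere). Pielou J′ = H′/ln S over detected genera,
defined as 0 when S ≤ 1. Bray–Curtis comes from scipy; PCoA double-centers
−½D², eigendecomposes symmetrically, returns coordinates for positive
eigenvalues and the full spectrum including negative eigenvalues (a
non-Euclidean Bray–Curtis matrix legitimately produces them; dropping them
silently would overstate explained variance). The toy mapper is an
exact-k-mer-seeded ungapped aligner for synthetic reads: a read counts when
a window of ≥ 80% of its length aligns at ≥ 90% identity. Rarefaction
subsamples reads without replacement and applies a detection rule of ≥ 1
mapped read and ≥ 10% horizontal coverage — a deliberate, configurable
choice since no canonical rule exists. Exclusive intersection counts follow
UpSet semantics: each genus contributes to exactly the subset of samples it
occupies.

## Hi-C validation (`hicval`)

Deconvolution assigns, per virus, all bins with ≥ `min_count` (default 5)
contacts lying within `dominance_ratio` (default 2) of the top bin —
co-assignment included; this is a documented, deterministic stand-in for a
proprietary reconstruction, validated on planted truth (noise-free tables
deconvolve to exactly the true pairs). "Simultaneously found" is read as
*the virus appears in the Hi-C link set at all*; undetected links are
excluded from precision, which is rounded to integer percent and missing
when nothing is detected.

## Pipeline (`pipeline`, `cli`)

One YAML config with per-stage blocks drives synth → screen → cluster →
spacers → hosts → ecology → hic; a single global seed reaches every
stochastic step, and the manifest records per-stage outputs with SHA-256
hashes so determinism is checkable by hash equality. Stage failures carry
the stage name and a machine-readable code.

## Problem sizes

The test suite runs communities of roughly 10–50 viruses and up to 30
hosts of 50 kb, 200-pair matcher/oracle sweeps, exhaustive truth tables to
12 genes/protein-clusters, and 20 × 100 kb false-positive scans — sizes
chosen so the whole suite completes in a few minutes on one core while
still exercising every code path at the documented defaults.

## Known limitations

- The matcher is ungapped; an indel-containing protospacer is found only
  via its longest ungapped flank, if that flank alone passes.
- Exact-repeat CRISPR detection misses naturally degenerate repeats unless
  `tolerate_mismatch` is enabled; orientation and Cas typing are out of
  scope.
- Genus clustering by connected components can chain overlapping genera
  that cohesive-cluster methods would split; on planted data (no cross-genus
  sharing) the distinction vanishes.
- E-values are not computed: at ≥ 97% identity on ≥ 19 bp matches against
  desk-scale databases the default e-value cutoff never binds.
- Abundance, diversity and rarefaction values on synthetic communities
  characterise the estimators, not any real ecosystem; real-data index
  ranges depend on the data and are not reproduced here.
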