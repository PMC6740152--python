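# Methods

This note records the models, algorithms and numerical choices behind
`sidescan`, and what the synthetic-genome tests do and do not demonstrate.

## Coordinates and formats

All coordinates are 0-based half-open on the forward strand. Minus-strand
hits keep forward genome coordinates with a strand flag; consensus
coordinates always refer to the consensus forward orientation (the
RepeatMasker convention, so copy counts and landscapes aggregate cleanly
across strands). BED export is native; GFF3 converts to 1-based inclusive.
Hit tables are TSV with columns `score, pct_identity, evalue, seq_id,
start, end, strand, family, q_start, q_end, aligned_len`; the TSV
reader/writer pair round-trips byte-identically.

## Homology search

`search_genome` is a seed-and-extend scanner. Exact k-mer seeds (k = 11,
configurable) are located with a sorted 2-bit-encoded index of the genome;
seed diagonals are clustered into candidate windows, and each window is
aligned with edlib (banded bit-parallel edit distance with full path). The
edit path is then rescored under the scoring scheme (match +1, mismatch −2,
gap open −5, gap extend −2; a gap of length L costs `open + (L−1)·extend`)
and trimmed to its maximum-scoring contiguous subpath (Kadane over path
runs, gap runs treated as atomic). Windows holding several copies are
handled by masking each accepted hit and re-extending the flanking
remainders. Significance uses the Karlin–Altschul approximation
`E = K·m·n·e^{−λS}` with λ solved from
`(1/4)e^{λ·match} + (3/4)e^{λ·mismatch} = 1` (uniform base composition) and
K = 0.1 by default; `calibrate_karlin` refits both from a Gumbel fit to a
simulated null when a genome's composition warrants it. Hits with
`E ≤ 10⁻¹⁰` are kept — the threshold is a significance *cut-off*
(smaller-is-better). Overlapping opposite-strand hits keep the higher
score (ties keep `+`).

An exact affine-gap Smith–Waterman (`local_align`, Bio.Align.PairwiseAligner
in local mode, deterministic lowest-start tie-break) is used wherever
precision on small inputs matters: block annotation, identity
computations, and as the implementation checked against an independent
hand-written Gotoh DP oracle in the tests. Path-based rescoring of edlib
alignments was chosen for the genome scan because full SW traceback is two
orders of magnitude slower at megabase scale; on substitution-dominated
repeat copies the two paths coincide.

One numerical subtlety: under unit edit costs a mismatch pair ties with a
compensating insertion/deletion pair, and edlib resolves such ties
identically for every copy aligned against one reference. Left alone this
fabricates systematic gap columns in pile-ups. `canonicalize_tokens`
therefore rewrites any short balanced I/D window (≤ 40 columns, equal query
and target consumption) back into diagonal steps before profile counting
and divergence estimation; match status is recomputed from the sequences.

## Consensus reconstruction

The two-round procedure: (1) search with a seed query, keep the top-scoring
`n_seed_hits` (50) hits spanning ≥ 90 % of the query ("full-length",
configurable — the fraction is a package definition since repeat-library
practice varies), pile their sequences onto the query by pairwise
anchoring, and call a per-column majority; (2) re-search with the round-1
consensus and rebuild from *all* positive hits. Copies are extracted with a
15 bp flank so that terminal bases clipped by local-alignment trimming can
re-enter the pile-up; anchoring (edlib infix alignment, rescored for
significance) drops inserted bases relative to the reference — the
consensus cannot grow within a round, only via re-seeding — and counts
deletions in a gap row. Majority calls break ties in the fixed order
A < C < G < T (tie counts logged); gap-majority columns are removed;
columns with no coverage fall back to the reference base. On fixtures the
procedure is a fixed point once the hit set stabilises (round 3 = round 2).

ORF validation scans all six frames for the longest ATG→stop open reading
frame under the standard code; a LINE consensus passes at ≥ 300 aa
(the scale of an endonuclease/RT-bearing ORF), while an internal-deletion
derivative fails because the deletion destroys the frame. No profile
database is consulted; ORF length is the proxy for RT-domain presence.

## Architecture annotation

`find_homologous_blocks` trims the poly-A tail, takes the best local
alignment of the SIDE core against the LINE, then re-aligns the flanking
SIDE segments to find the second block; the 5′ block must start within
10 bp of the SIDE start and the 3′ block end within 10 bp of the core end.
Percent identity is computed over gap-free alignment columns only (gapped
columns excluded from numerator and denominator) — identity definitions
vary in the literature, so this one is stated and unit-tested. The deleted
LINE interval is the span between the blocks' LINE coordinates; the
breakpoint microhomology scan reports every word of length 3–12 shared by
the 15 bp windows immediately upstream of the deletion start and
downstream of the deletion end (both window and k-range configurable;
15 bp matches the scale over which breakpoint conservation is visible).
TSD detection demands an *exact* duplicated word (2–20 bp) abutting the
insertion on both sides; a mismatch-tolerant mode was deliberately left
out to keep reports deterministic. Poly-A detection walks back from the 3′
terminus, requires the sequence to end in the target base, and allows at
most one non-target base per 10 bp window (both parameters configurable;
the same detector with base = C finds the poly-C stretch that closes the
5′ homologous region). Logo matrices carry per-position frequencies and
information `2 + Σ f·log₂ f` bits.

## Landscapes and correlation

Fragments with genome span < 160 bp are discarded before merging
(≥ 160 retained; the boundary is inclusive by the filter's definition).
This is the disambiguation step: because SIDE and LINE share their ends,
short fragments could belong to either family, and the shared blocks are
kept shorter than the threshold in the simulator exactly as they are in
the real pair. Defragmentation then chains same-family, same-strand,
collinear fragments when the genomic gap is ≤ `merge_max_gap` (50 bp) plus
any consensus-coordinate gap; fragments whose consensus coordinates are
near-contiguous (within 20 bp) may instead bridge up to 600 bp of genomic
gap — the signature of a copy interrupted by a nested, unrelated insertion,
which leaves no room on the consensus. Both knobs are configurable; with
`merge_max_gap = 0` and the allowance off, merging degenerates to one copy
per hit.

Per-copy divergence pools gap-free aligned columns over a copy's fragments
against the family consensus: `p = mismatches / columns`,
`d = −(3/4)·ln(1 − 4p/3)`. Copies at `p ≥ 0.75` are saturated, flagged and
excluded from landscapes with a warning. Landscapes bin copies and bp by
`d` in 0.01-wide bins; bp totals are conserved. No calibration to years is
attempted. Copy-number correlation across genomes uses the Spearman rank
statistic (robust to counts spanning orders of magnitude; a
Pearson-on-log10 alternative is provided), with a two-sided permutation
p-value — exhaustive for n ≤ 8 genomes, 10 000 seeded Monte-Carlo draws
otherwise.

## The synthetic genome generator

`plant_copies` emulates the biological scenario the pipeline targets. The
master LINE (~3.24 kb by default) is 5′-UTR + one long stop-free ORF
(ATG…TAA, ~850 aa) + 3′-UTR + poly-A; the future deletion breakpoints sit
inside the UTRs, the upstream flank closing with a poly-C stretch and a
5 bp direct-repeat motif (`AGGCC`) that reappears just downstream of the
deletion end — the repeat placement consistent with template-jump
(copy-choice) formation of the deletion. The SIDE master keeps the first
120 and last 140 bp around a 100 bp random variable region (360 bp total,
within the observed 263–386 bp range for such elements; blocks kept below
the 160 bp filter so the two families cannot mask each other). Copies are
mutated under a Jukes–Cantor clock — each site substituted with probability
`(3/4)(1 − e^{−4d/3})` to a uniform different base, substitutions only, so
the p↔d relation is exact for recovery tests — with per-copy d drawn from
a truncated-normal burst mixture (default one burst at d = 0.05,
sd = 0.01). LINE copies are 5′-truncated with probability 0.3 (geometric
length, mean 500 bp, capped at 90 %); 10 % of copies are interrupted by a
100–500 bp unrelated insertion; every insertion gets a 4–8 bp TSD
duplicated from a random target word; strands are random; everything is
reproducible from one seed and recorded in a truth table.

What the generator does *not* model: indels within copies (fragmentation
is the only length-changing process, so observed divergence is pure
substitution), nested element-in-element insertions beyond deliberate
fragmentation, compositional heterogeneity, low-complexity sequence, and
selection. Passing recovery tests therefore demonstrates correctness of
the pipeline's logic under a clean substitution process, not robustness to
every artefact of real assemblies.

## Problem sizes and seeds

The default validation scenario is a 2 Mb genome with 150 LINE and 300
SIDE copies (burst d = 0.05) — large enough that copy-number recovery,
TSD recovery and landscape modes are measured on hundreds of events, small
enough to run in seconds. Consensus recovery uses 50 copies at d = 0.10;
the aligner oracle runs 1 000 random pairs ≤ 50 bp; the cross-genome
correlation uses 8 simulated genomes with proportional planted counts.
All stochastic tests fix their seeds. One known sensitivity: with the
burst mean sitting exactly on a 0.01-bin edge, per-copy estimation noise
(binomial, sd ≈ 0.01 for 360 bp copies) splits the mode's mass between the
two adjacent bins, so the SIDE and LINE modal bins can differ by one or
two bins for some seeds even though both distributions peak at the planted
age; the fixed-seed tests assert the coincident-mode case the analysis is
designed to exhibit, and the acceptance script reports the offset
honestly for whatever seed it is given.

## Known limitations

- Protein-space (tblastn-like) search is not implemented; the RT-domain
  stage is emulated at the DNA level against the ORF region.
- The Karlin–Altschul parameters are the ungapped approximation; gapped
  e-value theory is out of scope.
- No low-complexity masking; poly-A-rich genomes would need it.
- Consensus coordinates cannot grow within a round, so element ends only
  recover when some copies carry them (hence the 15 bp extraction flank).
- The exhaustive Spearman permutation test is O(n!) and capped at n = 8.
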