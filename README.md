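# sidescan

Toolkit for discovering and analysing **short internally deleted elements
(SIDEs)** and their partner **CR1-clade LINEs** in genome assemblies.

A SIDE is a nonautonomous retroelement created by internal deletion of a
non-LTR retrotransposon: it keeps its partner LINE's 5′ end (which carries
the promoter) and 3′ end (the recognition site of the LINE-encoded reverse
transcriptase) around a central region of non-homologous sequence, and so
can be mobilised in trans by the intact partner. Detecting such pairs,
reconstructing their ancestral (consensus) sequences, and comparing their
replication histories requires a chain of analyses that this package
implements end to end:

- **Homology search** — seed-and-extend local alignment of a consensus
  against a genome (exact 11-mer seeds, edlib path extension rescored under
  an affine-gap scheme), with Karlin–Altschul significance
  `E = K·m·n·e^{−λS}` and a cut-off of `E ≤ 10⁻¹⁰`. An exact affine-gap
  Smith–Waterman (`local_align`) backs the fine-grained annotation.
- **Iterative majority-rule consensus** — top-50 full-length hits seed a
  round-1 consensus; an exhaustive re-search with that consensus yields the
  final consensus from all positive hits.
- **Architecture annotation** — the SIDE's 5′/3′ LINE-homologous blocks and
  central variable region, poly-A tails, target-site duplications (TSDs),
  and the short direct repeats (microhomologies) flanking the deletion
  breakpoints, plus a sequence-logo matrix of the breakpoint neighbourhood.
- **Divergence landscapes** — fragments shorter than 160 bp are discarded
  (they cannot be attributed unambiguously to the SIDE or the LINE, whose
  ends are homologous), adjacent collinear fragments are merged into
  copies, and each copy's mismatch proportion *p* against its family
  consensus is corrected for multiple hits with the Jukes–Cantor distance
  `d = −(3/4)·ln(1 − 4p/3)`. Binning copies (or bp) by *d* gives the
  activity-through-age landscape; low-*d* modes mark recent bursts.
- **Copy-number correlation** — Spearman rank correlation of SIDE and LINE
  copy numbers across genomes, with exact (n ≤ 8) or seeded Monte-Carlo
  permutation p-values.
- **Synthetic genomes with ground truth** — a generator planting a
  CR1-like LINE family (~3.3 kb, single long ORF, poly-A tail, frequent 5′
  truncation) and its internal-deletion derivative (~360 bp) at controlled
  burst divergences, with TSDs, microhomology-flanked deletion breakpoints
  and fragmentation, recording every copy in a truth table. All recovery
  claims in the test suite are measured against this truth.

## Worked example

Simulate a 150 kb genome with 8 LINE and 16 SIDE copies, search it with the
SIDE master, and summarise:

```sh
$ sidescan --seed 3 simulate --out run --genome-len 150000 --n-line 8 --n-side 16
wrote genome, masters and truth table to run

$ sidescan search --query side.fa --genome run/genome.fa --out side_hits.tsv
34 hits -> side_hits.tsv

$ sidescan landscape --hits side_hits.tsv --consensus side.fa --genome run/genome.fa
16 copies, 2.981% of genome; table -> landscape.tsv

$ sidescan build-consensus --genome run/genome.fa --seed-query side.fa --out cons.fa
final consensus (360 bp, depth 34) -> cons.fa
```

The 34 raw hits include the SIDE's 5′/3′ end-blocks matching inside LINE
copies; after the ≥160 bp fragment filter and defragmentation exactly the
16 planted SIDE copies remain, covering 2.981 % of the genome.
`sidescan annotate --side side.fa --line line.fa` then reports the
architecture — a 5′ block at LINE positions 0–122 and a 3′ block at
3096–3230 (both 100 % identity here), an 8 bp poly-A tail, and the inferred
deleted interval whose flanks carry the 5 bp direct repeat `AGGCC` — and
`sidescan correlate --table counts.tsv` prints the Spearman statistic with
its exact permutation p-value (e.g. `rho = 1.0, p = 1/60` for five
perfectly monotone genomes).

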