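"""Synthetic genomes with planted LINE and SIDE copies and full ground truth.

The generator emulates the biological scenario the pipeline targets: a host
genome carrying (a) a CR1-like LINE family (~3.3 kb: 5'-UTR ending in a
poly-C junction region, one long endonuclease/RT-style ORF, 3'-UTR, poly-A
tail), frequently truncated at the 5' end upon insertion; (b) a SIDE family
formed by internal deletion of the LINE between short direct-repeat
microhomologies, keeping the LINE's 5' and 3' ends around a non-homologous
central region (~260-390 bp total); (c) per-copy divergences drawn around
one or more replication-burst ages under a Jukes-Cantor substitution clock;
(d) target-site duplications at every insertion and occasional interruption
of a copy by an unrelated insertion (fragmentation). Every planted copy is
recorded in a truth table, the acceptance surface for recovery tests.

The mutation process is substitutions-only, so the observed mismatch
fraction relates exactly to the target distance d through
p_sub = (3/4)(1 - exp(-4 d / 3)); fragmentation is modelled separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DnaRecord, GenomicInterval, revcomp, write_fasta

logger = logging.getLogger("sidescan")

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

LINE_FAMILY = "LINE"
SIDE_FAMILY = "SIDE"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic scenario; defaults are the study conditions.

    Element geometry follows the real pair: LINE ~3.3 kb with a single long
    ORF, SIDE of ~360 bp whose 5'/3' blocks (120/140 bp) stay below the
    160 bp fragment filter so the two families cannot mask each other.
    Bursts are (mean JC distance, weight) mixture components with per-copy
    spread d_sd. Truncation affects only LINE copies (5' end), with a
    geometric length capped at 90% of the copy.
    """

    genome_len: int = 2_000_000
    gc: float = 0.38
    n_line: int = 150
    n_side: int = 300
    burst_d: tuple[tuple[float, float], ...] = ((0.05, 1.0),)
    d_sd: float = 0.01
    p_truncate_5prime: float = 0.3
    truncation_geometric_p: float = 0.002
    p_fragment: float = 0.10
    tsd_len_range: tuple[int, int] = (4, 8)
    polya_len_range: tuple[int, int] = (8, 14)
    five_utr_len: int = 300
    orf_len_nt: int = 2550
    three_utr_len: int = 380
    side_five_len: int = 120
    side_three_len: int = 140
    variable_region_len: int = 100
    microhomology_motif: str = "AGGCC"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_line < 0 or self.n_side < 0:
            raise ValueError("copy numbers must be >= 0")
        w = sum(w for _, w in self.burst_d)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError("burst weights must sum to 1")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0,1)")
        if self.side_five_len + self.side_three_len >= self.master_line_len:
            raise ValueError("SIDE blocks exceed the LINE length")

    @property
    def master_line_len(self) -> int:
        return (
            self.five_utr_len
            + self.orf_len_nt
            + self.three_utr_len
            + self.polya_len_range[0]
        )


@dataclass
class SyntheticTruth:
    """Ground truth for one planted copy."""

    family: str
    genome_iv: GenomicInterval
    strand: str
    true_d: float
    truncated_bp: int
    tsd: str
    fragmented: bool


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Stop-free random codons."""
    out = []
    while len(out) < n_codons:
        codon = "".join(rng.choice(_BASES, 3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def make_master_line(config: SimulationConfig, rng: np.random.Generator) -> DnaRecord:
    """Build the master (ancestral) LINE sequence.

    Layout: 5'-UTR, single long ATG...stop ORF, 3'-UTR, poly-A tail. The
    future deletion breakpoints (at side_five_len from the start and
    side_three_len from the end, both inside the UTRs under the default
    geometry) are marked the way the real element is: the upstream flank
    ends with a poly-C stretch followed by the microhomology motif, and the
    downstream flank opens with a second copy of the motif.
    """
    motif = config.microhomology_motif
    polyc = "C" * 8
    lead = config.side_five_len - len(polyc) - len(motif)
    if lead < 0 or config.side_five_len > config.five_utr_len:
        raise ValueError("side_five_len must fit inside the 5'-UTR")
    utr5 = (
        _random_dna(rng, lead, config.gc)
        + polyc
        + motif
        + _random_dna(rng, config.five_utr_len - config.side_five_len, config.gc)
    )

    n_codons = config.orf_len_nt // 3 - 2  # minus ATG and stop
    orf = "ATG" + _random_codons(rng, n_codons) + "TAA"

    polya = "A" * config.polya_len_range[0]
    tail_in_utr3 = config.side_three_len - len(polya)
    if not (len(motif) <= tail_in_utr3 <= config.three_utr_len):
        raise ValueError("side_three_len must fit inside the 3'-UTR plus poly-A")
    utr3 = (
        _random_dna(rng, config.three_utr_len - tail_in_utr3, config.gc)
        + motif
        + _random_dna(rng, tail_in_utr3 - len(motif), config.gc)
    )
    seq = utr5 + orf + utr3 + polya
    return DnaRecord(id=f"{LINE_FAMILY}_master", seq=seq)


def deletion_interval(config: SimulationConfig) -> tuple[int, int]:
    """The LINE interval removed when deriving the SIDE (0-based half-open)."""
    return (config.side_five_len, config.master_line_len - config.side_three_len)


def derive_side(
    master: DnaRecord, config: SimulationConfig, rng: np.random.Generator
) -> DnaRecord:
    """Internal-deletion derivative of the master LINE.

    Keeps the first side_five_len and last side_three_len bases (the
    deletion boundaries sit at the planted microhomology copies, one copy
    retained at each block edge, as template jumping between the repeats
    would leave) and fills the middle with a random, non-homologous variable
    region.
    """
    L = len(master.seq)
    if config.side_five_len + config.side_three_len >= L:
        raise ValueError("SIDE blocks exceed the master length")
    variable = _random_dna(rng, config.variable_region_len, 0.5)
    seq = master.seq[: config.side_five_len] + variable + master.seq[L - config.side_three_len :]
    return DnaRecord(id=f"{SIDE_FAMILY}_master", seq=seq)


def p_sub_of_d(d: float) -> float:
    """Expected mismatch fraction after evolving a site to JC distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def mutate_copy(
    master: DnaRecord | str, target_d: float, rng: np.random.Generator
) -> str:
    """Evolve a copy to Jukes-Cantor distance target_d (substitutions only).

    Each site is substituted with probability (3/4)(1 - e^{-4d/3}) to a
    uniformly chosen different base, so the expected observed mismatch
    fraction equals that probability and the Jukes-Cantor estimator
    round-trips to d.
    """
    if target_d < 0:
        raise ValueError("target_d must be >= 0")
    seq = master.seq if isinstance(master, DnaRecord) else master
    if target_d == 0:
        return seq
    p = p_sub_of_d(target_d)
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < p
    idx = np.nonzero(mask)[0]
    for i in idx:
        if arr[i] in "ACGT":
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def truncate_5prime(
    copy: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, int]:
    """With probability p_truncate_5prime remove a geometric-length prefix,
    capped at 90% of the copy (the hallmark of low-processivity CR1
    reverse transcription)."""
    if rng.random() >= config.p_truncate_5prime:
        return copy, 0
    cut = int(rng.geometric(config.truncation_geometric_p))
    cut = min(cut, int(0.9 * len(copy)))
    return copy[cut:], cut


def plant_copies(
    config: SimulationConfig,
) -> tuple[DnaRecord, list[SyntheticTruth], DnaRecord, DnaRecord]:
    """Assemble the synthetic genome.

    Returns (genome, truth, master_line, master_side). Every copy gets a
    divergence drawn from the burst mixture (normal, sd=d_sd, floored at 0),
    a random strand, a TSD duplicated at the insertion site, optional 5'
    truncation (LINE only) and, with probability p_fragment, an interrupting
    unrelated insertion that splits it in two. Insertion sites are uniform
    and non-nested; everything is reproducible from config.rng_seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    master_line = make_master_line(config, rng)
    master_side = derive_side(master_line, config, rng)

    means = np.array([m for m, _ in config.burst_d])
    weights = np.array([w for _, w in config.burst_d])

    inserts: list[tuple[str, str, float, int, str, bool]] = []
    # (family, seq, true_d, truncated_bp, tsd, fragmented)
    total_bp = 0
    for family, master, n in (
        (LINE_FAMILY, master_line, config.n_line),
        (SIDE_FAMILY, master_side, config.n_side),
    ):
        for _ in range(n):
            comp = rng.choice(len(means), p=weights)
            d = max(0.0, rng.normal(means[comp], config.d_sd))
            seq = mutate_copy(master.seq, d, rng)
            trunc = 0
            if family == LINE_FAMILY:
                seq, trunc = truncate_5prime(seq, config, rng)
            tsd_len = int(rng.integers(config.tsd_len_range[0], config.tsd_len_range[1] + 1))
            tsd = _random_dna(rng, tsd_len, 0.5)
            fragmented = bool(rng.random() < config.p_fragment)
            inserts.append((family, seq, d, trunc, tsd, fragmented))
            total_bp += len(seq) + 2 * tsd_len
    if total_bp >= config.genome_len / 2:
        raise ValueError(
            f"planted material ({total_bp} bp) exceeds half the genome length"
        )

    order = rng.permutation(len(inserts))
    offsets = np.sort(rng.choice(config.genome_len, size=len(inserts), replace=False))

    pieces: list[str] = []
    truth: list[SyntheticTruth] = []
    prev = 0
    pos = 0  # running length of assembled genome
    gid = "chr1"
    for slot, which in enumerate(order):
        family, seq, d, trunc, tsd, fragmented = inserts[which]
        background = _random_dna(rng, offsets[slot] - prev, config.gc)
        prev = offsets[slot]
        pieces.append(background)
        pos += len(background)

        strand = "+" if rng.random() < 0.5 else "-"
        placed = seq if strand == "+" else revcomp(seq)
        if fragmented:
            # interrupt the copy with an unrelated random insertion
            cut = int(rng.integers(len(placed) // 4, 3 * len(placed) // 4))
            filler = _random_dna(rng, int(rng.integers(100, 500)), config.gc)
            placed = placed[:cut] + filler + placed[cut:]
        pieces.append(tsd)
        pos += len(tsd)
        start = pos
        pieces.append(placed)
        pos += len(placed)
        end = pos
        pieces.append(tsd)
        pos += len(tsd)
        truth.append(
            SyntheticTruth(
                family=family,
                genome_iv=GenomicInterval(gid, start, end, strand),
                strand=strand,
                true_d=float(d),
                truncated_bp=int(trunc),
                tsd=tsd,
                fragmented=fragmented,
            )
        )
    pieces.append(_random_dna(rng, config.genome_len - prev, config.gc))
    genome = DnaRecord(id=gid, seq="".join(pieces))
    truth.sort(key=lambda t: t.genome_iv.start)
    logger.info(
        "simulated genome: %d bp, %d LINE + %d SIDE copies planted",
        len(genome.seq),
        config.n_line,
        config.n_side,
    )
    return genome, truth, master_line, master_side


def truth_to_frame(truth: list[SyntheticTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [t.genome_iv.seq_id for t in truth],
            "start": [t.genome_iv.start for t in truth],
            "end": [t.genome_iv.end for t in truth],
            "family": [t.family for t in truth],
            "strand": [t.strand for t in truth],
            "true_d": [t.true_d for t in truth],
            "truncated_bp": [t.truncated_bp for t in truth],
            "tsd": [t.tsd for t in truth],
            "fragmented": [t.fragmented for t in truth],
        }
    )


def write_simulation(
    out_dir: str | Path,
    genome: DnaRecord,
    truth: list[SyntheticTruth],
    master_line: DnaRecord,
    master_side: DnaRecord,
) -> None:
    """Emit genome FASTA, masters FASTA and the truth table (BED6+extra TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([genome], out / "genome.fa")
    write_fasta([master_line, master_side], out / "masters.fa")
    frame = truth_to_frame(truth)
    bed_cols = ["seq_id", "start", "end", "family", "true_d", "strand"]
    extra = ["truncated_bp", "tsd", "fragmented"]
    frame[bed_cols + extra].to_csv(out / "truth.tsv", sep="\t", index=False)
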