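"""Structural annotation of a SIDE against its partner LINE.

A short internally deleted element (SIDE) keeps its partner LINE's 5' and 3'
ends — the promoter-bearing 5'-UTR and the 3'-UTR the reverse transcriptase
recognises — around a central region of non-homologous sequence. This module
locates those homologous blocks, the poly-A tail, target-site duplications
flanking genomic insertions, and the short direct repeats (microhomologies)
bordering the internal deletion, plus a position-frequency logo of the
breakpoint neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import LocalAlignment, ScoringScheme, local_align
from .io import DnaRecord, GenomicInterval

logger = logging.getLogger("sidescan")


@dataclass
class HomologyBlock:
    """A SIDE interval aligned to a LINE interval, with percent identity."""

    side_start: int
    side_end: int
    line_start: int
    line_end: int
    pct_identity: float
    score: float


@dataclass
class ElementArchitecture:
    """SIDE decomposition: 5' LINE-homologous block, central variable region,
    3' LINE-homologous block, poly-A tail length."""

    five_block: HomologyBlock | None
    variable_region: tuple[int, int] | None
    three_block: HomologyBlock | None
    polya_len: int


@dataclass
class Microhomology:
    """Direct repeat flanking a deletion; positions are on the LINE."""

    motif: str
    length: int
    upstream_pos: int
    downstream_pos: int


@dataclass
class TsdReport:
    """Target-site duplication flanking a genomic insertion."""

    motif: str
    length: int
    left_iv: GenomicInterval
    right_iv: GenomicInterval


@dataclass
class LogoMatrix:
    """Per-position base frequencies and information content (bits)."""

    freqs: np.ndarray  # (L, 4) rows sum to 1
    info_bits: np.ndarray  # (L,)


def percent_identity(a: str, b: str) -> float:
    """Percent identity over the gap-free columns of one alignment.

    Columns holding a gap in either sequence are excluded from both the
    numerator and denominator.
    """
    if len(a) != len(b):
        raise ValueError("aligned strings must have equal length")
    matches = 0
    cols = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
    if cols == 0:
        raise ValueError("percent identity undefined: no gap-free columns")
    return 100.0 * matches / cols


def detect_polya(
    seq: DnaRecord | str,
    min_run: int = 5,
    max_mismatch_per_10: int = 1,
    base: str = "A",
) -> int:
    """Length of the terminal homopolymer tail (default poly-A).

    The tail is the longest suffix ending in the target base whose every
    10 bp window holds at most ``max_mismatch_per_10`` non-target bases;
    leading non-target bases are trimmed. Returns 0 when shorter than
    min_run or when the sequence does not end in the target base. The same
    detector parameterised with base="C" finds the poly-C stretch that
    terminates the 5' homologous region.
    """
    s = seq.seq if isinstance(seq, DnaRecord) else seq
    if not s or s[-1] != base:
        return 0
    flags: list[bool] = []  # True where non-target, walking 3'->5'
    for c in reversed(s):
        is_mismatch = c != base
        # each extension creates one new 10 bp window: the latest 10 bases
        if is_mismatch and sum(flags[-9:]) + 1 > max_mismatch_per_10:
            break
        flags.append(is_mismatch)
    # trim 5'-most non-target bases off the tail
    while flags and flags[-1]:
        flags.pop()
    tail = len(flags)
    return tail if tail >= min_run else 0


def detect_tsd(
    genome: DnaRecord,
    insertion: GenomicInterval,
    window: int = 20,
    len_range: tuple[int, int] = (2, 20),
) -> TsdReport | None:
    """Longest exact duplicated word whose right edge abuts the insertion
    start and left edge abuts the insertion end.

    Target-primed reverse transcription duplicates the nicked host site, so
    a genuine insertion is bracketed by identical words. Returns None when
    no duplication of length within len_range exists, or when the insertion
    sits too close to a contig edge for the flanks to be inspected.
    """
    s, e = insertion.start, insertion.end
    lo, hi = len_range
    if s < lo or e + lo > len(genome.seq):
        logger.warning("insertion at contig edge; TSD undetectable")
        return None
    left = genome.seq[max(0, s - window) : s]
    right = genome.seq[e : e + window]
    for L in range(min(hi, len(left), len(right)), lo - 1, -1):
        if left[-L:] == right[:L]:
            return TsdReport(
                motif=right[:L],
                length=L,
                left_iv=GenomicInterval(insertion.seq_id, s - L, s),
                right_iv=GenomicInterval(insertion.seq_id, e, e + L),
            )
    return None


def find_breakpoint_microhomology(
    line: DnaRecord,
    deleted: tuple[int, int],
    k_range: tuple[int, int] = (3, 12),
    window: int = 15,
) -> list[Microhomology]:
    """Direct repeats shared by the two breakpoint flanks of a deletion.

    Scans the ``window`` bp immediately upstream of the deletion start and
    immediately downstream of the deletion end for words of every length in
    k_range present in both; reported longest-first (then alphabetically).
    Such repeats implicate template jumping or repair-mediated deletion.
    """
    s, e = deleted
    if not (0 < s < e < len(line.seq)):
        raise ValueError("deleted interval must lie strictly inside the LINE")
    up_off = max(0, s - window)
    up = line.seq[up_off:s]
    down = line.seq[e : e + window]
    found: list[Microhomology] = []
    seen: set[str] = set()
    for k in range(min(k_range[1], len(up), len(down)), k_range[0] - 1, -1):
        down_words = {}
        for j in range(len(down) - k + 1):
            w = down[j : j + k]
            if w not in down_words:
                down_words[w] = e + j
        for i in range(len(up) - k, -1, -1):  # nearest the breakpoint first
            w = up[i : i + k]
            if w in down_words and w not in seen:
                seen.add(w)
                found.append(
                    Microhomology(
                        motif=w,
                        length=k,
                        upstream_pos=up_off + i,
                        downstream_pos=down_words[w],
                    )
                )
    found.sort(key=lambda m: (-m.length, m.motif))
    return found


def breakpoint_logo(seqs: list[str], anchor: int = 0) -> LogoMatrix:
    """Position-frequency matrix and information content of aligned windows.

    info = 2 + sum_b f_b log2 f_b bits per position (0 log 0 = 0); all
    sequences must share one length and be aligned on the anchor.
    """
    if not seqs:
        raise ValueError("breakpoint_logo requires at least one sequence")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all sequences must have equal length")
    counts = np.zeros((L, 4))
    idx = {b: i for i, b in enumerate("ACGT")}
    for s in seqs:
        for j, c in enumerate(s):
            if c in idx:
                counts[j, idx[c]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return LogoMatrix(freqs=freqs, info_bits=np.clip(info, 0.0, 2.0))


def _block_from_alignment(aln: LocalAlignment, side_off: int) -> HomologyBlock:
    return HomologyBlock(
        side_start=aln.a_start + side_off,
        side_end=aln.a_end + side_off,
        line_start=aln.b_start,
        line_end=aln.b_end,
        pct_identity=percent_identity(aln.aligned_a, aln.aligned_b),
        score=aln.score,
    )


def find_homologous_blocks(
    side: DnaRecord,
    line: DnaRecord,
    scheme: ScoringScheme | None = None,
    min_block: int = 50,
    end_slack: int = 10,
) -> ElementArchitecture:
    """Locate the SIDE's 5' and 3' LINE-homologous blocks.

    The best local alignment of the (poly-A-trimmed) SIDE against the LINE
    gives one block; the flanking SIDE segments are re-aligned to find the
    second. The 5' block must start within ``end_slack`` bp of the SIDE
    start and the 3' block end within ``end_slack`` bp of the SIDE end
    (before the poly-A); the stretch between them is the central variable
    region. A missing block is reported as None with a warning — the SIDE
    call is then unconfirmed.
    """
    scheme = scheme or ScoringScheme()
    if len(side.seq) < min_block or len(line.seq) < min_block:
        raise ValueError(f"sequences must be >= min_block ({min_block}) bp")
    polya = detect_polya(side)
    core_end = len(side.seq) - polya
    core = side.seq[:core_end]

    first = local_align(core, line.seq, scheme)
    blocks = [_block_from_alignment(first, 0)]
    # search the unaligned SIDE flanks for the second block
    for off, seg in ((0, core[: first.a_start]), (first.a_end, core[first.a_end :])):
        if len(seg) >= min_block:
            aln = local_align(seg, line.seq, scheme)
            if aln.a_end - aln.a_start >= min_block:
                blocks.append(_block_from_alignment(aln, off))
    blocks.sort(key=lambda b: b.side_start)

    five = blocks[0] if blocks[0].side_start <= end_slack else None
    three = None
    if len(blocks) > 1 and blocks[-1].side_end >= core_end - end_slack:
        three = blocks[-1]
    elif len(blocks) == 1 and five is not None and blocks[0].side_end >= core_end - end_slack:
        # degenerate: one block spans (almost) the whole element
        pass
    if five is None:
        logger.warning("no 5'-anchored homologous block; SIDE call unconfirmed")
    if three is None and not (five and five.side_end >= core_end - end_slack):
        logger.warning("no 3'-anchored homologous block; SIDE call unconfirmed")

    variable = None
    if five is not None and three is not None:
        variable = (five.side_end, three.side_start)
    return ElementArchitecture(
        five_block=five,
        variable_region=variable,
        three_block=three,
        polya_len=polya,
    )


def infer_deletion_interval(
    architecture: ElementArchitecture, line_len: int
) -> tuple[int, int]:
    """LINE interval absent from the SIDE: between the two homologous blocks.

    Errors when either block is missing or the blocks overlap on the LINE
    (then there is no internal deletion to speak of).
    """
    five, three = architecture.five_block, architecture.three_block
    if five is None or three is None:
        raise ValueError("both homologous blocks are required to infer a deletion")
    if three.line_start <= five.line_end:
        raise ValueError(
            "blocks overlap on the LINE: not an internal deletion "
            f"([{five.line_start},{five.line_end}) vs "
            f"[{three.line_start},{three.line_end}))"
        )
    if three.line_end > line_len:
        raise ValueError("3' block extends past the stated LINE length")
    return (five.line_end, three.line_start)
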