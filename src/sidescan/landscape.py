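"""Copy-number, divergence and activity-through-age analyses.

After a genome scan, raw hits are filtered by a minimum fragment length (so
the SIDE and its partner LINE cannot mask each other's copies through their
shared ends), chained into defragmented copies, and each copy is compared
with its family consensus to obtain the proportion of mismatching sites p
and the Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3). Binning copies (or
their base pairs) by d gives the divergence landscape: low-d modes mark
recent replication bursts. Copy numbers of a SIDE and its partner across
genomes are compared with a Spearman rank correlation whose p-value comes
from permutations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import edlib
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .align import Hit, ScoringScheme, canonicalize_tokens, cigar_tokens
from .io import DnaRecord, GenomicInterval, PipelineConfig, revcomp

logger = logging.getLogger("sidescan")

JC_MAX_P = 0.75


@dataclass
class MergedCopy:
    """A defragmented element copy: collinear same-strand fragments chained
    into one insertion, with pooled divergence to the family consensus."""

    family: str
    fragments: list[Hit]
    genome_iv: GenomicInterval
    strand: str
    matched_bp: int
    p: float | None = None
    d: float | None = None
    saturated: bool = False


@dataclass
class LandscapeTable:
    """Per-divergence-bin copy counts and summed base pairs for one family."""

    family: str
    bin_edges: np.ndarray
    copies: np.ndarray
    bp: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "copies": self.copies,
                "bp": self.bp,
            }
        )

    def modal_bin(self, by: str = "bp") -> int:
        weights = self.bp if by == "bp" else self.copies
        return int(np.argmax(weights))


@dataclass
class CorrelationResult:
    n: int
    statistic: float
    p_value: float
    method: str


def filter_fragments(hits: list[Hit], min_len: int) -> list[Hit]:
    """Retain hits whose genome span is >= min_len (the boundary itself is
    kept). Filtering precedes merging, so ambiguous short fragments shared
    between a SIDE and its partner LINE never enter either family's counts."""
    kept = [h for h in hits if h.genome_span() >= min_len]
    logger.info("fragment filter >=%d bp: %d -> %d hits", min_len, len(hits), len(kept))
    return kept


def merge_adjacent(
    hits: list[Hit],
    config: PipelineConfig | None = None,
    collinear_slack: int = 20,
    consensus_gap_allowance: bool = True,
    bridge_max_gap: int = 600,
    max_lookahead: int = 10_000,
) -> list[MergedCopy]:
    """Greedy chaining of adjacent collinear fragments into single copies.

    Fragments join iff they share family, genome sequence and strand, the
    genomic gap is at most merge_max_gap plus the consensus-coordinate gap
    between them (a deleted stretch of the copy leaves matching room on the
    consensus), and consensus coordinates advance collinearly (within
    ``collinear_slack`` bp of backtracking). Fragments whose consensus
    coordinates are near-contiguous (|gap| <= collinear_slack) may instead
    bridge a genomic gap up to ``bridge_max_gap``: that is the signature of
    a copy interrupted by a nested, unrelated insertion. Each hit lands in
    exactly one copy.
    """
    config = config or PipelineConfig()
    ordered = sorted(
        hits, key=lambda h: (h.genome_iv.seq_id, h.genome_iv.start, h.genome_iv.end)
    )
    copies: list[MergedCopy] = []
    open_chains: list[list[Hit]] = []

    def close(chain: list[Hit]) -> None:
        iv = GenomicInterval(
            chain[0].genome_iv.seq_id,
            chain[0].genome_iv.start,
            chain[-1].genome_iv.end,
            chain[0].strand,
        )
        copies.append(
            MergedCopy(
                family=chain[0].family,
                fragments=chain,
                genome_iv=iv,
                strand=chain[0].strand,
                matched_bp=sum(h.genome_span() for h in chain),
            )
        )

    for h in ordered:
        attached = False
        for chain in open_chains:
            prev = chain[-1]
            if (
                h.family != prev.family
                or h.strand != prev.strand
                or h.genome_iv.seq_id != prev.genome_iv.seq_id
            ):
                continue
            gap = h.genome_iv.start - prev.genome_iv.end
            if gap < 0:
                continue
            if h.strand == "+":
                q_gap = h.q_start - prev.q_end
                collinear = h.q_start >= prev.q_end - collinear_slack
            else:
                # on the minus strand, walking the genome left to right walks
                # the consensus right to left
                q_gap = prev.q_start - h.q_end
                collinear = h.q_end <= prev.q_start + collinear_slack
            allowance = max(0, q_gap) if consensus_gap_allowance else 0
            bridged = (
                consensus_gap_allowance
                and abs(q_gap) <= collinear_slack
                and gap <= bridge_max_gap
            )
            if collinear and (gap <= config.merge_max_gap + allowance or bridged):
                chain.append(h)
                attached = True
                break
        if not attached:
            open_chains.append([h])
        # retire chains that can no longer be extended
        still_open = []
        for chain in open_chains:
            if (
                chain[-1].genome_iv.seq_id != h.genome_iv.seq_id
                or h.genome_iv.start - chain[-1].genome_iv.end
                > config.merge_max_gap + max_lookahead
            ):
                close(chain)
            else:
                still_open.append(chain)
        open_chains = still_open
    for chain in open_chains:
        close(chain)
    copies.sort(key=lambda c: (c.genome_iv.seq_id, c.genome_iv.start))
    logger.info("defragmentation: %d hits -> %d copies", len(hits), len(copies))
    return copies


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3).

    Corrects the observed mismatch proportion p for multiple substitutions
    at one site; defined for 0 <= p < 0.75 (saturation above).
    """
    if not 0 <= p < JC_MAX_P:
        raise ValueError(f"Jukes-Cantor undefined for p={p} (needs 0 <= p < 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def copy_divergence(
    copy: MergedCopy,
    consensus: DnaRecord,
    genome: dict[str, DnaRecord],
    scheme: ScoringScheme | None = None,
) -> MergedCopy:
    """Fill in a copy's mismatch proportion p and Jukes-Cantor d versus its
    family consensus, pooling gap-free aligned columns over all fragments.

    Saturated copies (p >= 0.75) are flagged and later excluded from
    landscapes with a warning.
    """
    scheme = scheme or ScoringScheme()
    mism = 0
    cols = 0
    rec = genome[copy.genome_iv.seq_id]
    for h in copy.fragments:
        frag = rec.seq[h.genome_iv.start : h.genome_iv.end]
        if h.strand == "-":
            frag = revcomp(frag)
        ref = consensus.seq[h.q_start : h.q_end]
        if not ref or not frag:
            continue
        res = edlib.align(frag, ref, mode="NW", task="path")
        q_pos = t_pos = 0
        for op, n in canonicalize_tokens(cigar_tokens(res["cigar"])):
            if op in ("=", "X", "M"):
                # recompare bases: canonicalised M runs carry no match status
                for i in range(n):
                    cols += 1
                    if frag[q_pos + i] != ref[t_pos + i]:
                        mism += 1
                q_pos += n
                t_pos += n
            elif op == "I":
                q_pos += n
            else:
                t_pos += n
    if cols == 0:
        copy.p = None
        copy.d = None
        copy.saturated = True
        return copy
    p = mism / cols
    copy.p = p
    if p >= JC_MAX_P:
        copy.saturated = True
        logger.warning(
            "copy at %s:%d-%d saturated (p=%.3f); excluded from landscape",
            copy.genome_iv.seq_id,
            copy.genome_iv.start,
            copy.genome_iv.end,
            p,
        )
    else:
        copy.d = jukes_cantor(p)
    return copy


def activity_landscape(
    copies: list[MergedCopy], config: PipelineConfig | None = None
) -> LandscapeTable:
    """Bin copies by Jukes-Cantor distance (default bin width 0.01).

    Low bins hold the most recently transposed copies; a mode marks a
    replication burst. Base-pair totals are conserved: the bins sum to the
    matched bp of all non-saturated copies.
    """
    config = config or PipelineConfig()
    width = config.landscape_bin_width
    usable = [c for c in copies if c.d is not None and not c.saturated]
    n_excluded = len(copies) - len(usable)
    if n_excluded:
        logger.warning("landscape: %d saturated/unscored copies excluded", n_excluded)
    family = usable[0].family if usable else (copies[0].family if copies else "NA")
    max_d = max((c.d for c in usable), default=0.0)
    n_bins = max(1, int(math.floor(max_d / width)) + 1)
    edges = np.arange(n_bins + 1) * width
    counts = np.zeros(n_bins, dtype=np.int64)
    bp = np.zeros(n_bins, dtype=np.int64)
    for c in usable:
        b = min(int(c.d / width), n_bins - 1)
        counts[b] += 1
        bp[b] += c.matched_bp
    return LandscapeTable(family=family, bin_edges=edges, copies=counts, bp=bp)


def genome_coverage(copies: list[MergedCopy], genome_len: int) -> float:
    """Fraction of the genome covered by the union of copy intervals."""
    if genome_len <= 0:
        raise ValueError("genome_len must be > 0")
    ivs = sorted(
        ((c.genome_iv.seq_id, c.genome_iv.start, c.genome_iv.end) for c in copies)
    )
    covered = 0
    cur = None
    for sid, s, e in ivs:
        if cur is None or sid != cur[0] or s > cur[2]:
            if cur is not None:
                covered += cur[2] - cur[1]
            cur = (sid, s, e)
        else:
            cur = (sid, cur[1], max(cur[2], e))
    if cur is not None:
        covered += cur[2] - cur[1]
    return covered / genome_len


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("Spearman statistic undefined for constant ranks")
    return float((rx * ry).sum() / denom)


def copy_number_correlation(
    table: pd.DataFrame,
    side_col: str = "side",
    line_col: str = "line",
    seed: int = 0,
    n_mc: int = 10_000,
    exact_max_n: int = 8,
) -> CorrelationResult:
    """Spearman rank correlation of per-genome SIDE and LINE copy numbers.

    The two-sided p-value counts permutations of one margin whose |rho|
    reaches the observed |rho|: exhaustively for n <= exact_max_n, else by
    ``n_mc`` seeded Monte-Carlo draws. Copy numbers spanning several orders
    of magnitude make the rank statistic the robust choice.
    """
    x = np.asarray(table[side_col], dtype=float)
    y = np.asarray(table[line_col], dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("correlation requires counts from at least 4 genomes")
    rho = _spearman_rho(x, y)
    tol = 1e-12
    if n <= exact_max_n:
        hits = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(_spearman_rho(x[list(perm)], y)) >= abs(rho) - tol:
                hits += 1
        p = hits / total
        method = "spearman/exact-permutation"
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        xs = x.copy()
        for _ in range(n_mc):
            rng.shuffle(xs)
            if abs(_spearman_rho(xs, y)) >= abs(rho) - tol:
                hits += 1
        p = (hits + 1) / (n_mc + 1)
        method = f"spearman/mc-permutation({n_mc})"
    # cross-check the statistic against the library implementation
    lib_rho = spearmanr(x, y).statistic
    if not math.isclose(rho, lib_rho, abs_tol=1e-9):
        logger.warning("spearman statistic mismatch vs scipy: %f vs %f", rho, lib_rho)
    return CorrelationResult(n=n, statistic=rho, p_value=p, method=method)


def log_pearson_correlation(
    table: pd.DataFrame, side_col: str = "side", line_col: str = "line"
) -> CorrelationResult:
    """Pearson correlation of log10 copy numbers (alternative to Spearman)."""
    from scipy.stats import pearsonr

    x = np.log10(np.asarray(table[side_col], dtype=float))
    y = np.log10(np.asarray(table[line_col], dtype=float))
    r = pearsonr(x, y)
    return CorrelationResult(
        n=len(x), statistic=float(r.statistic), p_value=float(r.pvalue), method="pearson/log10"
    )


def plot_landscape(tables: list[LandscapeTable], path: str, by: str = "bp") -> None:
    """Bar-chart divergence landscapes for one or more families (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for t in tables:
        w = t.bin_edges[1] - t.bin_edges[0]
        vals = t.bp if by == "bp" else t.copies
        ax.bar(t.bin_edges[:-1], vals, width=w, align="edge", alpha=0.6, label=t.family)
    ax.set_xlabel("Jukes-Cantor divergence from family consensus")
    ax.set_ylabel("bp" if by == "bp" else "copies")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
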