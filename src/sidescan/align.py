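"""Local-alignment homology search: the pipeline's stand-in for blastn.

Two engines live here. ``local_align`` is an exact affine-gap Smith-Waterman
(via Bio.Align.PairwiseAligner) used wherever precision matters on small
inputs (block annotation, test oracles). ``search_genome`` is a
seed-and-extend scanner: exact k-mer seeds (default k=11) locate candidate
windows, each window is aligned with edlib (bit-parallel edit distance with
full path) and the path is rescored under the scoring scheme, trimmed to its
maximum-scoring contiguous subpath. Significance is assessed with the
Karlin-Altschul e-value E = K*m*n*exp(-lambda*score).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .io import DnaRecord, GenomicInterval, PipelineConfig, revcomp

logger = logging.getLogger("sidescan")

__all__ = [
    "ScoringScheme",
    "Hit",
    "LocalAlignment",
    "local_align",
    "evalue_of",
    "search_genome",
    "GenomeIndex",
    "calibrate_karlin",
]


def _solve_lambda(match: float, mismatch: float) -> float:
    """Karlin-Altschul lambda for uniform base composition.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 with p = 1/4, i.e.
    (1/4) e^{lambda*match} + (3/4) e^{lambda*mismatch} = 1.
    """

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


@dataclass
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus Karlin-Altschul parameters.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend`` (the opening
    base carries gap_open). lambda is solved from the substitution scores
    assuming uniform base composition; K defaults to 0.1 and can be
    recalibrated empirically with :func:`calibrate_karlin`.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = field(default=0.0)
    karlin_k: float = 0.1

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("scoring scheme requires match > 0 > mismatch")
        if self.karlin_lambda <= 0:
            self.karlin_lambda = _solve_lambda(self.match, self.mismatch)
        if self.karlin_k <= 0:
            raise ValueError("karlin_k must be > 0")

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        return al


@dataclass
class LocalAlignment:
    """Best local alignment of a vs b with aligned (gapped) strings."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str


@dataclass
class Hit:
    """One local-alignment match of a family consensus against a genome.

    genome_iv is always in forward genome coordinates; q_start/q_end are on
    the consensus in its forward orientation regardless of strand.
    """

    family: str
    genome_iv: GenomicInterval
    q_start: int
    q_end: int
    strand: str
    score: float
    evalue: float
    pct_identity: float
    aligned_len: int

    def genome_span(self) -> int:
        return len(self.genome_iv)


def local_align(a: str, b: str, scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Optimal affine-gap Smith-Waterman local alignment of a vs b.

    Ties between co-optimal alignments are broken deterministically by the
    lowest start on a, then on b (among the aligner's enumerated optima).
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    alns = scheme.aligner().align(a, b)
    best = None
    best_key = None
    # co-optimal enumeration can be combinatorial; 32 is plenty to realise
    # the lowest-start tie-break on test-sized inputs
    for i, aln in enumerate(alns):
        if i >= 32:
            break
        key = (int(aln.coordinates[0][0]), int(aln.coordinates[1][0]))
        if best_key is None or key < best_key:
            best_key = key
            best = aln
    coords = best.coordinates
    return LocalAlignment(
        score=float(best.score),
        a_start=int(coords[0][0]),
        a_end=int(coords[0][-1]),
        b_start=int(coords[1][0]),
        b_end=int(coords[1][-1]),
        aligned_a=str(best[0]),
        aligned_b=str(best[1]),
    )


def evalue_of(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expected number of chance hits at or above ``score``.

    E = K * m * n * exp(-lambda * score); monotone decreasing in score and
    linear in both sequence lengths.
    """
    if score < 0:
        raise ValueError("score must be >= 0")
    return float(scheme.karlin_k * m * n * np.exp(-scheme.karlin_lambda * score))


def calibrate_karlin(
    scheme: ScoringScheme,
    rng: np.random.Generator,
    n_pairs: int = 200,
    length: int = 100,
) -> ScoringScheme:
    """Refit lambda and K from a Monte-Carlo null of random sequence pairs.

    Maximum local scores of unrelated sequences follow a Gumbel law with
    P(S >= x) ~ 1 - exp(-K m n e^{-lambda x}); a Gumbel fit to simulated
    scores yields lambda = 1/beta and K = exp(mu/beta) / (m n).
    """
    from scipy.stats import gumbel_r

    al = scheme.aligner()
    bases = np.array(list("ACGT"))
    scores = np.empty(n_pairs)
    for i in range(n_pairs):
        a = "".join(rng.choice(bases, length))
        b = "".join(rng.choice(bases, length))
        scores[i] = al.score(a, b)
    mu, beta = gumbel_r.fit(scores)
    lam = 1.0 / beta
    k = float(np.exp(mu / beta) / (length * length))
    out = ScoringScheme(
        match=scheme.match,
        mismatch=scheme.mismatch,
        gap_open=scheme.gap_open,
        gap_extend=scheme.gap_extend,
        karlin_lambda=lam,
        karlin_k=k,
    )
    logger.info("calibrated Karlin parameters: lambda=%.4f K=%.4g", lam, k)
    return out


# ---------------------------------------------------------------------------
# Seed-and-extend genome scan
# ---------------------------------------------------------------------------

_ENC = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of all N-free k-mers; codes are base-4 integers."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + enc[j : j + n]
    bad = (enc >= 4).astype(np.int64)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    pos = np.nonzero(valid)[0]
    return codes[pos], pos


class GenomeIndex:
    """Sorted k-mer index over one genome record, reusable across searches."""

    def __init__(self, record: DnaRecord, k: int = 11):
        self.record = record
        self.k = k
        codes, pos = _kmer_codes(_encode(record.seq), k)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.positions = pos[order]

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.positions[lo:hi]


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def cigar_tokens(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(num)) for num, op in _CIGAR_RE.findall(cigar)]


def canonicalize_tokens(
    tokens: list[tuple[str, int]], cap: int = 40
) -> list[tuple[str, int]]:
    """Rewrite balanced insertion/deletion windows as diagonal runs.

    Under unit edit costs a mismatch pair ties with a compensating I/D pair,
    and edlib resolves the tie the same way for every copy aligned to one
    reference — which would fabricate systematic gap columns in a pile-up.
    Any window of at most ``cap`` columns that consumes equal query and
    target and contains both an I and a D is replaced by an 'M' run (match
    status is recomputed from the sequences downstream).
    """
    out: list[tuple[str, int]] = []
    i = 0
    n = len(tokens)
    while i < n:
        op, L = tokens[i]
        if op in "ID":
            cumq = cumt = 0
            seen_i = seen_d = False
            j = i
            cols = 0
            balanced_at = None
            while j < n and cols <= cap:
                o, l = tokens[j]
                if o == "I":
                    cumq += l
                    seen_i = True
                elif o == "D":
                    cumt += l
                    seen_d = True
                else:
                    cumq += l
                    cumt += l
                cols += l
                j += 1
                if cumq == cumt and seen_i and seen_d:
                    balanced_at = j
                    break
            if balanced_at is not None:
                out.append(("M", cumq))
                i = balanced_at
                continue
        out.append((op, L))
        i += 1
    return out


def _rescore_path(cigar: str, scheme: ScoringScheme):
    """Trim an edlib path to its maximum-scoring subpath under the scheme.

    Runs of the extended CIGAR become Kadane items (=: positive, X and gaps:
    negative, gaps costed affine). Returns (score, q_off, q_len, t_off,
    t_len, matches, sub_cols) of the best subpath, or None if no positive
    segment exists. Offsets are relative to the path start; sub_cols counts
    gap-free columns.
    """
    items = []  # (dscore, dq, dt, n_match, n_sub)
    for num, op in _CIGAR_RE.findall(cigar):
        L = int(num)
        if op == "=":
            items.append((L * scheme.match, L, L, L, L))
        elif op in ("X", "M"):
            items.append((L * scheme.mismatch, L, L, 0, L))
        elif op == "I":  # consumes query
            items.append((scheme.gap_open + (L - 1) * scheme.gap_extend, L, 0, 0, 0))
        else:  # D consumes target
            items.append((scheme.gap_open + (L - 1) * scheme.gap_extend, 0, L, 0, 0))
    best = (0.0, 0, 0)  # score, start_item, end_item (exclusive)
    cur = 0.0
    cur_start = 0
    for i, it in enumerate(items):
        if cur <= 0:
            cur = 0.0
            cur_start = i
        cur += it[0]
        if cur > best[0]:
            best = (cur, cur_start, i + 1)
    score, s, e = best
    if score <= 0 or s >= e:
        return None
    q_off = sum(it[1] for it in items[:s])
    t_off = sum(it[2] for it in items[:s])
    dq = sum(it[1] for it in items[s:e])
    dt = sum(it[2] for it in items[s:e])
    n_match = sum(it[3] for it in items[s:e])
    n_cols = sum(it[4] for it in items[s:e])
    return score, q_off, dq, t_off, dt, n_match, n_cols


def _extend_window(
    query: str,
    window: str,
    scheme: ScoringScheme,
    evalue_cutoff: float,
    m: int,
    n_total: int,
    min_len: int = 20,
):
    """Align query into window with edlib, trim, recurse around each hit.

    Yields (score, q_start, q_end, w_start, w_end, matches, cols) tuples in
    window coordinates; handles windows holding more than one copy by
    re-aligning the flanking remainders after each accepted hit.
    """
    out = []
    stack = [(0, window)]
    while stack:
        off, seg = stack.pop()
        if len(seg) < min_len:
            continue
        res = edlib.align(query, seg, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        t_start = res["locations"][0][0]
        trimmed = _rescore_path(res["cigar"], scheme)
        if trimmed is None:
            continue
        score, q_off, dq, t_off, dt, n_match, n_cols = trimmed
        if dt < 1 or evalue_of(score, m, n_total, scheme) > evalue_cutoff:
            continue
        w_s = off + t_start + t_off
        w_e = w_s + dt
        out.append((score, q_off, q_off + dq, w_s, w_e, n_match, n_cols))
        left = seg[: t_start + t_off]
        right = seg[t_start + t_off + dt :]
        if len(left) >= min_len:
            stack.append((off, left))
        if len(right) >= min_len:
            stack.append((off + t_start + t_off + dt, right))
    return out


def _seed_windows(
    index: GenomeIndex, query_enc_codes, query_len: int, pad: int = 150
) -> list[tuple[int, int]]:
    """Merge seed matches into candidate genome windows."""
    codes, qpos = query_enc_codes
    if len(codes) == 0:
        return []
    starts = []
    uniq, inv = np.unique(codes, return_inverse=True)
    lo = np.searchsorted(index.codes, uniq, side="left")
    hi = np.searchsorted(index.codes, uniq, side="right")
    for i in range(len(codes)):
        u = inv[i]
        if hi[u] > lo[u]:
            gp = index.positions[lo[u] : hi[u]]
            starts.append(gp - qpos[i])
    if not starts:
        return []
    anchors = np.sort(np.concatenate(starts))
    glen = len(index.record.seq)
    windows: list[tuple[int, int]] = []
    w_s = anchors[0]
    w_e = anchors[0]
    for a in anchors[1:]:
        if a - w_e <= query_len:
            w_e = a
        else:
            windows.append((max(0, w_s - pad), min(glen, w_e + query_len + pad)))
            w_s = w_e = a
    windows.append((max(0, w_s - pad), min(glen, w_e + query_len + pad)))
    # merge any residual overlaps
    merged: list[tuple[int, int]] = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _resolve_strand_overlaps(hits: list[Hit]) -> list[Hit]:
    """Keep the higher-scoring hit where opposite strands overlap >50%."""
    hits = sorted(hits, key=lambda h: (h.genome_iv.seq_id, h.genome_iv.start, h.strand))
    dropped = set()
    for i in range(len(hits)):
        if i in dropped:
            continue
        for j in range(i + 1, len(hits)):
            a, b = hits[i], hits[j]
            if a.genome_iv.seq_id != b.genome_iv.seq_id:
                break
            if b.genome_iv.start >= a.genome_iv.end:
                break
            if a.strand == b.strand:
                continue
            ov = min(a.genome_iv.end, b.genome_iv.end) - b.genome_iv.start
            if ov <= 0.5 * min(len(a.genome_iv), len(b.genome_iv)):
                continue
            if a.score > b.score:
                dropped.add(j)
            elif b.score > a.score:
                dropped.add(i)
            else:
                dropped.add(j if a.strand == "+" else i)
    return [h for i, h in enumerate(hits) if i not in dropped]


def search_genome(
    consensus: DnaRecord,
    genome: Sequence[DnaRecord],
    config: PipelineConfig | None = None,
    scheme: ScoringScheme | None = None,
    indexes: dict[str, GenomeIndex] | None = None,
) -> list[Hit]:
    """Find all significant copies of a consensus in a genome, both strands.

    Minus-strand matches are located by searching the reverse complement of
    the consensus and are reported in forward genome coordinates with
    consensus coordinates in forward consensus orientation. Hits with
    e-value <= config.evalue_dna are kept, sorted by genome position.
    """
    config = config or PipelineConfig()
    scheme = scheme or ScoringScheme()
    if len(consensus.seq) < 30:
        raise ValueError("consensus shorter than 30 bp")
    k = config.seed_k
    qlen = len(consensus.seq)
    n_total = sum(len(g.seq) for g in genome)
    hits: list[Hit] = []
    for rec in genome:
        if len(rec.seq) < k:
            logger.warning("genome record %s shorter than seed length; skipped", rec.id)
            continue
        if indexes is not None and rec.id in indexes:
            index = indexes[rec.id]
        else:
            index = GenomeIndex(rec, k=k)
            if indexes is not None:
                indexes[rec.id] = index
        for strand, qseq in (("+", consensus.seq), ("-", revcomp(consensus.seq))):
            qc = _kmer_codes(_encode(qseq), k)
            for w_s, w_e in _seed_windows(index, qc, qlen):
                window = rec.seq[w_s:w_e]
                for score, q_s, q_e, t_s, t_e, n_match, n_cols in _extend_window(
                    qseq, window, scheme, config.evalue_dna, qlen, n_total
                ):
                    if strand == "-":
                        q_s, q_e = qlen - q_e, qlen - q_s
                    hits.append(
                        Hit(
                            family=consensus.id,
                            genome_iv=GenomicInterval(rec.id, w_s + t_s, w_s + t_e, strand),
                            q_start=q_s,
                            q_end=q_e,
                            strand=strand,
                            score=score,
                            evalue=evalue_of(score, qlen, n_total, scheme),
                            pct_identity=100.0 * n_match / n_cols if n_cols else 0.0,
                            aligned_len=n_cols,
                        )
                    )
    hits = _resolve_strand_overlaps(hits)
    hits.sort(key=lambda h: (h.genome_iv.seq_id, h.genome_iv.start, h.genome_iv.end))
    logger.info(
        "search %s: %d significant hits at e<=%g", consensus.id, len(hits), config.evalue_dna
    )
    return hits
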