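"""Iterative majority-rule consensus reconstruction.

The procedure mirrors standard repeat-library practice: a seed query is
searched against the genome, the top-scoring full-length hits (default 50)
are piled up against the query and a per-column majority vote yields a
round-1 consensus; an exhaustive re-search with that consensus collects all
copies, whose pile-up gives the final consensus. Query construction by
joining element ends and ORF-based validation of autonomous-element
consensuses live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np
from Bio.Seq import Seq

from .align import (
    Hit,
    ScoringScheme,
    _rescore_path,
    canonicalize_tokens,
    cigar_tokens,
    evalue_of,
    search_genome,
)
from .io import DnaRecord, PipelineConfig, revcomp

logger = logging.getLogger("sidescan")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
GAP_ROW = 4  # row index of the gap counts in a profile matrix


class ConsensusError(RuntimeError):
    """A consensus-building stage could not proceed."""


@dataclass
class ConsensusProfile:
    """Per-column base/gap counts over copies anchored to a reference.

    ``counts`` is a 5 x L integer matrix (rows A, C, G, T, gap) in reference
    coordinates; ``depth`` is the number of anchored copies; insertions
    relative to the reference are tallied in ``n_insertions`` but excluded
    from the matrix, so the consensus cannot grow within a round.
    """

    counts: np.ndarray
    depth: int
    reference: DnaRecord
    n_insertions: int = 0

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class OrfReport:
    """Longest open reading frame found across the six frames."""

    best_orf_start: int
    best_orf_end: int
    length_aa: int
    frame: int
    strand: str
    passes: bool


def select_full_length_hits(
    hits: list[Hit], consensus_len: int, config: PipelineConfig
) -> list[Hit]:
    """The first (top-scoring) n_seed_hits hits spanning >= full_length_frac
    of the consensus.

    Raises ConsensusError when no hit qualifies, pointing at
    full_length_frac as the knob to lower.
    """
    ordered = sorted(hits, key=lambda h: -h.score)
    min_span = config.full_length_frac * consensus_len
    qualifying = [h for h in ordered if (h.q_end - h.q_start) >= min_span]
    if not qualifying:
        raise ConsensusError(
            "no full-length hits at full_length_frac="
            f"{config.full_length_frac}; lower it to admit shorter copies"
        )
    return qualifying[: config.n_seed_hits]


def extract_copy(genome: dict[str, DnaRecord], hit: Hit, flank: int = 0) -> DnaRecord:
    """Pull a hit's genome sequence, oriented to the consensus forward strand.

    A small ``flank`` restores terminal bases that local-alignment trimming
    clipped off a diverged copy; anchoring drops whatever does not belong.
    """
    rec = genome[hit.genome_iv.seq_id]
    s = max(0, hit.genome_iv.start - flank)
    e = min(len(rec.seq), hit.genome_iv.end + flank)
    seq = rec.seq[s:e]
    if hit.strand == "-":
        seq = revcomp(seq)
    return DnaRecord(
        id=f"{rec.id}:{hit.genome_iv.start}-{hit.genome_iv.end}({hit.strand})",
        seq=seq,
    )


def anchor_align(
    copies: list[DnaRecord],
    reference: DnaRecord,
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-10,
) -> ConsensusProfile:
    """Pile copies onto reference columns by pairwise anchoring.

    Each copy is aligned to the reference (edlib infix alignment, rescored
    under the scheme); its bases fall into the reference columns they pair
    with, deletions add to the gap row, insertions are counted but dropped.
    Copies without a significant alignment are dropped with a warning.
    """
    scheme = scheme or ScoringScheme()
    L = len(reference.seq)
    counts = np.zeros((5, L), dtype=np.int64)
    ref_n = len(reference.seq)
    n_ins = 0
    depth = 0
    for copy in copies:
        res = edlib.align(copy.seq, reference.seq, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            logger.warning("copy %s: no alignment to reference; dropped", copy.id)
            continue
        trimmed = _rescore_path(res["cigar"], scheme)
        if trimmed is None or evalue_of(trimmed[0], len(copy.seq), ref_n, scheme) > evalue_cutoff:
            logger.warning("copy %s: no significant alignment; dropped", copy.id)
            continue
        depth += 1
        t_pos = res["locations"][0][0]
        q_pos = 0
        for op, n in canonicalize_tokens(cigar_tokens(res["cigar"])):
            if op in ("=", "X", "M"):
                for i in range(n):
                    base = copy.seq[q_pos + i]
                    if base in _BASE_INDEX:
                        counts[_BASE_INDEX[base], t_pos + i] += 1
                q_pos += n
                t_pos += n
            elif op == "I":  # insertion relative to reference: dropped
                n_ins += n
                q_pos += n
            else:  # D: deletion in copy -> gap in these columns
                counts[GAP_ROW, t_pos : t_pos + n] += 1
                t_pos += n
    if n_ins:
        logger.info("anchor_align: %d inserted bases excluded from profile", n_ins)
    return ConsensusProfile(counts=counts, depth=depth, reference=reference, n_insertions=n_ins)


def majority_consensus(profile: ConsensusProfile, min_depth: int = 1) -> DnaRecord:
    """Per-column majority base; gap-majority columns are removed.

    Ties between bases are broken by the fixed order A < C < G < T (tie
    count logged). Columns covered by fewer than min_depth copies fall back
    to the reference base.
    """
    if profile.depth < 2:
        raise ConsensusError("majority consensus requires depth >= 2")
    counts = profile.counts
    base_counts = counts[:4]
    best = base_counts.max(axis=0)
    # argmax returns the lowest index on ties = the fixed A<C<G<T order
    call = base_counts.argmax(axis=0)
    n_ties = int(((base_counts == best).sum(axis=0) > 1).sum())
    if n_ties:
        logger.info("majority_consensus: %d tied columns broken by base order", n_ties)
    covered = counts.sum(axis=0)
    gap_major = counts[GAP_ROW] > best
    out = []
    for j in range(profile.length):
        if gap_major[j]:
            continue
        if covered[j] < min_depth or best[j] == 0:
            out.append(profile.reference.seq[j])
        else:
            out.append(_BASES[call[j]])
    return DnaRecord(id=f"{profile.reference.id}_consensus", seq="".join(out))


def iterate_consensus(
    genome: list[DnaRecord],
    seed_query: DnaRecord,
    config: PipelineConfig | None = None,
    scheme: ScoringScheme | None = None,
    indexes: dict | None = None,
) -> tuple[DnaRecord, ConsensusProfile]:
    """Two-round consensus: seed search -> top full-length pile-up ->
    exhaustive re-search -> final consensus from all positive hits."""
    config = config or PipelineConfig()
    scheme = scheme or ScoringScheme()
    genome_map = {g.id: g for g in genome}
    if indexes is None:
        indexes = {}

    hits1 = search_genome(seed_query, genome, config, scheme, indexes=indexes)
    if not hits1:
        raise ConsensusError("seed query produced no significant hits")
    seeds = select_full_length_hits(hits1, len(seed_query.seq), config)
    logger.info(
        "consensus round 1: %d hits, %d full-length seeds", len(hits1), len(seeds)
    )
    copies1 = [extract_copy(genome_map, h, flank=15) for h in seeds]
    profile1 = anchor_align(copies1, seed_query, scheme, config.evalue_dna)
    cons1 = majority_consensus(profile1)
    cons1.id = f"{seed_query.id}_r1"

    hits2 = search_genome(cons1, genome, config, scheme, indexes=indexes)
    logger.info("consensus round 2: %d hits", len(hits2))
    copies2 = [extract_copy(genome_map, h, flank=15) for h in hits2]
    profile2 = anchor_align(copies2, cons1, scheme, config.evalue_dna)
    final = majority_consensus(profile2)
    final.id = f"{seed_query.id}_consensus"
    return final, profile2


def join_ends(element: DnaRecord, five_len: int, three_len: int) -> DnaRecord:
    """Concatenate the element's first five_len and last three_len bases.

    The joined query finds short internally deleted derivatives whose only
    homology to the full element lies at its two ends.
    """
    if five_len < 0 or three_len < 0 or five_len + three_len > len(element.seq):
        raise ValueError(
            f"join_ends: five_len + three_len must be <= element length "
            f"({len(element.seq)})"
        )
    seq = element.seq[:five_len] + (element.seq[-three_len:] if three_len else "")
    return DnaRecord(id=f"{element.id}_joined", seq=seq, description=element.description)


def validate_orf(consensus: DnaRecord, min_aa: int = 300) -> OrfReport:
    """Longest ATG-to-stop ORF across all six frames, standard code.

    passes requires length_aa >= min_aa (default 300 aa, the scale of a
    reverse-transcriptase-bearing LINE ORF); an internally deleted
    derivative fails because the deletion destroys the reading frame.
    """
    if len(consensus.seq) < 3 * min_aa and len(consensus.seq) < 3:
        raise ValueError("sequence too short for ORF scan")
    best = OrfReport(0, 0, 0, 0, "+", False)
    L = len(consensus.seq)
    for strand in ("+", "-"):
        seq = consensus.seq if strand == "+" else revcomp(consensus.seq)
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            start = None
            for i, c in enumerate(aa + "*"):
                if c == "M" and start is None:
                    start = i
                elif c == "*" and start is not None:
                    if i < len(aa):  # require a real stop codon
                        length_aa = i - start
                        if length_aa > best.length_aa:
                            nt_s = frame + 3 * start
                            nt_e = frame + 3 * (i + 1)
                            if strand == "-":
                                nt_s, nt_e = L - nt_e, L - nt_s
                            best = OrfReport(nt_s, nt_e, length_aa, frame, strand, False)
                    start = None
    best.passes = best.length_aa >= min_aa
    return best
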