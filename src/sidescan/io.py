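"""Readers, writers and configuration for the pipeline.

All coordinates are 0-based, half-open, on the forward strand of the named
sequence. Minus-strand hits carry a strand flag but keep forward genome
coordinates (RepeatMasker convention); consensus coordinates always refer to
the consensus in its forward orientation. BED export is native; GFF3 export
converts to 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("sidescan")

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DnaRecord:
    """A named DNA sequence over the strict alphabet {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


class FastaFormatError(ValueError):
    """Malformed FASTA input, with the offending line number when known."""


def _clean_seq(seq: str, rec_id: str) -> str:
    up = seq.upper()
    if set(up) <= DNA_ALPHABET:
        return up
    n_bad = sum(1 for c in up if c not in DNA_ALPHABET)
    logger.warning(
        "record %s: %d non-ACGTN characters mapped to N", rec_id, n_bad
    )
    return "".join(c if c in DNA_ALPHABET else "N" for c in up)


def read_fasta(path: str | Path) -> list[DnaRecord]:
    """Read a FASTA file into DnaRecords, order preserved.

    Sequences are uppercased; ambiguity codes and other non-ACGT characters
    are mapped to N with a logged warning. Empty sequences are an error.
    """
    path = Path(path)
    records: list[DnaRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise FastaFormatError(
                    f"{path}: record {rec.id!r} has empty sequence"
                )
            records.append(
                DnaRecord(id=rec.id, seq=_clean_seq(seq, rec.id),
                          description=rec.description)
            )
    except FastaFormatError:
        raise
    except ValueError as exc:
        raise FastaFormatError(f"{path}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[DnaRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with fixed line width (round-trips with read_fasta)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        for rec in bio:
            header = rec.description if rec.description and rec.description != rec.id else rec.id
            fh.write(f">{header}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "score",
    "pct_identity",
    "evalue",
    "seq_id",
    "start",
    "end",
    "strand",
    "family",
    "q_start",
    "q_end",
    "aligned_len",
]

HIT_TABLE_DIALECTS = ("tsv", "bed", "gff3")


def hits_to_frame(hits: Sequence) -> pd.DataFrame:
    """Tabulate Hit objects (align.Hit) into the documented column set."""
    rows = [
        {
            "score": h.score,
            "pct_identity": round(h.pct_identity, 2),
            "evalue": h.evalue,
            "seq_id": h.genome_iv.seq_id,
            "start": h.genome_iv.start,
            "end": h.genome_iv.end,
            "strand": h.strand,
            "family": h.family,
            "q_start": h.q_start,
            "q_end": h.q_end,
            "aligned_len": h.aligned_len,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hit_table(hits: Sequence, path: str | Path, dialect: str = "tsv") -> None:
    """Write hits as TSV (full columns), BED6 or GFF3.

    TSV round-trips byte-identically through read_hit_table. BED6 and GFF3
    carry the same genomic intervals; GFF3 coordinates are 1-based inclusive.
    """
    if dialect not in HIT_TABLE_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; choose from {HIT_TABLE_DIALECTS}"
        )
    frame = hits_to_frame(hits)
    if dialect == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif dialect == "bed":
        with open(path, "w") as fh:
            for _, r in frame.iterrows():
                fh.write(
                    f"{r.seq_id}\t{r.start}\t{r.end}\t{r.family}\t"
                    f"{int(round(r.score))}\t{r.strand}\n"
                )
    else:  # gff3
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, r in frame.iterrows():
                attrs = (
                    f"ID={r.family}_{r.seq_id}_{r.start};family={r.family};"
                    f"q_start={r.q_start};q_end={r.q_end};"
                    f"pct_identity={r.pct_identity}"
                )
                fh.write(
                    f"{r.seq_id}\tsidescan\tdispersed_repeat\t{r.start + 1}\t{r.end}\t"
                    f"{int(round(r.score))}\t{r.strand}\t.\t{attrs}\n"
                )


def read_hit_table(path: str | Path):
    """Read a TSV hit table back into a list of align.Hit objects."""
    from .align import Hit  # local import to avoid a cycle

    frame = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: hit table missing columns {sorted(missing)}")
    hits = []
    for _, r in frame.iterrows():
        hits.append(
            Hit(
                family=str(r.family),
                genome_iv=GenomicInterval(str(r.seq_id), int(r.start), int(r.end), str(r.strand)),
                q_start=int(r.q_start),
                q_end=int(r.q_end),
                strand=str(r.strand),
                score=float(r.score),
                evalue=float(r.evalue),
                pct_identity=float(r.pct_identity),
                aligned_len=int(r.aligned_len),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across pipeline stages.

    evalue_dna / evalue_protein are significance cut-offs (hits with
    e-value <= threshold are kept). min_fragment_len is the fragment filter
    applied before defragmentation so SIDE and LINE hits cannot mask each
    other's copies: fragments shorter than the longest region the two
    families share are discarded (160 bp default; 250 bp for genomes where
    the shared ends are longer).
    """

    evalue_dna: float = 1e-10
    evalue_protein: float = 1e-5
    n_seed_hits: int = 50
    full_length_frac: float = 0.90
    min_fragment_len: int = 160
    merge_max_gap: int = 50
    landscape_bin_width: float = 0.01
    tsd_search_window: int = 20
    seed_k: int = 11
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "evalue_dna",
            "evalue_protein",
            "n_seed_hits",
            "min_fragment_len",
            "landscape_bin_width",
            "tsd_search_window",
            "seed_k",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be > 0")
        if self.merge_max_gap < 0:
            raise ValueError("config: merge_max_gap must be >= 0")
        if not (0 < self.full_length_frac <= 1):
            raise ValueError("config: full_length_frac must be in (0, 1]")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a key-value (YAML) config file, apply overrides, fill defaults.

    Unknown keys raise a ValueError listing the valid keys. The resulting
    configuration is logged at INFO level.
    """
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - valid
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    cfg = PipelineConfig(**values)
    logger.info("config: %s", cfg)
    return cfg


def setup_logging(level: str = "INFO") -> None:
    """Route pipeline logging to standard error."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
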