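"""Readers and writers for the plain-text formats the pipeline touches.

FASTA/FASTQ parsing and emission is delegated to Biopython; this module adds
the validation the pipeline relies on (restricted alphabet, sequence/quality
length equality, mate pairing) plus a YAML run configuration with documented
defaults and stderr logging. Coordinates everywhere in the package are
0-based, half-open; strand is "+"/"-"; FASTQ qualities are Phred+33.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")

log = logging.getLogger("rhbulkseq")


def configure_logging(level: str = "INFO") -> None:
    """Log to stderr with the given level name."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass
class SeqRecord:
    """A named DNA sequence over {A, C, G, T, N}, stored uppercase."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be nonempty")
        self.sequence = self.sequence.upper()
        extra = set(self.sequence) - VALID_BASES
        if extra:
            raise ValueError(
                f"record {self.id!r}: invalid bases {sorted(extra)} (alphabet ACGTN)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FastqRecord:
    """Single-end read: sequence plus Phred+33 quality of equal length."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )


@dataclass
class ReadPair:
    """A mate pair; each mate's quality string matches its length."""

    id: str
    mate1: str
    mate2: str
    qual1: str = ""
    qual2: str = ""

    def __post_init__(self) -> None:
        if not self.qual1:
            self.qual1 = "I" * len(self.mate1)
        if not self.qual2:
            self.qual2 = "I" * len(self.mate2)
        if len(self.mate1) != len(self.qual1) or len(self.mate2) != len(self.qual2):
            raise FormatError(f"read pair {self.id!r}: mate/quality length mismatch")


def read_fasta(path) -> list[SeqRecord]:
    """Parse a FASTA file into SeqRecords (order preserved, uppercased)."""
    path = Path(path)
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file (line 1)")
        lineno, line = first
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected '>' header, got {line.strip()!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, sequence=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 80) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path) -> list[FastqRecord]:
    """Parse 4-line FASTQ records; enforces seq/qual length equality."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            records.append(FastqRecord(id=rec.id, sequence=str(rec.seq), quality=qual))
    except ValueError as exc:  # Biopython reports the offending record in the message
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def _strip_mate_suffix(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def pair_reads(mates1: list[FastqRecord], mates2: list[FastqRecord]) -> list[ReadPair]:
    """Pair r1/r2 records by id (ignoring /1 and /2 suffixes)."""
    by_id = {_strip_mate_suffix(r.id): r for r in mates2}
    pairs = []
    for r1 in mates1:
        key = _strip_mate_suffix(r1.id)
        r2 = by_id.get(key)
        if r2 is None:
            raise FormatError(f"unpaired read {r1.id!r}: no matching mate 2")
        pairs.append(ReadPair(key, r1.sequence, r2.sequence, r1.quality, r2.quality))
    return pairs


def write_read_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    write_fastq([FastqRecord(p.id + "/1", p.mate1, p.qual1) for p in pairs], path1)
    write_fastq([FastqRecord(p.id + "/2", p.mate2, p.qual2) for p in pairs], path2)


INTERVAL_COLUMNS = ["scaffold", "start", "end", "name"]


def read_intervals_tsv(path) -> pd.DataFrame:
    """BED-like TSV (scaffold, start, end, name); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, names=INTERVAL_COLUMNS, comment="#")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_intervals_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=INTERVAL_COLUMNS)


@dataclass
class RunConfig:
    """All pipeline thresholds with their documented defaults.

    seed seeds every random draw in the run. Enzymes are named recognition
    sites cut after base 5. Coverage thresholds follow the presence/absence
    contrast; extension parameters bound the reference-guided growth.
    """

    seed: int = 0
    enzymes: tuple[str, ...] = ("PstI", "AatII")
    read_length: int = 100            # bp per mate
    depth: float = 8.0                # per-line mean fragment-end coverage
    size_min: int = 100               # size-selection window, bp
    size_max: int = 600
    error_rate: float = 0.002         # substitution rate per base
    contam_frac: float = 0.01         # foreign-read fraction
    k: int = 31                       # k-mer size for filtering/anchoring
    min_shared_kmers: int = 1         # read filter retention threshold
    min_overlap: int = 30             # exact-overlap merge threshold, bp
    min_present_cov: float = 5.0      # presence call threshold (x coverage)
    max_absent_cov: float = 0.0       # absence call threshold
    flank: int = 1000                 # extension growth per iteration, bp
    max_len: int = 70_000             # extension length cap, bp
    max_iter: int = 100
    min_log10_lr: float = 1.0         # deletion-typing ambiguity threshold
    breaks_per_Mb: float = 1.0        # radiation breakpoint density
    retention_prob: float = 0.75      # per-segment retention probability

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.contam_frac < 1:
            raise ValueError("contam_frac must be in [0, 1)")
        if self.size_min > self.size_max:
            raise ValueError("size_min must not exceed size_max")


def load_run_config(path) -> RunConfig:
    """Load a YAML config; missing keys take defaults, unknown keys warn."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
            continue
        if key == "enzymes":
            value = tuple(value)
        expected = type(getattr(RunConfig(), key))
        if expected is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, expected):
            raise ValueError(
                f"config key {key!r}: expected {expected.__name__}, got {value!r}"
            )
        kwargs[key] = value
    return RunConfig(**kwargs)
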