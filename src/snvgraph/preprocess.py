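"""Read preprocessing: adapter trimming, filtering and unique-sequence collapsing.

Small-RNA libraries are sequenced through the insert into the 3' adapter, so
the first step is locating the adapter and truncating each read at its start.
Reads containing undetermined bases (``N``) are discarded, reads are restricted
to the insert-length window of interest (20-24 nt by default), and the
survivors are collapsed into per-length tables of unique sequences with their
observed abundances.  Base-call quality strings are carried through unchanged
but never consulted: the downstream error model is built purely from sequence
abundances.

Reads containing homopolymer tracts are deliberately *not* removed here; a
homopolymer read may be the high-abundance parent of erroneous variants, so
its removal is deferred until after error correction (see
:func:`snvgraph.correction.remove_homopolymers`).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "RawRead",
    "UniqueSequence",
    "PreprocessConfig",
    "trim_adapter",
    "filter_and_collapse",
    "read_fastx",
    "write_count_table",
    "read_count_table",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class RawRead:
    """A single sequencing read: bases plus an optional, unused quality string."""

    bases: str
    quality: str | None = None

    def normalized(self) -> "RawRead":
        """Uppercase the bases and map anything outside {A,C,G,T,N} to N."""
        up = self.bases.upper()
        bases = "".join(c if c in _VALID or c == "N" else "N" for c in up)
        return RawRead(bases, self.quality)


@dataclass(frozen=True, order=True)
class UniqueSequence:
    """A distinct read sequence with its observed abundance (the model's X)."""

    seq: str
    abundance: int

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError(f"abundance must be >= 1, got {self.abundance}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class PreprocessConfig:
    """Trimming and filtering parameters.

    ``adapter_mismatch_schedule`` maps a minimum overlap length to the number
    of mismatches tolerated at that overlap; for a given overlap the entry
    with the largest key not exceeding it applies.  Overlaps with no entry
    fall back to ``floor(overlap / 10)`` mismatches, i.e. perfect matching is
    required for short overlaps and roughly one mismatch per ten aligned
    bases thereafter.
    """

    adapter: str = ""
    min_len: int = 20
    max_len: int = 24
    adapter_min_overlap: int = 6
    adapter_mismatch_schedule: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        self.adapter = self.adapter.upper()

    def allowed_mismatches(self, overlap: int) -> int:
        applicable = [k for k in self.adapter_mismatch_schedule if k <= overlap]
        if applicable:
            return self.adapter_mismatch_schedule[max(applicable)]
        return math.floor(overlap / 10)


def trim_adapter(read: RawRead, cfg: PreprocessConfig) -> RawRead:
    """Truncate ``read`` at the leftmost admissible 3' adapter match.

    At every start position the read suffix is compared against the adapter
    prefix of the same length (the adapter may run off the end of the read).
    A start is admissible when the overlap is at least
    ``cfg.adapter_min_overlap`` and the mismatch count is within the
    schedule's allowance.  The read is returned unchanged when no admissible
    start exists.
    """
    if not cfg.adapter:
        raise ValueError("adapter sequence not configured")
    bases = read.bases
    adapter = cfg.adapter
    n, la = len(bases), len(adapter)
    for start in range(n):
        overlap = min(n - start, la)
        if overlap < cfg.adapter_min_overlap:
            break
        budget = cfg.allowed_mismatches(overlap)
        mism = 0
        for a, b in zip(bases[start : start + overlap], adapter[:overlap]):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        if mism <= budget:
            qual = read.quality[:start] if read.quality is not None else None
            return RawRead(bases[:start], qual)
    return read


def filter_and_collapse(
    reads: Iterable[RawRead], cfg: PreprocessConfig
) -> dict[int, list[UniqueSequence]]:
    """Drop N-containing and out-of-length reads; collapse the rest to counts.

    Returns one table per read length in ``[cfg.min_len, cfg.max_len]``, each
    sorted by descending abundance then lexicographically (a stable order so
    repeated runs produce byte-identical downstream files).  Reads trimmed to
    length zero fall out of the length window and are dropped with the rest.
    """
    counters: dict[int, Counter[str]] = {}
    for read in reads:
        read = read.normalized()
        seq = read.bases
        if "N" in seq:
            continue
        length = len(seq)
        if length < cfg.min_len or length > cfg.max_len:
            continue
        counters.setdefault(length, Counter())[seq] += 1
    tables: dict[int, list[UniqueSequence]] = {}
    for length, counter in counters.items():
        recs = [UniqueSequence(s, c) for s, c in counter.items()]
        recs.sort(key=lambda r: (-r.abundance, r.seq))
        tables[length] = recs
    return tables


def read_fastx(path: str | Path) -> Iterator[RawRead]:
    """Yield reads from a FASTQ or FASTA file (format sniffed from content)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    fmt = "fastq" if first.startswith("@") else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        if fmt == "fastq":
            quals = rec.letter_annotations.get("phred_quality")
            qual = (
                "".join(chr(q + 33) for q in quals) if quals is not None else None
            )
        else:
            qual = None
        yield RawRead(str(rec.seq), qual)


def write_count_table(records: Iterable[UniqueSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq\tabundance\n")
        for rec in records:
            fh.write(f"{rec.seq}\t{rec.abundance}\n")


def read_count_table(path: str | Path) -> list[UniqueSequence]:
    records: list[UniqueSequence] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("seq"):
            raise ValueError(f"{path}: expected 'seq<TAB>abundance' header")
        for line in fh:
            seq, ab = line.rstrip("\n").split("\t")
            records.append(UniqueSequence(seq, int(ab)))
    return records


def preprocess_reads(
    reads: Iterable[RawRead], cfg: PreprocessConfig, trim: bool = True
) -> dict[int, list[UniqueSequence]]:
    """Full preprocessing: optional adapter trimming, then filter + collapse."""
    if trim:
        reads = (trim_adapter(r, cfg) for r in reads)
    return filter_and_collapse(reads, cfg)
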