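"""Scoring a correction run against truth labels or a reference genome.

Two truth sources are supported.  Simulated datasets carry explicit labels
(:class:`~snvgraph.simulate.TruthRecord`).  For real control libraries (e.g. a
PhiX spike-in) truth is derived by matching every unique sequence against the
reference: a sequence matching some reference window exactly is "correct",
anything at one or more mismatches is "erroneous".  Matching is an exhaustive
Hamming scan over all equal-length windows of both strands, with the
reference treated as circular (small control genomes usually are), and
distances beyond ``max_mismatch`` reported as a single ">k" class the way
mapping-software mismatch caps truncate such tables.

Following the error-correction usage, *sensitivity* is the fraction of
correct reads the corrector retained and *specificity* is the fraction of
erroneous reads it identified (classified as errors).  Both are computed
over read counts by default; a unique-sequence variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .correction import CorrectionOutcome
from .simulate import TruthRecord

__all__ = [
    "ConfusionCounts",
    "match_reference",
    "mismatch_profile",
    "score",
    "truth_from_distances",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass
class ConfusionCounts:
    """Correction-vs-truth confusion table (read counts or sequence counts)."""

    correct_retained: int = 0
    correct_removed: int = 0
    error_removed: int = 0
    error_retained: int = 0

    @property
    def total(self) -> int:
        return (
            self.correct_retained
            + self.correct_removed
            + self.error_removed
            + self.error_retained
        )

    @property
    def sensitivity(self) -> float:
        denom = self.correct_retained + self.correct_removed
        return self.correct_retained / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.error_removed + self.error_retained
        return self.error_removed / denom if denom else float("nan")


def match_reference(
    seqs: Iterable[str],
    reference: str,
    max_mismatch: int = 3,
    circular: bool = True,
) -> dict[str, int]:
    """Best Hamming distance of each sequence to any reference window.

    Scans every window of matching length on both strands; with
    ``circular=True`` the reference is extended so origin-spanning windows
    are covered.  Distances above ``max_mismatch`` are reported as
    ``max_mismatch + 1`` (the ">k" class).
    """
    reference = reference.upper()
    seq_list = sorted(set(seqs))
    out: dict[str, int] = {}
    by_len: dict[int, list[str]] = {}
    for s in seq_list:
        if len(s) > len(reference):
            raise ValueError("sequence longer than the reference")
        by_len.setdefault(len(s), []).append(s)
    for L, group in by_len.items():
        windows = []
        for strand in (reference, _revcomp(reference)):
            ext = strand + (strand[: L - 1] if circular else "")
            arr = _encode(ext)
            windows.append(np.lib.stride_tricks.sliding_window_view(arr, L))
        wins = np.vstack(windows)
        for s in group:
            d = int((wins != _encode(s)).sum(axis=1).min())
            out[s] = d if d <= max_mismatch else max_mismatch + 1
    return out


def truth_from_distances(distances: Mapping[str, int]) -> dict[str, TruthRecord]:
    """Reference-derived truth: exact match => correct, else erroneous."""
    return {
        s: TruthRecord(is_error=(d != 0), source_parent=None)
        for s, d in distances.items()
    }


def mismatch_profile(
    outcomes: Sequence[CorrectionOutcome],
    distances: Mapping[str, int],
    max_mismatch: int = 3,
) -> pd.DataFrame:
    """Cross-tabulate model calls against best reference mismatch count.

    Rows are mismatch classes (0 .. max_mismatch, then ">k"); columns count
    unique sequences the model called correct (biological) vs erroneous.
    """
    labels = [str(i) for i in range(max_mismatch + 1)] + [f">{max_mismatch}"]
    table = pd.DataFrame(0, index=labels, columns=["correct", "erroneous"])
    for o in outcomes:
        d = distances[o.seq]
        row = labels[d] if d <= max_mismatch else labels[-1]
        col = "correct" if o.classification == "biological" else "erroneous"
        table.loc[row, col] += 1
    return table


def score(
    outcomes: Sequence[CorrectionOutcome],
    truth: Mapping[str, TruthRecord],
    by_reads: bool = True,
    include_unmatched: bool = False,
    unmatched: Iterable[str] = (),
) -> ConfusionCounts:
    """Confusion counts of a correction run against truth labels.

    Retained means classified biological; removed means classified error.
    With ``by_reads`` (default) each sequence contributes its pre-correction
    abundance, matching the convention of quoting rates over sequencing
    reads; otherwise each unique sequence counts once.  Sequences listed in
    ``unmatched`` (e.g. beyond the reference mapper's mismatch cap) are
    excluded from the denominators unless ``include_unmatched`` is set, in
    which case they count as erroneous.
    """
    unmatched_set = set(unmatched)
    counts = ConfusionCounts()
    for o in outcomes:
        if o.seq in unmatched_set and not include_unmatched:
            continue
        if o.seq not in truth and o.seq not in unmatched_set:
            raise KeyError(f"no truth label for sequence {o.seq!r}")
        is_error = True if o.seq in unmatched_set else truth[o.seq].is_error
        w = o.abundance_before if by_reads else 1
        retained = o.classification == "biological"
        if is_error and retained:
            counts.error_retained += w
        elif is_error:
            counts.error_removed += w
        elif retained:
            counts.correct_retained += w
        else:
            counts.correct_removed += w
    return counts


def write_report(
    counts: ConfusionCounts,
    path: str | Path,
    profile: pd.DataFrame | None = None,
) -> None:
    with open(path, "w") as fh:
        if profile is not None:
            fh.write(profile.to_csv(sep="\t", index_label="mismatches"))
            fh.write("\n")
        fh.write(f"sensitivity\t{counts.sensitivity:.4f}\n")
        fh.write(f"specificity\t{counts.specificity:.4f}\n")
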