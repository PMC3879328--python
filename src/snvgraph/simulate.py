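"""Synthetic short-read datasets with a known error process and truth labels.

The simulator emulates a deeply sequenced small-RNA library: a set of
distinct "parent" insert sequences of lengths 20-24 with heavy-tailed
(log-uniform) abundances, each copy of which is then pushed through a
per-cycle substitution-error process.  Errors are drawn per position from a
categorical distribution over {no error, 3 alternative bases} whose
probabilities come from a generating :class:`~snvgraph.error_model.ErrorModel`
— by default the Illumina GA profile with its position-1 spike and
exponentially rising per-cycle rates.  Marginally, the error count in every
(position, substitution) cell is binomial; jointly, a single copy can pick up
errors at several positions, producing the deeper graph levels that stress
the breadth-first corrector.

Parents are drawn with pairwise Hamming distance >= 3 within each length, so
single- and double-error children can never coincide with (or bridge to)
another parent and truth labels stay unambiguous.  Every emitted sequence is
labelled: parents are correct, everything else is an error traceable to its
source parent.

What this generator does not emulate: true biological variants sharing a
subgraph with their parent, quality-score structure, indels, adapter
read-through, and lane- or flowcell-position effects.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .error_model import (
    SUBSTITUTIONS,
    ErrorModel,
    ExpFit,
    ModelConfig,
    RateSurface,
    Substitution,
    estimate_model,
)
from .preprocess import UniqueSequence
from .variant_graph import build_graph, connected_subgraphs

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulatedDataset",
    "illumina_ga_lane2_model",
    "simulate_dataset",
    "fit_from_tables",
    "roundtrip_recovery",
]

_BASES = "ACGT"

# Illumina GA (outer-lane) reference profile: raw position-1 rate plus
# exponential parameters (A, b) over positions 2-24 for each substitution.
# C>A and G>T dominate (crosstalk), and A>T rises fastest along the read
# (T-fluorophore accumulation).
_GA_LANE2 = {
    "A>C": (1.4e-03, 1.4e-04, 0.11),
    "A>G": (5.1e-04, 2.0e-04, 0.04),
    "A>T": (4.1e-04, 3.4e-05, 0.15),
    "C>A": (2.8e-03, 4.3e-04, 0.07),
    "C>G": (4.2e-04, 8.0e-05, 0.05),
    "C>T": (6.3e-04, 2.1e-04, 0.07),
    "G>A": (4.3e-04, 1.6e-04, 0.05),
    "G>C": (5.1e-04, 1.4e-04, 0.10),
    "G>T": (1.5e-03, 3.5e-04, 0.10),
    "T>A": (3.6e-04, 7.4e-05, 0.08),
    "T>C": (6.1e-04, 3.5e-04, 0.04),
    "T>G": (3.3e-04, 2.8e-04, 0.05),
}


def illumina_ga_lane2_model() -> ErrorModel:
    """The Illumina GA outer-lane error profile used as the default generator."""
    position1: dict[Substitution, float] = {}
    fits: dict[Substitution, ExpFit] = {}
    for name, (p1, A, b) in _GA_LANE2.items():
        sub = Substitution.parse(name)
        position1[sub] = p1
        fits[sub] = ExpFit(sub, A, b)
    return ErrorModel(position1, fits)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Abundances are log-uniform between the configured bounds, emulating the
    heavy-tailed expression range of real small-RNA libraries where a
    handful of sequences occur 10^5+ times.
    """

    n_parents: int = 2000
    length_range: tuple[int, int] = (20, 24)
    abundance_range: tuple[int, int] = (20, 200_000)
    model: ErrorModel = field(default_factory=illumina_ga_lane2_model)
    seed: int = 0
    min_parent_distance: int = 3

    def __post_init__(self) -> None:
        if self.n_parents < 1:
            raise ValueError("n_parents must be >= 1")
        lo, hi = self.abundance_range
        if not 1 <= lo <= hi:
            raise ValueError("abundance bounds must satisfy 1 <= lo <= hi")
        if self.min_parent_distance < 1:
            raise ValueError("min_parent_distance must be >= 1")


class TruthRecord(NamedTuple):
    is_error: bool
    source_parent: str | None


@dataclass
class SimulatedDataset:
    """Collapsed unique-sequence tables plus per-sequence truth labels."""

    tables: dict[int, list[UniqueSequence]]
    truth: dict[str, TruthRecord]
    parents: list[UniqueSequence]

    @property
    def total_reads(self) -> int:
        return sum(r.abundance for t in self.tables.values() for r in t)

    def iter_reads(self) -> Iterator[str]:
        """Expand the tables back into individual read sequences."""
        for length in sorted(self.tables):
            for rec in self.tables[length]:
                for _ in range(rec.abundance):
                    yield rec.seq

    def write_fastq(self, path: str | Path) -> None:
        """Write expanded reads with uninformative qualities (never used)."""
        with open(path, "w") as fh:
            for i, seq in enumerate(self.iter_reads(), 1):
                fh.write(f"@sim_{i}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("seq\tis_error\tsource_parent\n")
            for seq in sorted(self.truth):
                rec = self.truth[seq]
                fh.write(f"{seq}\t{int(rec.is_error)}\t{rec.source_parent or ''}\n")


def _rate_tensor(model: ErrorModel, length: int) -> np.ndarray:
    """rates[pos-1, r1, r2]: model rate at each cell; diagonal zero."""
    rates = np.zeros((length, 4, 4))
    for pos in range(1, length + 1):
        for i, r1 in enumerate(_BASES):
            for j, r2 in enumerate(_BASES):
                if i != j:
                    rates[pos - 1, i, j] = model.rate(pos, Substitution(r1, r2))
    return rates


def _draw_parents(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    lo_l, hi_l = cfg.length_range
    lo_a, hi_a = cfg.abundance_range
    per_length: dict[int, list[np.ndarray]] = {}
    parents: list[tuple[str, int]] = []
    max_attempts = 200 * cfg.n_parents
    attempts = 0
    while len(parents) < cfg.n_parents:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "cannot place the requested number of parents at the "
                "required pairwise distance; reduce n_parents or spacing"
            )
        length = int(rng.integers(lo_l, hi_l + 1))
        cand = rng.integers(0, 4, size=length)
        existing = per_length.get(length)
        if existing is not None:
            dists = (np.asarray(existing) != cand).sum(axis=1)
            if dists.min() < cfg.min_parent_distance:
                continue
        per_length.setdefault(length, []).append(cand)
        abundance = max(1, round(float(np.exp(rng.uniform(np.log(lo_a), np.log(hi_a))))))
        seq = "".join(_BASES[b] for b in cand)
        parents.append((seq, abundance))
    return parents


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate one dataset: parents, per-copy errors, collapsed tables, truth.

    For each parent copy and each position, the called base is categorical
    over {r1, 3 alternatives} with the generating model's probabilities.
    Copies are never materialised individually: per position the error
    counts for the three alternatives are drawn multinomially and assigned
    to uniformly random copy indices (one substitution at most per copy and
    position), and only copies that picked up at least one error are
    expanded into variant sequences.  Output is byte-identical for a fixed
    seed.
    """
    rng = np.random.default_rng(cfg.seed)
    parent_list = _draw_parents(cfg, rng)
    counters: dict[int, Counter[str]] = {}
    truth: dict[str, TruthRecord] = {}
    tensors: dict[int, np.ndarray] = {}

    for pseq, X in parent_list:
        L = len(pseq)
        if L not in tensors:
            tensors[L] = _rate_tensor(cfg.model, L)
        rates = tensors[L]
        enc = np.frombuffer(pseq.encode(), dtype=np.uint8)
        base_idx = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), enc)
        events: dict[int, list[tuple[int, str]]] = {}
        for pos in range(L):
            r1 = int(base_idx[pos])
            targets = [j for j in range(4) if j != r1]
            probs = rates[pos, r1, targets]
            p_tot = probs.sum()
            if p_tot == 0:
                continue
            counts = rng.multinomial(X, [*probs, 1.0 - p_tot])[:3]
            m = int(counts.sum())
            if m == 0:
                continue
            ids = rng.integers(0, X, size=m)
            tgt = np.repeat(targets, counts)
            # at most one substitution per (copy, position): first draw wins
            _, first = np.unique(ids, return_index=True)
            for k in first:
                events.setdefault(int(ids[k]), []).append((pos, _BASES[tgt[k]]))

        counter = counters.setdefault(L, Counter())
        n_err_copies = len(events)
        if X - n_err_copies > 0:
            counter[pseq] += X - n_err_copies
        truth.setdefault(pseq, TruthRecord(False, None))
        for copy_events in events.values():
            chars = list(pseq)
            for pos, base in copy_events:
                chars[pos] = base
            eseq = "".join(chars)
            counter[eseq] += 1
            if eseq not in truth:
                truth[eseq] = TruthRecord(True, pseq)

    tables: dict[int, list[UniqueSequence]] = {}
    for L, counter in counters.items():
        recs = [UniqueSequence(s, c) for s, c in counter.items()]
        recs.sort(key=lambda r: (-r.abundance, r.seq))
        tables[L] = recs
    parent_recs = [UniqueSequence(s, a) for s, a in parent_list]
    return SimulatedDataset(tables, truth, parent_recs)


def fit_from_tables(
    tables: Mapping[int, Sequence[UniqueSequence]],
    model_cfg: ModelConfig | None = None,
) -> tuple[ErrorModel, RateSurface]:
    """Build per-length graphs from count tables and run the estimation pipeline."""
    graphs = []
    for length in sorted(tables):
        g = build_graph(list(tables[length]))
        graphs.append((g, connected_subgraphs(g)))
    return estimate_model(graphs, model_cfg)


def expected_cell_errors(dataset: SimulatedDataset, model: ErrorModel) -> pd.DataFrame:
    """Expected simulated error counts per substitution, from the parent set.

    Returns, per substitution, the expected error-read count at position 1
    and summed over the exponential-fit range — the yardstick for deciding
    which cells carry enough events for parameter recovery to be meaningful.
    """
    rows = []
    for sub in SUBSTITUTIONS:
        e1 = 0.0
        efit = 0.0
        for parent in dataset.parents:
            X = parent.abundance
            for i, base in enumerate(parent.seq):
                if base != sub.r1:
                    continue
                if i == 0:
                    e1 += X * model.rate(1, sub)
                else:
                    efit += X * model.rate(i + 1, sub)
        rows.append({"sub": str(sub), "expected_pos1": e1, "expected_fit_range": efit})
    return pd.DataFrame(rows).set_index("sub")


def roundtrip_recovery(
    cfg: SimConfig, model_cfg: ModelConfig | None = None
) -> pd.DataFrame:
    """Simulate, re-estimate, and tabulate generating vs recovered parameters.

    One row per substitution with the generating and recovered position-1
    rate, amplitude A and exponent b, their ratios, and the expected error
    counts used to flag undersampled cells (``well_sampled`` is False where
    fewer than 50 errors are expected, and ratios there are unreliable).
    """
    dataset = simulate_dataset(cfg)
    recovered, _ = fit_from_tables(dataset.tables, model_cfg)
    expected = expected_cell_errors(dataset, cfg.model)
    rows = []
    for sub in SUBSTITUTIONS:
        gen_p1 = cfg.model.position1.get(sub, 0.0)
        gen_fit = cfg.model.fits.get(sub)
        rec_p1 = recovered.position1.get(sub, 0.0)
        rec_fit = recovered.fits.get(sub)
        rows.append(
            {
                "sub": str(sub),
                "gen_position1": gen_p1,
                "rec_position1": rec_p1,
                "position1_ratio": rec_p1 / gen_p1 if gen_p1 > 0 else np.nan,
                "gen_A": gen_fit.A if gen_fit else 0.0,
                "rec_A": rec_fit.A if rec_fit else 0.0,
                "A_ratio": (rec_fit.A / gen_fit.A)
                if gen_fit and rec_fit and gen_fit.A > 0
                else np.nan,
                "gen_b": gen_fit.b if gen_fit else 0.0,
                "rec_b": rec_fit.b if rec_fit else 0.0,
                "expected_pos1": expected.loc[str(sub), "expected_pos1"],
                "expected_fit_range": expected.loc[str(sub), "expected_fit_range"],
                "well_sampled": bool(
                    expected.loc[str(sub), "expected_pos1"] >= 50
                    and expected.loc[str(sub), "expected_fit_range"] >= 50
                ),
            }
        )
    return pd.DataFrame(rows).set_index("sub")
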