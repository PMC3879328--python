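"""Error classification and correction of variant graphs.

Given a fitted :class:`~snvgraph.error_model.ErrorModel`, each sequence in a
connected subgraph is tested against the abundance the model predicts for a
sequencing error of its kind.  The expected number of erroneous reads for a
substitution R = r1 -> r2 at position ``pos``, given ``N_correct`` reads of
the parent sequence carrying r1 there, follows from the error odds:

    N_error(pos, R) = P_error(pos, R) / (1 - P_error(pos, R)) * N_correct

The null hypothesis is that a child sequence *is* a sequencing error; its
observed abundance is referred to an exact one-sided binomial test with
success probability P_error(pos, R) and n = parent + child abundance.  A
child abundant far beyond expectation rejects the null and is classified a
true biological variant; otherwise it is classified an error and its
abundance merged into the neighbour it was tested against.

Correction walks each subgraph breadth-first from its parent, so sequences
more than one substitution away are handled too: every node is tested
against its most abundant already-classified neighbour, and a node
classified biological becomes the local reference for its own descendants.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

from scipy import stats

from .error_model import ErrorModel, Substitution
from .preprocess import UniqueSequence
from .variant_graph import Subgraph, VariantGraph, build_graph, connected_subgraphs

__all__ = [
    "ExpectedErrors",
    "CorrectionOutcome",
    "expected_errors",
    "classify_child",
    "correct_graph",
    "correct_tables",
    "remove_homopolymers",
    "max_homopolymer_run",
]


class ExpectedErrors(NamedTuple):
    """Model-predicted erroneous-read count for one (position, substitution)."""

    pos: int
    sub: Substitution
    p_error: float
    n_correct: int
    n_error: float


@dataclass
class CorrectionOutcome:
    """Per-sequence classification and, for errors, the merge destination."""

    seq: str
    abundance_before: int
    classification: Literal["error", "biological"]
    merged_into: str | None
    p_value: float | None

    def __post_init__(self) -> None:
        if self.classification == "biological" and self.merged_into is not None:
            raise ValueError("biological sequences are never merged")


def expected_errors(
    model: ErrorModel, parent_abundance: int, pos: int, sub: Substitution
) -> ExpectedErrors:
    """Evaluate the error-odds prediction for one cell."""
    p = model.rate(pos, sub)
    if p >= 1.0:
        raise ValueError(f"degenerate model: P_error({pos}, {sub}) >= 1")
    n_error = p / (1.0 - p) * parent_abundance
    return ExpectedErrors(pos, sub, p, parent_abundance, n_error)


def classify_child(
    child_abundance: int, expected: ExpectedErrors, alpha: float = 0.05
) -> tuple[Literal["error", "biological"], float]:
    """Exact one-sided binomial test of a child's abundance.

    Under the null (the child is a sequencing error) each of the
    n = parent + child reads is miscalled into the child independently with
    probability P_error, so the p-value is P(X >= observed) for
    X ~ B(n, P_error).  The null is rejected — the child called biological —
    when the p-value falls below ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = expected.n_correct + child_abundance
    p_value = float(stats.binom.sf(child_abundance - 1, n, expected.p_error))
    return ("biological" if p_value < alpha else "error"), p_value


def _diff_one(a: str, b: str) -> tuple[int, Substitution]:
    diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    assert len(diffs) == 1, "classification reference must be a distance-1 neighbour"
    i = diffs[0]
    return i + 1, Substitution(a[i], b[i])


def correct_graph(
    sg: Subgraph, g: VariantGraph, model: ErrorModel, alpha: float = 0.05
) -> list[CorrectionOutcome]:
    """Classify every member of one subgraph, breadth-first from the parent.

    The parent is biological by construction.  Each subsequent node is
    tested against its most abundant already-classified neighbour (abundance
    ties break lexicographically) using the original observed abundances,
    and error calls record that neighbour as their merge destination.  Total
    abundance is conserved: merging reassigns counts, it never drops them.
    """
    nodes = g.nodes
    classified: dict[int, CorrectionOutcome] = {}
    root = sg.parent_index
    classified[root] = CorrectionOutcome(
        nodes[root].seq, nodes[root].abundance, "biological", None, None
    )
    queue = deque([root])
    while queue:
        u = queue.popleft()
        pending = [v for v in g.neighbors(u) if v not in classified]
        pending.sort(key=lambda v: (-nodes[v].abundance, nodes[v].seq))
        for v in pending:
            if v in classified:
                continue
            ref = min(
                (w for w in g.neighbors(v) if w in classified),
                key=lambda w: (-nodes[w].abundance, nodes[w].seq),
            )
            pos, sub = _diff_one(nodes[ref].seq, nodes[v].seq)
            exp = expected_errors(model, nodes[ref].abundance, pos, sub)
            call, p_value = classify_child(nodes[v].abundance, exp, alpha)
            classified[v] = CorrectionOutcome(
                nodes[v].seq,
                nodes[v].abundance,
                call,
                nodes[ref].seq if call == "error" else None,
                p_value,
            )
            queue.append(v)
    out = [classified[i] for i in sorted(classified)]
    assert len(out) == sg.n_nodes
    return out


def _merge_outcomes(
    outcomes: Sequence[CorrectionOutcome], merge: bool
) -> list[UniqueSequence]:
    """Resolve merge chains into the corrected unique-sequence table."""
    by_seq = {o.seq: o for o in outcomes}
    final: dict[str, int] = {}
    for o in outcomes:
        if o.classification == "biological":
            final[o.seq] = final.get(o.seq, 0) + o.abundance_before
        elif merge:
            dest = o
            while dest.classification == "error":
                dest = by_seq[dest.merged_into]
            final[dest.seq] = final.get(dest.seq, 0) + o.abundance_before
    recs = [UniqueSequence(s, a) for s, a in final.items()]
    recs.sort(key=lambda r: (-r.abundance, r.seq))
    return recs


def correct_tables(
    tables: Mapping[int, Sequence[UniqueSequence]],
    model: ErrorModel,
    alpha: float = 0.05,
    merge: bool = True,
) -> tuple[dict[int, list[UniqueSequence]], list[CorrectionOutcome]]:
    """Correct every length table: build graphs, classify, merge (or drop) errors.

    With ``merge=True`` (default) each error's abundance is added to its
    surviving ancestor, so total abundance is conserved; with ``merge=False``
    error reads are discarded instead.  Returns the corrected tables plus
    the full correction log.
    """
    corrected: dict[int, list[UniqueSequence]] = {}
    log: list[CorrectionOutcome] = []
    for length in sorted(tables):
        g = build_graph(list(tables[length]))
        outcomes: list[CorrectionOutcome] = []
        for sg in connected_subgraphs(g):
            outcomes.extend(correct_graph(sg, g, model, alpha))
        before = sum(r.abundance for r in tables[length])
        merged = _merge_outcomes(outcomes, merge)
        if merge:
            after = sum(r.abundance for r in merged)
            assert after == before, "correction must conserve total abundance"
        corrected[length] = merged
        log.extend(outcomes)
    return corrected, log


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if seq else 0


def remove_homopolymers(
    table: Iterable[UniqueSequence], min_tract: int = 15
) -> list[UniqueSequence]:
    """Drop sequences containing a homopolymer tract of ``min_tract``+ bases.

    Applied only *after* model building and correction, so that homopolymer
    parents are still present to absorb their erroneous children.  The
    tract-length floor guards against degenerate settings that would strip
    every read.
    """
    if min_tract < 5:
        raise ValueError("min_tract < 5 would remove near-arbitrary sequences")
    return [rec for rec in table if max_homopolymer_run(rec.seq) < min_tract]


def write_correction_log(
    outcomes: Sequence[CorrectionOutcome], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("seq\tabundance\tclassification\tmerged_into\tp_value\n")
        for o in outcomes:
            merged = o.merged_into or ""
            pv = "" if o.p_value is None else f"{o.p_value:.6g}"
            fh.write(
                f"{o.seq}\t{o.abundance_before}\t{o.classification}\t{merged}\t{pv}\n"
            )


def write_corrected_fasta(
    table: Sequence[UniqueSequence], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(table, 1):
            fh.write(f">seq_{i}_x{rec.abundance}\n{rec.seq}\n")
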