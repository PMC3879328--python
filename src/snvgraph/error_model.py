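"""Position- and substitution-specific error-rate estimation.

The model assigns each of the 12 directed base substitutions r1 -> r2 its own
error-rate profile along the read, without forcing the position effect and
the substitution effect to multiply.  This flexibility matters on Illumina
data: crosstalk inflates G<->T and A<->C miscalls everywhere, while
T-fluorophore accumulation inflates late-cycle T miscalls specifically, an
interaction a separable model P(pos)·P(R) cannot represent.

Estimation proceeds from large, parent-dominated connected subgraphs of the
variant graph:

1.  Select subgraphs with at least ``min_subgraph_nodes`` nodes and parental
    abundance ratio a_parent / a_total >= t/100, for a descending series of
    thresholds t (default 90, 85, 80, 75, 70, 30).
2.  From each selected subgraph, every direct child of the parent yields a
    per-graph estimate P̂_k = a_child / (a_child + a_parent) at the child's
    (position, substitution); (position, substitution) cells with no child
    contribute explicit zero estimates, so absence of errors informs the
    average.
3.  Pool per-graph estimates into a weighted average per cell, weighting by
    the parental abundance a_parent of the contributing graph.
4.  Prune estimates above the upper limit of a 95% binomial interval
    B(n = a_parent, p = pooled rate) — these are most likely true biological
    variants — and recompute the average once from the survivors.
5.  Smooth residual spikes: a value greater than twice the average of its two
    nearest neighbouring positions is replaced by that average.  Position 1
    is left untouched: its rate is genuinely elevated (longer handling time
    at the start of a run) and is reported raw rather than fitted.
6.  Fill cells missing at a high threshold from the next threshold down.
7.  Fit an exponential A·e^(b·pos) per substitution over positions 2-24 by
    least squares in log space — the exponential shape is the expected
    signature of phasing error accumulation along the read.

The resulting :class:`ErrorModel` evaluates to the raw rate at position 1 and
to the fitted exponential elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .variant_graph import Subgraph, VariantGraph

__all__ = [
    "Substitution",
    "SUBSTITUTIONS",
    "RateObservation",
    "RateSurface",
    "ExpFit",
    "ErrorModel",
    "ModelConfig",
    "select_subgraphs",
    "observe_rates",
    "weighted_average",
    "ci_prune",
    "smooth",
    "fill_gaps",
    "fit_exponentials",
    "estimate_model",
    "expected_variant_count",
]

_BASES = "ACGT"


class Substitution(NamedTuple):
    """A directed base miscall r1 -> r2 (r1 was sequenced, r2 was called)."""

    r1: str
    r2: str

    def __str__(self) -> str:
        return f"{self.r1}>{self.r2}"

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        r1, r2 = text.split(">")
        if r1 not in _BASES or r2 not in _BASES or r1 == r2:
            raise ValueError(f"invalid substitution {text!r}")
        return cls(r1, r2)


#: the 12 possible substitutions, in fixed (r1, r2) lexicographic order
SUBSTITUTIONS: tuple[Substitution, ...] = tuple(
    Substitution(a, b) for a in _BASES for b in _BASES if a != b
)


class RateObservation(NamedTuple):
    """One per-subgraph rate estimate P̂_k(pos, R) with its weight a_parent."""

    pos: int
    sub: Substitution
    estimate: float
    weight: int
    graph_id: int


@dataclass
class RateSurface:
    """Pooled per-cell rates; ``provenance`` records each cell's source threshold."""

    values: dict[tuple[int, Substitution], float]
    provenance: dict[tuple[int, Substitution], int] = field(default_factory=dict)

    def get(self, pos: int, sub: Substitution) -> float | None:
        return self.values.get((pos, sub))


@dataclass(frozen=True)
class ExpFit:
    """Exponential profile A·e^(b·pos) for one substitution over [fit_lo, fit_hi]."""

    sub: Substitution
    A: float
    b: float
    fit_lo: int = 2
    fit_hi: int = 24

    def __call__(self, pos: int | np.ndarray) -> float | np.ndarray:
        return self.A * np.exp(self.b * np.asarray(pos, dtype=float))


class InsufficientDataError(ValueError):
    """Raised when a substitution has too few positive cells to fit a curve."""


@dataclass
class ErrorModel:
    """Raw position-1 rates plus fitted exponential profiles per substitution."""

    position1: dict[Substitution, float]
    fits: dict[Substitution, ExpFit]
    read_length_range: tuple[int, int] = (20, 24)

    def rate(self, pos: int, sub: Substitution) -> float:
        """Model error probability at a 1-based position for a substitution."""
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        if pos == 1:
            return self.position1.get(sub, 0.0)
        fit = self.fits.get(sub)
        if fit is None:
            return 0.0
        return min(1.0, float(fit(pos)))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "read_length_range": list(self.read_length_range),
            "substitutions": {
                str(sub): {
                    "position1": self.position1.get(sub, 0.0),
                    "A": self.fits[sub].A if sub in self.fits else 0.0,
                    "b": self.fits[sub].b if sub in self.fits else 0.0,
                    "fit_lo": self.fits[sub].fit_lo if sub in self.fits else 2,
                    "fit_hi": self.fits[sub].fit_hi if sub in self.fits else 24,
                }
                for sub in SUBSTITUTIONS
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ErrorModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        position1: dict[Substitution, float] = {}
        fits: dict[Substitution, ExpFit] = {}
        for name, vals in payload["substitutions"].items():
            sub = Substitution.parse(name)
            position1[sub] = float(vals["position1"])
            fits[sub] = ExpFit(
                sub,
                float(vals["A"]),
                float(vals["b"]),
                int(vals.get("fit_lo", 2)),
                int(vals.get("fit_hi", 24)),
            )
        return cls(position1, fits, tuple(payload.get("read_length_range", (20, 24))))


@dataclass
class ModelConfig:
    """Estimation parameters.

    min_subgraph_nodes : smallest subgraph used for estimation (default 40,
        the large-graph regime where abundance statistics are reliable).
    thresholds : parental-abundance-ratio percentages, consumed in
        descending order; lower thresholds only fill cells the higher ones
        left empty.
    ci_level : two-sided binomial interval level for pruning (0.95 -> upper
        limit at the 97.5th percentile).
    smoothing_factor : a value is replaced when it exceeds this multiple of
        its neighbour average.
    """

    min_subgraph_nodes: int = 40
    thresholds: tuple[int, ...] = (90, 85, 80, 75, 70, 30)
    ci_level: float = 0.95
    smoothing_factor: float = 2.0
    fit_lo: int = 2
    fit_hi: int = 24

    def __post_init__(self) -> None:
        if not all(0 < t <= 100 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 100]")
        self.thresholds = tuple(sorted(self.thresholds, reverse=True))
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def select_subgraphs(
    subgraphs: Iterable[Subgraph], cfg: ModelConfig, t: int
) -> list[Subgraph]:
    """Keep subgraphs with enough nodes and parental abundance ratio >= t/100."""
    return [
        sg
        for sg in subgraphs
        if sg.n_nodes >= cfg.min_subgraph_nodes and sg.parent_ratio >= t / 100.0
    ]


def observe_rates(
    sg: Subgraph, g: VariantGraph, graph_id: int = 0
) -> list[RateObservation]:
    """Per-subgraph rate estimates from the parent's direct children.

    Each distance-1 child of the parent contributes
    P̂ = a_child / (a_child + a_parent) at the (position, substitution) where
    it differs from the parent.  Every other (position, substitution)
    reachable from the parent sequence — the 3 alternative bases at each
    position — contributes an explicit zero estimate with the same weight,
    so subgraphs without errors at a cell pull the pooled average down.
    """
    parent = g.nodes[sg.parent_index]
    pseq = parent.seq
    a_parent = parent.abundance
    observed: dict[tuple[int, Substitution], float] = {}
    for ci in g.neighbors(sg.parent_index):
        child = g.nodes[ci]
        diff = [i for i, (a, b) in enumerate(zip(pseq, child.seq)) if a != b]
        assert len(diff) == 1, "graph edge must join distance-1 sequences"
        i = diff[0]
        key = (i + 1, Substitution(pseq[i], child.seq[i]))
        assert key not in observed, "unique sequences: one child per cell"
        observed[key] = child.abundance / (child.abundance + a_parent)
    out: list[RateObservation] = []
    for i, r1 in enumerate(pseq):
        for r2 in _BASES:
            if r2 == r1:
                continue
            key = (i + 1, Substitution(r1, r2))
            est = observed.get(key, 0.0)
            out.append(RateObservation(key[0], key[1], est, a_parent, graph_id))
    return out


def weighted_average(obs: Sequence[RateObservation]) -> RateSurface:
    """Pool per-graph estimates per cell, weighting by parental abundance."""
    sums: dict[tuple[int, Substitution], float] = {}
    weights: dict[tuple[int, Substitution], float] = {}
    for o in obs:
        key = (o.pos, o.sub)
        sums[key] = sums.get(key, 0.0) + o.weight * o.estimate
        weights[key] = weights.get(key, 0.0) + o.weight
    return RateSurface({k: sums[k] / weights[k] for k in sums})


def ci_prune(
    obs: Sequence[RateObservation], surface: RateSurface, cfg: ModelConfig
) -> tuple[list[RateObservation], RateSurface]:
    """Drop per-graph estimates above the binomial interval; re-average once.

    For each cell, the pooled rate p and a graph's parental abundance n
    define B(n, p); an estimate above ppf(1 - (1-ci_level)/2) / n is treated
    as a likely biological variant and removed.  The weighted average is then
    recomputed once from the surviving estimates.
    """
    upper_q = 1.0 - (1.0 - cfg.ci_level) / 2.0
    kept: list[RateObservation] = []
    for o in obs:
        p = surface.values[(o.pos, o.sub)]
        bound = stats.binom.ppf(upper_q, o.weight, p) / o.weight
        if o.estimate <= bound:
            kept.append(o)
    return kept, weighted_average(kept)


def smooth(surface: RateSurface, cfg: ModelConfig | None = None) -> RateSurface:
    """Replace spikes by their two-nearest-neighbour average.

    Scanning positions left to right per substitution (already-smoothed left
    neighbours feed subsequent comparisons), a value greater than
    ``smoothing_factor`` times the average of its two nearest neighbouring
    positions is replaced by that average; at the ends the single available
    neighbour stands in for both.  Position 1 is excluded both as a target
    and as a neighbour: its elevated rate is a real feature of the platform,
    not an outlier, and smoothing against it would mask genuine spikes at
    position 2.  Such spikes arise from cells dominated by biological
    variants, which produce no excess of *estimates* for the interval prune
    to remove.
    """
    cfg = cfg or ModelConfig()
    values = dict(surface.values)
    for sub in SUBSTITUTIONS:
        positions = sorted(p for (p, s) in values if s == sub and p >= 2)
        if len(positions) < 2:
            continue
        for idx, pos in enumerate(positions):
            nbrs = []
            if idx > 0:
                nbrs.append(values[(positions[idx - 1], sub)])
            if idx < len(positions) - 1:
                nbrs.append(values[(positions[idx + 1], sub)])
            avg = sum(nbrs) / len(nbrs)
            if values[(pos, sub)] > cfg.smoothing_factor * avg:
                values[(pos, sub)] = avg
    return RateSurface(values, dict(surface.provenance))


def fill_gaps(
    surfaces_by_threshold: Mapping[int, RateSurface], cfg: ModelConfig | None = None
) -> RateSurface:
    """Merge per-threshold surfaces, highest threshold winning per cell."""
    cfg = cfg or ModelConfig()
    values: dict[tuple[int, Substitution], float] = {}
    provenance: dict[tuple[int, Substitution], int] = {}
    for t in sorted(surfaces_by_threshold, reverse=True):
        for key, val in surfaces_by_threshold[t].values.items():
            if key not in values:
                values[key] = val
                provenance[key] = t
    return RateSurface(values, provenance)


def fit_exponentials(
    surface: RateSurface, cfg: ModelConfig | None = None
) -> ErrorModel:
    """Fit A·e^(b·pos) per substitution over the fit range; keep position 1 raw.

    The fit is linear least squares on log(rate) versus position, using the
    strictly positive cells in [fit_lo, fit_hi] (zero rates carry no
    information about the exponential's scale and would make the log
    undefined).  A substitution with no positive cell is modelled as flat
    zero; a single positive cell cannot pin down both A and b and raises
    :class:`InsufficientDataError`.
    """
    cfg = cfg or ModelConfig()
    position1: dict[Substitution, float] = {}
    fits: dict[Substitution, ExpFit] = {}
    for sub in SUBSTITUTIONS:
        position1[sub] = surface.values.get((1, sub), 0.0)
        cells = {
            p: v
            for (p, s), v in surface.values.items()
            if s == sub and cfg.fit_lo <= p <= cfg.fit_hi
        }
        positive = {p: v for p, v in cells.items() if v > 0}
        if not positive:
            fits[sub] = ExpFit(sub, 0.0, 0.0, cfg.fit_lo, cfg.fit_hi)
            continue
        if len(positive) < 2:
            raise InsufficientDataError(
                f"substitution {sub}: {len(positive)} positive cell(s) in "
                f"positions {cfg.fit_lo}-{cfg.fit_hi}; need >= 2 to fit"
            )
        xs = np.array(sorted(positive), dtype=float)
        ys = np.log([positive[int(p)] for p in xs])
        b, log_a = np.polyfit(xs, ys, 1)
        fits[sub] = ExpFit(sub, float(np.exp(log_a)), float(b), cfg.fit_lo, cfg.fit_hi)
    return ErrorModel(position1, fits)


def estimate_model(
    graphs: Sequence[tuple[VariantGraph, Sequence[Subgraph]]],
    cfg: ModelConfig | None = None,
) -> tuple[ErrorModel, RateSurface]:
    """Full estimation pipeline over per-length graphs.

    For each threshold t (descending): select subgraphs across all lengths,
    collect observations, pool, prune, smooth.  The per-threshold surfaces
    are then merged (gap filling) and the exponentials fitted.  Returns the
    fitted model together with the merged pre-fit surface.
    """
    cfg = cfg or ModelConfig()
    surfaces: dict[int, RateSurface] = {}
    for t in cfg.thresholds:
        obs: list[RateObservation] = []
        gid = 0
        for g, subgraphs in graphs:
            for sg in select_subgraphs(subgraphs, cfg, t):
                obs.extend(observe_rates(sg, g, graph_id=gid))
                gid += 1
        if not obs:
            continue
        pooled = weighted_average(obs)
        _, pooled = ci_prune(obs, pooled, cfg)
        surfaces[t] = smooth(pooled, cfg)
    merged = fill_gaps(surfaces, cfg)
    return fit_exponentials(merged, cfg), merged


def expected_variant_count(X: int, L: int, p: float) -> float:
    """Expected number of distinct single-nucleotide variants of a sequence.

    A sequence of length L seen X times has 3L possible distance-1
    neighbours; under a uniform per-read error probability p each neighbour
    is observed at least once with probability 1 - (1-p)^X, giving
    Y = 3L·[1 - (1-p)^X].  Diagnostic only: the full model replaces the
    constant p with the per-position, per-substitution surface.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if X < 0 or L < 1:
        raise ValueError("require X >= 0 and L >= 1")
    return 3 * L * (1.0 - (1.0 - p) ** X)


def write_surface(surface: RateSurface, path: str | Path) -> None:
    """Dump the pre-fit surface as TSV: pos, substitution, rate, source threshold."""
    with open(path, "w") as fh:
        fh.write("pos\tsub\trate\tsource_threshold\n")
        for (pos, sub), val in sorted(
            surface.values.items(), key=lambda kv: (kv[0][1], kv[0][0])
        ):
            t = surface.provenance.get((pos, sub), "")
            fh.write(f"{pos}\t{sub}\t{val:.6g}\t{t}\n")
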