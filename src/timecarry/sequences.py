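"""Path-guided, first-order counterbalanced trial sequences.

A session's trial order is an Eulerian circuit on the complete directed
multigraph over the stimulus labels (seven durations plus a null label),
with every arc -- including self-loops -- duplicated ``multiplicity``
times.  Every ordered pair of labels therefore occurs exactly
``multiplicity`` times cyclically, which is what makes the prior-trial
conditions of the carryover analysis balanced by construction.  Arc
choice is guided by a low-frequency sinusoidal "guide" signal so that
the emitted order is perceptually smooth rather than white.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NULL_LABEL = "null"

__all__ = [
    "NULL_LABEL",
    "DurationSet",
    "TrialSequence",
    "make_duration_set",
    "make_guide",
    "generate_sequence",
    "transition_counts",
]


@dataclass(frozen=True)
class DurationSet:
    """A geometric grid of stimulus durations plus a null (blank) label."""

    t_min: float
    t_max: float
    n_levels: int
    durations: tuple[float, ...]
    null_label: str = NULL_LABEL

    @property
    def duration_labels(self) -> tuple[str, ...]:
        """Labels ``d1..dN`` for the stimulus durations, shortest first."""
        return tuple(f"d{i + 1}" for i in range(self.n_levels))

    @property
    def labels(self) -> tuple[str, ...]:
        """All labels in canonical order: null first, then durations."""
        return (self.null_label,) + self.duration_labels

    def duration_of(self, label: str) -> float | None:
        """Duration in ms for a label; ``None`` for the null label."""
        if label == self.null_label:
            return None
        return self.durations[self.duration_labels.index(label)]

    def rank_of(self, label: str) -> int:
        """Integer rank used for guide matching (null = 0, d1..dN = 1..N)."""
        if label == self.null_label:
            return 0
        return self.duration_labels.index(label) + 1

    @property
    def rounded_durations(self) -> tuple[int, ...]:
        """Durations rounded to the nearest ms, for presentation/export."""
        return tuple(int(round(d)) for d in self.durations)

    @property
    def geometric_mean(self) -> float:
        return float(np.sqrt(self.t_min * self.t_max))


@dataclass(frozen=True)
class TrialSequence:
    """An ordered label sequence with its counterbalance metadata."""

    labels: tuple[str, ...]
    multiplicity: int
    guide: np.ndarray = field(repr=False)
    seed: int
    duration_set: DurationSet

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def label_order(self) -> tuple[str, ...]:
        return self.duration_set.labels

    def durations_ms(self) -> list[float | None]:
        """Per-trial duration in ms (``None`` on null trials)."""
        return [self.duration_set.duration_of(lab) for lab in self.labels]


def make_duration_set(t_min: float, t_max: float, n_levels: int) -> DurationSet:
    """Build ``n_levels`` log-spaced durations between ``t_min`` and ``t_max`` ms.

    Consecutive durations share a constant ratio ``(t_max/t_min)**(1/(n-1))``;
    full precision is retained internally, rounding happens only at export.
    """
    if t_min <= 0:
        raise ValueError(f"t_min must be positive, got {t_min}")
    if t_max <= t_min:
        raise ValueError(f"t_max must exceed t_min, got {t_min=}, {t_max=}")
    if n_levels < 2:
        raise ValueError(f"n_levels must be at least 2, got {n_levels}")
    durations = tuple(float(d) for d in np.geomspace(t_min, t_max, n_levels))
    return DurationSet(float(t_min), float(t_max), int(n_levels), durations)


def make_guide(
    length: int,
    n_sinusoids: int = 2,
    period_range: tuple[float, float] = (20.0, 40.0),
    seed: int | None = None,
) -> np.ndarray:
    """Sum of ``n_sinusoids`` sinusoids with random periods and phases.

    Periods are drawn uniformly from ``period_range`` (in sequence
    elements) and phases uniformly from [0, 2pi).  Deterministic for a
    fixed seed.
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    lo, hi = period_range
    if not (2 <= lo <= hi <= length):
        raise ValueError(f"period_range must satisfy 2 <= lo <= hi <= length, got {period_range}")
    if n_sinusoids < 1:
        raise ValueError(f"n_sinusoids must be at least 1, got {n_sinusoids}")
    rng = np.random.default_rng(seed)
    t = np.arange(length, dtype=float)
    guide = np.zeros(length)
    for _ in range(n_sinusoids):
        period = rng.uniform(lo, hi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        guide += np.sin(2.0 * np.pi * t / period + phase)
    return guide


def _scaled_guide(guide: np.ndarray, n_ranks: int) -> np.ndarray:
    """Min-max rescale the guide onto the label-rank range [0, n_ranks-1]."""
    g = np.asarray(guide, dtype=float)
    lo, hi = g.min(), g.max()
    if hi == lo:
        return np.zeros_like(g)
    return (g - lo) / (hi - lo) * (n_ranks - 1)


def _guided_walk(
    start: int,
    remaining: np.ndarray,
    node_rank: np.ndarray,
    target: np.ndarray,
    pos: int,
    rng: np.random.Generator,
) -> list[int]:
    """Greedy walk from ``start`` until no outgoing arc remains.

    Because in-degree equals out-degree at every node, the walk can only
    get stuck back at ``start``, so it always returns a closed circuit.
    """
    path = [start]
    node = start
    n = len(target)
    while remaining[node].sum() > 0:
        candidates = np.flatnonzero(remaining[node])
        want = target[min(pos, n - 1)]
        dist = np.abs(node_rank[candidates] - want)
        best = candidates[dist == dist.min()]
        nxt = int(rng.choice(best))
        remaining[node, nxt] -= 1
        path.append(nxt)
        node = nxt
        pos += 1
    return path


def _best_rotation(nodes: np.ndarray, target: np.ndarray) -> int:
    """Cyclic shift of ``nodes`` maximizing correlation with ``target``.

    Computed for all shifts at once via the FFT cross-correlation of the
    centered series.
    """
    x = nodes - nodes.mean()
    y = target - target.mean()
    if np.allclose(x, 0) or np.allclose(y, 0):
        return 0
    cross = np.fft.irfft(np.fft.rfft(x) * np.conj(np.fft.rfft(y)), n=len(x))
    # cross[r] = sum_i y[i] * x[(i + r) mod n]  -> corr of roll(x, -r) with y
    return int(np.argmax(cross))


def generate_sequence(
    duration_set: DurationSet,
    multiplicity: int,
    guide: np.ndarray,
    seed: int | None = None,
) -> TrialSequence:
    """Emit a first-order counterbalanced sequence approximating the guide.

    Constructs an Eulerian circuit on the complete directed multigraph
    over the label set (each ordered pair, self-pairs included, appearing
    ``multiplicity`` times) by a greedy guide-matching walk with
    Hierholzer splicing when the walk closes early.  The counterbalance
    invariants hold exactly; the guide is matched only approximately.
    """
    if multiplicity < 1:
        raise ValueError(f"multiplicity must be at least 1, got {multiplicity}")
    labels = duration_set.labels
    k = len(labels)
    n_arcs = k * k * multiplicity
    guide = np.asarray(guide, dtype=float)
    if len(guide) < n_arcs:
        raise ValueError(f"guide length {len(guide)} is shorter than the sequence length {n_arcs}")
    rng = np.random.default_rng(seed)
    target = _scaled_guide(guide[:n_arcs], k)

    # Guide rank of each node: durations keep their order rank; the null
    # label sits mid-range so null clusters fall in neutral guide regions
    # (an extreme null rank biases the stimulus context around nulls,
    # distorting the prior-null analysis condition downstream).
    node_rank = np.array([(k - 1) / 2.0] + list(range(1, k)))

    remaining = np.full((k, k), multiplicity, dtype=int)
    start = int(np.argmin(np.abs(node_rank - target[0])))
    path = _guided_walk(start, remaining, node_rank, target, 0, rng)

    # Hierholzer repair: splice closed sub-walks at nodes with unused arcs.
    while remaining.sum() > 0:
        for i, node in enumerate(path):
            if remaining[node].sum() > 0:
                sub = _guided_walk(node, remaining, node_rank, target, i, rng)
                path = path[: i + 1] + sub[1:] + path[i + 1 :]
                break
        else:  # pragma: no cover - unreachable on a connected Eulerian graph
            raise RuntimeError("failed to complete the Eulerian circuit")

    if len(path) != n_arcs + 1 or path[0] != path[-1]:  # pragma: no cover
        raise RuntimeError("constructed walk is not a closed Eulerian circuit")

    # Linearize at the cyclic rotation best matching the guide; rotation
    # leaves the cyclic pair counts untouched.
    nodes = np.asarray(path[:-1], dtype=int)
    shift = _best_rotation(node_rank[nodes], target)
    rotated = np.roll(nodes, -shift)

    seq_labels = tuple(labels[node] for node in rotated)
    return TrialSequence(
        labels=seq_labels,
        multiplicity=int(multiplicity),
        guide=guide[:n_arcs],
        seed=-1 if seed is None else int(seed),
        duration_set=duration_set,
    )


def transition_counts(seq: TrialSequence) -> np.ndarray:
    """Cyclic ordered-pair counts, indexed by ``seq.label_order``.

    The wrap-around (last -> first) transition is included, so the matrix
    sums to the sequence length.
    """
    if len(seq) == 0:
        raise ValueError("sequence is empty")
    order = seq.label_order
    index = {lab: i for i, lab in enumerate(order)}
    k = len(order)
    counts = np.zeros((k, k), dtype=int)
    lab = seq.labels
    for i in range(len(lab)):
        counts[index[lab[i]], index[lab[(i + 1) % len(lab)]]] += 1
    return counts
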