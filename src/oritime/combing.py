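"""DNA-combing measurements: fork velocity, inter-origin distance, figures.

Fibers carry ordered IdU/CldU tracks from a dual-pulse labelling (IdU for
pulse 1, CldU for pulse 2).  An initiation event is read from the label
geometry: an IdU-containing region flanked on both sides by contiguous CldU
tracks (the origin fired before or during pulse 1), or a pair of divergent
CldU-only tracks separated by a short gap (fired around the pulse
boundary, the IdU core below detection).  Fork velocity is measured on CldU
tracks of ongoing forks only -- adjacent to IdU on exactly one side and not
truncated by a fiber end -- as track length / pulse-2 duration.

Replication figures are scored into five classes:

1. ``isolated_fork`` -- a lone labelled track group with no origin signature;
2. ``one_origin_bidirectional`` -- both forks of a single initiation visible;
3. ``single_origin_only`` -- one initiation whose partner forks are cut off
   by the fiber ends;
4. ``interspersed_origins`` -- two or more initiation events on one fiber;
5. ``termination`` -- converging forks that met (a gap-free CldU junction
   flanked by IdU on both sides) with no initiation on the fiber.

Each fiber contributes at most one origin-level structure (classes 2-4,
taking precedence in the order interspersed > one-origin), while eventless
fibers contribute one structure per connected track group (classes 1 and 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synth import Fiber, FiberSet

__all__ = [
    "ForkMeasurement",
    "IodMeasurement",
    "FigureClassCounts",
    "BoxSummary",
    "FIGURE_CLASSES",
    "find_initiation_events",
    "fork_velocity",
    "inter_origin_distances",
    "count_long_iods",
    "classify_figures",
    "box_summary",
    "mann_whitney",
    "chi_square_counts",
]

FIGURE_CLASSES = (
    "isolated_fork",
    "one_origin_bidirectional",
    "single_origin_only",
    "interspersed_origins",
    "termination",
)

_ADJ_TOL = 1e-6     # kb; generator emits exactly touching segments


@dataclass(frozen=True)
class ForkMeasurement:
    fiber_id: str
    velocity: float         # kb/min
    track_length: float     # kb
    label_used: str = "CldU"


@dataclass(frozen=True)
class IodMeasurement:
    fiber_id: str
    distance: float         # kb


@dataclass(frozen=True)
class BoxSummary:
    """Median with 10-90 percentile whiskers, outliers outside the whiskers."""

    median: float
    p10: float
    p90: float
    outliers: tuple

    def to_dict(self) -> dict:
        return {"median": self.median, "p10": self.p10, "p90": self.p90,
                "n_outliers": len(self.outliers)}


@dataclass
class FigureClassCounts:
    counts: dict = field(default_factory=lambda: {c: 0 for c in FIGURE_CLASSES})

    def __post_init__(self) -> None:
        for c in FIGURE_CLASSES:
            self.counts.setdefault(c, 0)
        unknown = set(self.counts) - set(FIGURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown figure classes: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts must be non-negative")

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in FIGURE_CLASSES], dtype=np.int64)

    def proportion(self, cls: str) -> float:
        return self.counts[cls] / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# label-pattern parsing
# ---------------------------------------------------------------------------

def _tracks(fiber: Fiber):
    """Ordered labelled tracks, merging touching segments of the same label."""
    segs = [s for s in fiber.segments if s.label in ("IdU", "CldU")]
    merged: list[list] = []
    for s in segs:
        if merged and merged[-1][0] == s.label and s.start <= merged[-1][2] + _ADJ_TOL:
            merged[-1][2] = max(merged[-1][2], s.end)
        else:
            merged.append([s.label, s.start, s.end])
    return merged


def _adjacent(a_end: float, b_start: float) -> bool:
    return b_start - a_end <= _ADJ_TOL


def _event_records(fiber: Fiber, max_divergent_gap: float = 3.0,
                   max_core_gap: float = 10.0):
    """Initiation events with the flank geometry they involve.

    An IdU core may contain a short internal unlabelled gap (the origin
    fired just before pulse 1) up to ``max_core_gap`` kb; an older origin's
    two diverged forks are scored as separate structures instead, since on
    a micrograph nothing ties two distant forks to one initiation.
    """
    tracks = _tracks(fiber)
    n = len(tracks)
    events = []
    i = 0
    while i < n:
        if tracks[i][0] != "IdU":
            i += 1
            continue
        # IdU region: IdU tracks uninterrupted by CldU, short internal gaps
        j = i
        while (j + 1 < n and tracks[j + 1][0] == "IdU"
               and tracks[j + 1][1] - tracks[j][2] <= max_core_gap):
            j += 1
        left_ok = i > 0 and tracks[i - 1][0] == "CldU" and \
            _adjacent(tracks[i - 1][2], tracks[i][1])
        right_ok = j + 1 < n and tracks[j + 1][0] == "CldU" and \
            _adjacent(tracks[j][2], tracks[j + 1][1])
        if left_ok and right_ok:
            events.append({
                "position": 0.5 * (tracks[i][1] + tracks[j][2]),
                "kind": "idu_core",
                "left_outer": tracks[i - 1][1],
                "right_outer": tracks[j + 1][2],
            })
        i = j + 1
    # divergent CldU-only pairs: neither track touches any IdU, short gap
    def touches_idu(k):
        before = k > 0 and tracks[k - 1][0] == "IdU" and \
            _adjacent(tracks[k - 1][2], tracks[k][1])
        after = k + 1 < n and tracks[k + 1][0] == "IdU" and \
            _adjacent(tracks[k][2], tracks[k + 1][1])
        return before or after

    for k in range(n - 1):
        if tracks[k][0] == "CldU" and tracks[k + 1][0] == "CldU":
            gap = tracks[k + 1][1] - tracks[k][2]
            if _ADJ_TOL < gap <= max_divergent_gap and \
                    not touches_idu(k) and not touches_idu(k + 1):
                events.append({
                    "position": 0.5 * (tracks[k][2] + tracks[k + 1][1]),
                    "kind": "divergent_cldu",
                    "left_outer": tracks[k][1],
                    "right_outer": tracks[k + 1][2],
                })
    events.sort(key=lambda e: e["position"])
    return events, tracks


def find_initiation_events(fiber: Fiber, max_divergent_gap: float = 3.0,
                           max_core_gap: float = 10.0):
    """Ordered initiation-event positions (kb) on one fiber."""
    events, _ = _event_records(fiber, max_divergent_gap=max_divergent_gap,
                               max_core_gap=max_core_gap)
    return [e["position"] for e in events]


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def fork_velocity(fibers: FiberSet, pulse2_minutes: float | None = None):
    """Velocity of each ongoing fork, from its CldU track.

    A measurable fork is a CldU track adjacent to an IdU track on exactly one
    side (CldU-only tracks are excluded: they may come from forks born during
    pulse 2) whose outer end lies strictly inside the fiber (tracks running
    off a fiber end are truncated and excluded).
    """
    if pulse2_minutes is None:
        pulse2_minutes = fibers.pulse2_minutes
    if not pulse2_minutes > 0:
        raise ValueError("pulse2_minutes must be positive")
    out = []
    for fiber in fibers:
        tracks = _tracks(fiber)
        n = len(tracks)
        for k, (label, start, end) in enumerate(tracks):
            if label != "CldU":
                continue
            left_idu = k > 0 and tracks[k - 1][0] == "IdU" and \
                _adjacent(tracks[k - 1][2], start)
            right_idu = k + 1 < n and tracks[k + 1][0] == "IdU" and \
                _adjacent(end, tracks[k + 1][1])
            if left_idu == right_idu:       # none (newborn) or both (merged)
                continue
            outer = end if left_idu else start
            if outer <= _ADJ_TOL or outer >= fiber.length - _ADJ_TOL:
                continue                    # truncated at a fiber end
            length = end - start
            out.append(ForkMeasurement(
                fiber_id=fiber.fiber_id,
                velocity=length / pulse2_minutes,
                track_length=length,
            ))
    return out


def inter_origin_distances(fibers: FiberSet):
    """Distances between consecutive initiation events on the same fiber."""
    out = []
    for fiber in fibers:
        events = find_initiation_events(fiber)
        for a, b in zip(events, events[1:]):
            out.append(IodMeasurement(fiber_id=fiber.fiber_id, distance=b - a))
    return out


def count_long_iods(iods, threshold: float = 300.0) -> int:
    """Number of inter-origin distances exceeding ``threshold`` kb."""
    return sum(1 for m in iods if m.distance > threshold)


def classify_figures(fibers: FiberSet) -> FigureClassCounts:
    """Score replication structures into the five figure classes."""
    counts = FigureClassCounts()
    for fiber in fibers:
        events, tracks = _event_records(fiber)
        if not tracks:
            continue
        if len(events) >= 2:
            counts.counts["interspersed_origins"] += 1
            continue
        if len(events) == 1:
            e = events[0]
            complete = (
                e["left_outer"] > _ADJ_TOL
                and e["right_outer"] < fiber.length - _ADJ_TOL
            )
            cls = "one_origin_bidirectional" if complete else "single_origin_only"
            counts.counts[cls] += 1
            continue
        # no initiation: score each connected track group
        groups: list[list] = []
        for k, t in enumerate(tracks):
            if groups and _adjacent(tracks[k - 1][2], t[1]):
                groups[-1].append(t)
            else:
                groups.append([t])
        for g in groups:
            is_term = any(
                g[k][0] == "CldU"
                and k > 0 and g[k - 1][0] == "IdU"
                and k + 1 < len(g) and g[k + 1][0] == "IdU"
                for k in range(len(g))
            )
            counts.counts["termination" if is_term else "isolated_fork"] += 1
    return counts


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def box_summary(values) -> BoxSummary:
    """Median and 10-90 percentile whiskers (linear interpolation)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("box_summary requires a non-empty list")
    p10, med, p90 = np.percentile(arr, [10, 50, 90])
    outliers = tuple(arr[(arr < p10) | (arr > p90)])
    return BoxSummary(median=float(med), p10=float(p10), p90=float(p90),
                      outliers=outliers)


def mann_whitney(a, b):
    """Mann-Whitney U (for sample ``a``) with a two-sided p-value.

    Exact enumeration of the U null distribution when there are no ties and
    ``n_a * n_b <= 400``; otherwise the normal approximation with midrank tie
    correction and continuity correction.  Identical pooled samples give
    p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and a.size * b.size <= 400) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_counts(counts_a, counts_b):
    """Pearson chi-square over two class-count vectors with pooled expecteds.

    Accepts :class:`FigureClassCounts` or plain sequences over the same
    classes.  Classes with pooled expected count zero are dropped (df
    adjusted).  Returns ``(X2, df, p)``.
    """
    if isinstance(counts_a, FigureClassCounts):
        counts_a = counts_a.as_array()
    if isinstance(counts_b, FigureClassCounts):
        counts_b = counts_b.as_array()
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the same class set")
    pooled = a + b
    keep = pooled > 0
    if not np.all(keep):
        import warnings

        warnings.warn("dropping classes with pooled expected count 0",
                      stacklevel=2)
        a, b, pooled = a[keep], b[keep], pooled[keep]
    if len(pooled) < 2:
        raise ValueError("need at least two non-empty classes")
    na, nb, grand = a.sum(), b.sum(), pooled.sum()
    exp_a = na * pooled / grand
    exp_b = nb * pooled / grand
    x2 = float(((a - exp_a) ** 2 / exp_a).sum() + ((b - exp_b) ** 2 / exp_b).sum())
    df = int(len(pooled) - 1)
    p = float(stats.chi2.sf(x2, df))
    return x2, df, p
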