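"""Synthetic replication-origin data generator.

Everything downstream (timing-resolved coverage distributions, DNA-combing
statistics, qPCR quantification) is exercised against data produced here.
The generator encodes a minimal origin-firing model of S phase:

* a chromosome carries origins placed by a renewal process (exponential
  spacing by default, fixed spacing optionally);
* each origin belongs to an *early* or *late* timing class with a
  deterministic class firing time (early origins fire first);
* replication timing of any locus is the earliest arrival time over all
  origins, travelling at a constant fork speed;
* histone-mark ChIP coverage is Poisson counting noise around a flat
  background, multiplied by a fold enrichment inside a window around early
  origins only;
* single molecules replicate stochastically: each origin fires all-or-none
  with a per-condition probability, at its class time plus a per-cell
  uniform jitter, and an origin overrun by an incoming fork before its own
  firing time is passively replicated (it never fires).  Molecules are
  pulse-labelled (IdU then CldU), fragmented into fibers, and segments
  below the combing detection limit are lost.

All randomness flows through :class:`numpy.random.Generator` streams derived
from the mandatory config seed, so a fixed config reproduces outputs bit for
bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .timing import CoverageTrack, TimingProfile

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "Origin",
    "GenomeModel",
    "FiberSegment",
    "Fiber",
    "FiberSet",
    "chip_config",
    "combing_config",
    "make_genome",
    "make_timing_profile",
    "make_chip_track",
    "make_fibers",
    "make_qpcr",
    "make_facs",
    "reads_from_track",
]

LN2 = float(np.log(2.0))


class ConfigError(ValueError):
    """Invalid simulation configuration or genome model."""


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-operation stream derived from the run seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Lengths are in bp for genomic intervals and kb for fibers; times in
    minutes; ``fork_speed`` in kb/min.  ``seed`` is mandatory.
    """

    seed: int
    chrom_name: str = "chrS"
    chrom_length: int = 10_000_000          # bp
    interval_size: int = 1000               # bp, Repli-Seq resolution
    origin_spacing_mean: float = 100.0      # kb between adjacent origin sites
    fixed_spacing: bool = False             # fixed instead of exponential
    fork_speed: float = 1.5                 # kb/min
    fork_speed_cv: float = 0.0              # per-molecule relative spread
    measurement_noise_kb: float = 0.7       # optical jitter on track boundaries
    late_firing_minutes: float = 90.0       # class firing time of late origins
    firing_spread_minutes: float = 15.0     # per-cell uniform firing jitter
    label_start_minutes: float = 0.0        # IdU pulse begins with the cohort
    label_start_jitter_minutes: float = 0.0     # async population: per-molecule
                                                # pulse start U(0, jitter) later
    pulse1_minutes: float = 15.0            # IdU
    pulse2_minutes: float = 30.0            # CldU
    n_fibers: int = 300
    fiber_length_mean: float = 650.0        # kb, exponential fragmentation
    detection_threshold: float = 1.0        # kb, shortest visible segment
    depth: int = 1_000_000                  # target reads per ChIP library
    background_rate: float = 100.0          # expected reads per interval
    enrichment_window: float = 2000.0       # bp around early origins
    mark_enrichment: dict = field(
        default_factory=lambda: {"H3K4me3": 4.0, "H3K4me2": 3.0, "H3K4me1": 2.0}
    )
    ct_sd: float = 0.15                     # cycles, qPCR noise
    ct_input_base: float = 20.0             # cycles, input Ct centre
    input_fraction: float = 1.0             # chromatin aliquot used as input

    def __post_init__(self) -> None:
        positive = {
            "chrom_length": self.chrom_length,
            "interval_size": self.interval_size,
            "origin_spacing_mean": self.origin_spacing_mean,
            "fork_speed": self.fork_speed,
            "pulse1_minutes": self.pulse1_minutes,
            "pulse2_minutes": self.pulse2_minutes,
            "n_fibers": self.n_fibers,
            "fiber_length_mean": self.fiber_length_mean,
            "detection_threshold": self.detection_threshold,
            "depth": self.depth,
            "background_rate": self.background_rate,
            "input_fraction": self.input_fraction,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigError(f"{name} must be positive, got {value!r}")
        if self.input_fraction > 1:
            raise ConfigError("input_fraction must be in (0, 1]")
        for name in ("fork_speed_cv", "firing_spread_minutes", "ct_sd",
                     "label_start_minutes", "late_firing_minutes",
                     "enrichment_window", "measurement_noise_kb",
                     "label_start_jitter_minutes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for mark, fold in self.mark_enrichment.items():
            if fold < 1:
                raise ConfigError(f"fold enrichment for {mark} must be >= 1")


def chip_config(seed: int, **overrides) -> SimulationConfig:
    """Study conditions for the ChIP / replication-timing scenario.

    Origins at licensed-origin density (one per ~25 kb, the scale of mapped
    human origins) so the +/-2 kb mark windows carry an appreciable share of
    the genome, as they do around real early origins.
    """
    params = dict(origin_spacing_mean=25.0)
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


def combing_config(seed: int, **overrides) -> SimulationConfig:
    """Study conditions for the DNA-combing scenario.

    Origins at efficient-origin density (one per ~120 kb), the spacing scale
    single-molecule fiber assays observe between actual initiation events.
    The firing cohort goes off within the IdU pulse, emulating labelling of
    cells released into early S after synchronization.
    """
    params = dict(origin_spacing_mean=120.0, n_fibers=400)
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


@dataclass(frozen=True)
class Origin:
    """One replication origin on the model chromosome."""

    position: int                       # bp
    timing_class: str                   # 'early' | 'late'
    firing_time: float                  # min from S-phase start
    mark_enrichment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timing_class not in ("early", "late"):
            raise ConfigError(f"unknown timing_class {self.timing_class!r}")
        if self.firing_time < 0:
            raise ConfigError("firing_time must be >= 0")


@dataclass(frozen=True)
class GenomeModel:
    """Simulated chromosome: origins, fork speed and firing conditions."""

    chrom_name: str
    chrom_length: int                   # bp
    origins: tuple                      # of Origin, positions increasing
    fork_speed: float                   # kb/min
    conditions: dict                    # condition name -> firing probability

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ConfigError("chrom_length must be positive")
        if self.fork_speed <= 0:
            raise ConfigError("fork_speed must be positive")
        pos = [o.position for o in self.origins]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ConfigError("origin positions must be strictly increasing")
        if pos and (pos[0] < 0 or pos[-1] >= self.chrom_length):
            raise ConfigError("origin positions must lie in [0, chrom_length)")
        for name, p in self.conditions.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"firing probability for {name!r} not in [0,1]")
        early = [o.firing_time for o in self.origins if o.timing_class == "early"]
        late = [o.firing_time for o in self.origins if o.timing_class == "late"]
        if early and late and max(early) >= min(late):
            raise ConfigError("every early origin must fire before every late origin")

    @property
    def positions(self) -> np.ndarray:
        return np.array([o.position for o in self.origins], dtype=np.int64)


@dataclass(frozen=True)
class FiberSegment:
    """One labelled stretch on a combed fiber (kb coordinates on the fiber)."""

    label: str                          # 'IdU' | 'CldU' | 'unlabeled'
    start: float                        # kb
    end: float                          # kb

    def __post_init__(self) -> None:
        if self.label not in ("IdU", "CldU", "unlabeled"):
            raise ConfigError(f"unknown segment label {self.label!r}")
        if not self.end > self.start:
            raise ConfigError("segment end must exceed start")

    @property
    def length(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class Fiber:
    """A single combed DNA molecule fragment."""

    fiber_id: str
    length: float                       # kb
    segments: tuple                     # of FiberSegment, ordered, disjoint

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigError("fiber length must be positive")
        prev_end = 0.0
        eps = 1e-9
        for seg in self.segments:
            if seg.start < -eps or seg.end > self.length + eps:
                raise ConfigError(
                    f"segment [{seg.start}, {seg.end}] outside fiber "
                    f"{self.fiber_id} of length {self.length}"
                )
            if seg.start < prev_end - eps:
                raise ConfigError(
                    f"overlapping/unordered segments on fiber {self.fiber_id}"
                )
            prev_end = seg.end


@dataclass(frozen=True)
class FiberSet:
    """A collection of fibers from one labelling experiment."""

    fibers: tuple                       # of Fiber
    condition: str = ""
    pulse1_minutes: float = 15.0
    pulse2_minutes: float = 30.0

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self):
        return iter(self.fibers)


# ---------------------------------------------------------------------------
# genome & timing profile
# ---------------------------------------------------------------------------

def make_genome(
    config: SimulationConfig,
    early_fraction: float = 0.5,
    conditions: dict | None = None,
) -> GenomeModel:
    """Place origins along the chromosome and assign timing classes.

    Spacing is exponential with mean ``config.origin_spacing_mean`` kb
    (a Poisson process), or fixed when ``config.fixed_spacing``.  Each origin
    is independently early with probability ``early_fraction``; early origins
    fire at time 0, late origins at ``config.late_firing_minutes``.
    """
    if not 0 <= early_fraction <= 1:
        raise ConfigError("early_fraction must be in [0, 1]")
    if conditions is None:
        conditions = {"control": 1.0, "knockdown": 0.5}
    rng = _rng(config.seed, "genome")
    spacing_bp = config.origin_spacing_mean * 1000.0
    positions: list[int] = []
    pos = 0.0
    while True:
        step = spacing_bp if config.fixed_spacing else rng.exponential(spacing_bp)
        pos += step
        if pos >= config.chrom_length:
            break
        positions.append(int(pos))
    # exponential steps can collide after int truncation; dedupe
    positions = sorted(set(positions))
    is_early = rng.random(len(positions)) < early_fraction
    origins = tuple(
        Origin(
            position=p,
            timing_class="early" if e else "late",
            firing_time=0.0 if e else config.late_firing_minutes,
            mark_enrichment=dict(config.mark_enrichment),
        )
        for p, e in zip(positions, is_early)
    )
    return GenomeModel(
        chrom_name=config.chrom_name,
        chrom_length=config.chrom_length,
        origins=origins,
        fork_speed=config.fork_speed,
        conditions=dict(conditions),
    )


def _interval_grid(config: SimulationConfig):
    starts = np.arange(0, config.chrom_length, config.interval_size, dtype=np.int64)
    ends = np.minimum(starts + config.interval_size, config.chrom_length)
    return starts, ends


def _interval_origin_distance_kb(starts, ends, origin_pos: int) -> np.ndarray:
    """Point-to-interval distance (kb); zero when the origin lies inside."""
    left = starts - origin_pos          # >0 when interval right of origin
    right = origin_pos - (ends - 1)     # >0 when interval left of origin
    d = np.maximum(np.maximum(left, right), 0)
    return d / 1000.0


def make_timing_profile(genome: GenomeModel, config: SimulationConfig) -> TimingProfile:
    """Population replication timing on the 0-100 ENCODE-style scale.

    The replication time of an interval is the earliest arrival over all
    origins (firing time + distance / fork speed).  Times are linearly
    rescaled to [0, 100] with the earliest time mapped to 100, i.e. higher
    values mean earlier replication.
    """
    if not genome.origins:
        raise ConfigError("cannot compute timing for a genome with no origins")
    starts, ends = _interval_grid(config)
    t = np.full(starts.shape, np.inf)
    for o in genome.origins:
        d = _interval_origin_distance_kb(starts, ends, o.position)
        np.minimum(t, o.firing_time + d / genome.fork_speed, out=t)
    tmin, tmax = float(t.min()), float(t.max())
    if tmax == tmin:
        values = np.full(t.shape, 100.0)
    else:
        values = np.clip(100.0 * (tmax - t) / (tmax - tmin), 0.0, 100.0)
    chroms = np.full(starts.shape, genome.chrom_name, dtype=object)
    return TimingProfile(chroms=chroms, starts=starts, ends=ends, values=values)


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------

def make_chip_track(
    genome: GenomeModel,
    mark: str,
    config: SimulationConfig,
    knockdown_scale: float = 1.0,
) -> CoverageTrack:
    """Poisson read counts per interval for one ChIP (or input) library.

    Expected count is ``background_rate`` everywhere, multiplied inside a
    +/- ``enrichment_window`` around each *early* origin by
    ``1 + (fold - 1) * knockdown_scale`` (overlapping windows take the
    maximum factor rather than stacking).  ``mark="input"`` ignores
    enrichment entirely.
    """
    if knockdown_scale < 0:
        raise ConfigError("knockdown_scale must be >= 0")
    known = set().union(*(o.mark_enrichment.keys() for o in genome.origins)) \
        if genome.origins else set()
    if mark != "input" and mark not in known:
        raise ConfigError(f"unknown mark {mark!r}; known marks: {sorted(known)}")
    starts, ends = _interval_grid(config)
    factor = np.ones(starts.shape)
    if mark != "input":
        win_kb = config.enrichment_window / 1000.0
        for o in genome.origins:
            if o.timing_class != "early":
                continue
            fold = o.mark_enrichment.get(mark, 1.0)
            f = 1.0 + (fold - 1.0) * knockdown_scale
            d = _interval_origin_distance_kb(starts, ends, o.position)
            np.maximum(factor, np.where(d <= win_kb, f, 1.0), out=factor)
    rng = _rng(config.seed, f"chip:{mark}:{knockdown_scale}")
    counts = rng.poisson(config.background_rate * factor).astype(np.int64)
    chroms = np.full(starts.shape, genome.chrom_name, dtype=object)
    return CoverageTrack(
        chroms=chroms, starts=starts, ends=ends,
        counts=counts, library_size=int(counts.sum()),
    )


def reads_from_track(track: CoverageTrack, seed: int) -> pd.DataFrame:
    """Expand per-interval counts into individual 5' read start positions."""
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    chroms = np.repeat(track.chroms, track.counts)
    lo = np.repeat(track.starts, track.counts)
    hi = np.repeat(track.ends, track.counts)
    pos = rng.integers(lo, hi) if len(lo) else np.array([], dtype=np.int64)
    return pd.DataFrame({"chrom": chroms, "pos": pos})


# ---------------------------------------------------------------------------
# single-molecule fiber simulation
# ---------------------------------------------------------------------------

def _simulate_molecule(genome, config, p_fire, rng):
    """Label pattern of one replicating molecule.

    Returns a list of (label, start_kb, end_kb) segments, merged and sorted,
    over the whole chromosome.
    """
    x = genome.positions / 1000.0                       # kb
    n = len(x)
    v = genome.fork_speed * max(0.2, 1.0 + config.fork_speed_cv * rng.standard_normal())
    fired = rng.random(n) < p_fire
    jitter = rng.uniform(0.0, config.firing_spread_minutes, size=n)
    tau = np.array([o.firing_time for o in genome.origins]) + jitter

    # passive replication: process candidates in firing order; a candidate
    # fires only if no already-fired origin's fork reaches it first
    idx = [i for i in np.argsort(tau, kind="stable") if fired[i]]
    active: list[int] = []
    for i in idx:
        covered = any(tau[j] + abs(x[i] - x[j]) / v < tau[i] for j in active)
        if not covered:
            active.append(i)
    active.sort()
    if not active:
        return [], v
    ax = x[active]
    at = tau[active]

    # influence boundaries between consecutive fired origins (equal speeds
    # keep regions in positional order); outermost forks run to the ends
    L = genome.chrom_length / 1000.0
    right_bound = np.empty(len(active))
    left_bound = np.empty(len(active))
    for k in range(len(active)):
        if k + 1 < len(active):
            b = 0.5 * (ax[k] + ax[k + 1]) + 0.5 * v * (at[k + 1] - at[k])
            right_bound[k] = min(max(b, ax[k]), ax[k + 1])
        else:
            right_bound[k] = L
        if k > 0:
            left_bound[k] = right_bound[k - 1]
        else:
            left_bound[k] = 0.0

    # asynchronous population: this molecule's pulse begins at a random
    # point of S phase
    T = config.label_start_minutes
    if config.label_start_jitter_minutes > 0:
        T += rng.uniform(0.0, config.label_start_jitter_minutes)
    p1, p2 = config.pulse1_minutes, config.pulse2_minutes
    segs: list[tuple[str, float, float]] = []
    for k in range(len(active)):
        t0 = at[k]
        for sign, bound in ((+1, right_bound[k]), (-1, left_bound[k])):
            # fork position at time t: ax[k] + sign * v * (t - t0)
            def span(ta, tb):
                a = ax[k] + sign * v * max(0.0, ta - t0)
                b = ax[k] + sign * v * max(0.0, tb - t0)
                lo, hi = (a, b) if sign > 0 else (b, a)
                lo = max(lo, min(ax[k], bound))
                hi = min(hi, max(ax[k], bound))
                return lo, hi
            for label, ta, tb in (("IdU", T, T + p1), ("CldU", T + p1, T + p1 + p2)):
                lo, hi = span(ta, tb)
                if hi > lo + 1e-12:
                    segs.append((label, lo, hi))
    segs.sort(key=lambda s: (s[1], s[2]))
    merged: list[list] = []
    for label, lo, hi in segs:
        if merged and merged[-1][0] == label and lo <= merged[-1][2] + 1e-9:
            merged[-1][2] = max(merged[-1][2], hi)
        else:
            merged.append([label, lo, hi])
    merged = _jitter_boundaries(merged, config.measurement_noise_kb, L, rng)
    return [tuple(m) for m in merged], v


def _jitter_boundaries(segs, sd, L, rng):
    """Optical measurement noise on track boundaries.

    Coordinates shared between touching segments move together, so label
    junctions stay junctions; segments squeezed to nothing are dropped.
    """
    if sd <= 0 or not segs:
        return segs
    coords = sorted({c for _, lo, hi in segs for c in (lo, hi)})
    moved = {c: min(max(c + rng.normal(0.0, sd), 0.0), L) for c in coords}
    out = []
    prev_end = 0.0
    for label, lo, hi in segs:
        a, b = moved[lo], moved[hi]
        a = max(a, prev_end)
        if b > a + 1e-9:
            out.append([label, a, b])
            prev_end = b
    return out


def make_fibers(
    genome: GenomeModel,
    condition: str,
    config: SimulationConfig,
) -> FiberSet:
    """Simulate a dual-pulse combing experiment for one firing condition.

    Molecules are replicated under the condition's firing probability,
    labelled with IdU (pulse 1) then CldU (pulse 2), fragmented into fibers
    of exponential length, and segments below the detection threshold are
    dropped.  Generation stops once ``config.n_fibers`` fibers are collected.
    """
    if condition not in genome.conditions:
        raise ConfigError(
            f"unknown condition {condition!r}; "
            f"genome defines {sorted(genome.conditions)}"
        )
    p_fire = genome.conditions[condition]
    rng = _rng(config.seed, f"fibers:{condition}")
    L = genome.chrom_length / 1000.0
    fibers: list[Fiber] = []
    molecule = 0
    while len(fibers) < config.n_fibers:
        segs, _v = _simulate_molecule(genome, config, p_fire, rng)
        molecule += 1
        # fragmentation: exponential cut spacing along the molecule
        cuts = [0.0]
        while cuts[-1] < L:
            cuts.append(cuts[-1] + rng.exponential(config.fiber_length_mean))
        cuts[-1] = L
        for k in range(len(cuts) - 1):
            lo, hi = cuts[k], cuts[k + 1]
            flen = hi - lo
            if flen < config.detection_threshold:
                continue
            fsegs = []
            for label, a, b in segs:
                a2, b2 = max(a, lo), min(b, hi)
                if b2 - a2 >= config.detection_threshold:
                    fsegs.append(FiberSegment(label, a2 - lo, b2 - lo))
            fibers.append(
                Fiber(
                    fiber_id=f"{condition}_m{molecule}_f{k}",
                    length=flen,
                    segments=tuple(fsegs),
                )
            )
            if len(fibers) >= config.n_fibers:
                break
    return FiberSet(
        fibers=tuple(fibers),
        condition=condition,
        pulse1_minutes=config.pulse1_minutes,
        pulse2_minutes=config.pulse2_minutes,
    )


# ---------------------------------------------------------------------------
# qPCR and cytometry
# ---------------------------------------------------------------------------

def make_qpcr(
    amplicons: list,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Emit a Ct table for (amplicon, true % input) pairs.

    Gaussian Ct noise (SD ``config.ct_sd`` cycles) is added to both IP and
    input wells; a lognormal mean-bias correction of ``ln2 * sd^2`` cycles is
    applied to the IP centre so the *expected* recovered % input equals the
    requested truth exactly.
    """
    rng = _rng(config.seed, "qpcr")
    sd = config.ct_sd
    rows = []
    for label, pct in amplicons:
        if not pct > 0:
            raise ConfigError(f"true enrichment for {label!r} must be positive")
        ct_input = config.ct_input_base + rng.normal(0.0, sd)
        ct_input_adj_center = config.ct_input_base - np.log2(1.0 / config.input_fraction)
        ct_ip = (
            ct_input_adj_center
            - np.log2(pct / 100.0)
            + LN2 * sd**2
            + rng.normal(0.0, sd)
        )
        rows.append((label, "IP", float(ct_ip), config.input_fraction))
        rows.append((label, "input", float(ct_input), config.input_fraction))
    return pd.DataFrame(rows, columns=["amplicon", "role", "ct", "input_fraction"])


def make_facs(
    n_cells: int,
    net_s_signal: float,
    background: float,
    config: SimulationConfig,
    sigma_log: float = 0.35,
) -> dict:
    """Lognormal BrdU intensities for S-phase and BrdU-negative populations.

    The S population has mean ``background + net_s_signal``; the negative
    (G1 + G2/M) population has mean ``background``.
    """
    if net_s_signal < 0 or background < 0:
        raise ConfigError("intensities must be >= 0")
    rng = _rng(config.seed, "facs")

    def draw(mean):
        if mean <= 0:
            return np.zeros(n_cells)
        mu = np.log(mean) - 0.5 * sigma_log**2
        return rng.lognormal(mu, sigma_log, size=n_cells)

    return {"s": draw(background + net_s_signal), "negative": draw(background)}
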