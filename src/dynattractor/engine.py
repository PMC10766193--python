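"""Time integration, stimulation scheduling, probing and recording.

A :class:`Paradigm` declares everything about an experiment except the model
constants: the stimulated patterns (named index sets), the rectangular pulse
trains driving them, the warm-up and post-stimulation phases, and a schedule
of probe (test-pulse) read-outs.  :func:`run` integrates the network through
warm-up, stimulation and post phases and returns a :class:`SimulationRecord`
with downsampled weight statistics, per-pulse input-field read-outs, probe
trajectories and the final state.

Time convention: t = 0 is the start of the stimulation phase; the warm-up
occupies t in [-warmup, 0).  Probes evolve a disposable copy of the state
with learning and noise switched off, so the main trajectory is bit-identical
to a probe-free run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import core
from .params import ModelParams, scale_params  # noqa: F401  (re-exported)

_TOL = 1e-9

PROBE_AMPLITUDE = 1.0
PROBE_DURATION = 1.0
PROBE_READ_WINDOW = 5.0
PROBE_READ_TIME = 2.0


@dataclass(frozen=True)
class PulseTrain:
    """Periodic rectangular current pulses delivered to one pattern.

    The k-th pulse (k = 0..count-1) is active for
    onset + k*period <= t < onset + k*period + duration.
    """

    pattern: str
    onset: float
    period: float
    duration: float = 5.0
    amplitude: float = 1.0
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.count > 1 and self.duration >= self.period:
            raise ValueError("duration must be shorter than the period")

    @property
    def end(self) -> float:
        """Offset time of the last pulse."""
        return self.onset + (self.count - 1) * self.period + self.duration

    def active(self, t: float) -> bool:
        tk = t - self.onset
        if tk < -_TOL:
            return False
        k = int(tk // self.period) if self.period > 0 else 0
        if k >= self.count:
            return False
        return (tk - k * self.period) < self.duration - _TOL

    def pulse_onsets(self) -> np.ndarray:
        return self.onset + self.period * np.arange(self.count)


@dataclass(frozen=True)
class Paradigm:
    """Declarative stimulation schedule for one simulation.

    ``patterns`` maps pattern names to 0-based neuron index arrays;
    ``probe_times`` lists (time, pattern-name) pairs at which the membership
    read-out protocol is applied.  Trains addressed to *different* patterns
    must never overlap in time (validated at construction); a pattern may be
    driven by several trains (phases), which must not overlap either.
    """

    patterns: dict[str, np.ndarray]
    trains: tuple[PulseTrain, ...]
    warmup: float = 50_000.0
    post: float = 10_000.0
    probe_times: tuple[tuple[float, str], ...] = ()
    read_window: float = PROBE_READ_WINDOW

    def __post_init__(self):
        pats = {k: np.asarray(v, dtype=int) for k, v in self.patterns.items()}
        object.__setattr__(self, "patterns", pats)
        object.__setattr__(self, "trains", tuple(self.trains))
        object.__setattr__(
            self, "probe_times",
            tuple(sorted((float(t), str(p)) for t, p in self.probe_times)),
        )
        if self.warmup < 0 or self.post < 0:
            raise ValueError("warmup and post must be non-negative")
        for name, idx in pats.items():
            if len(np.unique(idx)) != len(idx):
                raise ValueError(f"pattern {name!r} has duplicate indices")
            if len(idx) and idx.min() < 0:
                raise ValueError(f"pattern {name!r} has negative indices")
        for tr in self.trains:
            if tr.pattern not in pats:
                raise ValueError(f"train references unknown pattern {tr.pattern!r}")
        for t, p in self.probe_times:
            if p not in pats:
                raise ValueError(f"probe references unknown pattern {p!r}")
        self._check_no_overlap()

    def _check_no_overlap(self) -> None:
        starts, ends, labels = [], [], []
        for ti, tr in enumerate(self.trains):
            on = tr.pulse_onsets()
            starts.append(on)
            ends.append(on + tr.duration)
            labels.append(np.full(len(on), ti))
        if not starts:
            return
        starts = np.concatenate(starts)
        ends = np.concatenate(ends)
        labels = np.concatenate(labels)
        order = np.argsort(starts, kind="stable")
        s, e, l = starts[order], ends[order], labels[order]
        clash = s[1:] < e[:-1] - _TOL
        if np.any(clash):
            i = int(np.argmax(clash))
            raise ValueError(
                "overlapping pulses: train %d pulse at t=%.3f and train %d "
                "pulse at t=%.3f" % (l[i], s[i], l[i + 1], s[i + 1])
            )

    @property
    def stim_end(self) -> float:
        """End of the last pulse (0 for a warm-up-only paradigm)."""
        return max((tr.end for tr in self.trains), default=0.0)

    @property
    def t_end(self) -> float:
        return self.stim_end + self.post

    def max_index(self) -> int:
        return max((int(idx.max()) for idx in self.patterns.values()
                    if len(idx)), default=-1)

    def input_at(self, t: float, N: int) -> np.ndarray:
        """External input vector at time t."""
        I = np.zeros(N)
        for tr in self.trains:
            if tr.active(t):
                I[self.patterns[tr.pattern]] = tr.amplitude
        return I

    def replace(self, **changes) -> "Paradigm":
        return dataclasses.replace(self, **changes)


@dataclass
class ProbeResult:
    """Rate trajectories of all neurons under an isolated test pulse.

    The probed copy of the network receives amplitude-1 input on the
    pattern's originally stimulated neurons for 1 a.u., with learning and
    noise disabled; ``rates[k]`` holds the rate vector at ``times[k]`` a.u.
    after probe onset (row 0 is the pre-pulse state).
    """

    time: float
    pattern: str
    times: np.ndarray
    rates: np.ndarray


@dataclass(frozen=True)
class RecordingOptions:
    """What :func:`run` records, and at which cadence (in a.u.)."""

    weight_cadence: float = 500.0       # block-wise weight statistics
    dense_weight_cadence: float | None = None  # per-step within-pattern means
    record_fields: bool = True          # h and r at each pulse read-out step
    rate_trace: bool = True             # per-step mean/max network rate


@dataclass
class SimulationRecord:
    """Self-describing result of one simulation run."""

    params: ModelParams
    seed: int
    patterns: dict[str, np.ndarray]
    t_start: float
    t_end: float
    probes: list[ProbeResult] = field(default_factory=list)
    weight_times: np.ndarray | None = None
    weight_stats: dict[str, np.ndarray] = field(default_factory=dict)
    dense_weight_times: np.ndarray | None = None
    dense_within: dict[str, np.ndarray] = field(default_factory=dict)
    pulse_times: np.ndarray | None = None
    pulse_patterns: list[str] = field(default_factory=list)
    pulse_fields: np.ndarray | None = None
    pulse_rates: np.ndarray | None = None
    rate_times: np.ndarray | None = None
    rate_mean: np.ndarray | None = None
    rate_max: np.ndarray | None = None
    final_r: np.ndarray | None = None
    final_theta: np.ndarray | None = None
    final_W: np.ndarray | None = None
    events: list[tuple[float, str]] = field(default_factory=list)

    def probes_for(self, pattern: str) -> list[ProbeResult]:
        return [p for p in self.probes if p.pattern == pattern]


def probe(state: core.NetworkState, pattern: np.ndarray, params: ModelParams,
          read_window: float = PROBE_READ_WINDOW,
          duration: float = PROBE_DURATION,
          amplitude: float = PROBE_AMPLITUDE) -> ProbeResult:
    """Apply an isolated test pulse to a copy of the state.

    Learning and noise are switched off, so the caller's state and random
    stream are untouched and the main trajectory continues as if the test
    input had never been applied.
    """
    p = params
    pattern = np.asarray(pattern, dtype=int)
    r = state.r.copy()
    theta = state.theta.copy()
    W = state.W  # read-only here: no learning during a probe
    n_steps = int(round(read_window / p.dt))
    times = np.arange(n_steps + 1) * p.dt
    rates = np.empty((n_steps + 1, p.N))
    rates[0] = r
    I = np.zeros(p.N)
    for k in range(n_steps):
        t_loc = k * p.dt
        I[:] = 0.0
        if t_loc < duration - _TOL:
            I[pattern] = amplitude
        h = core.input_field(W, r, I, p)
        r_next = core.step_rates(r, h, theta, None, p)
        theta = core.step_thresholds(theta, r, p)
        r = r_next
        rates[k + 1] = r
    return ProbeResult(time=state.t, pattern="", times=times, rates=rates)


def run(paradigm: Paradigm, params: ModelParams, seed: int,
        recording: RecordingOptions | None = None,
        progress=None) -> SimulationRecord:
    """Integrate the network through warm-up, stimulation and post phases.

    Warm-up runs with learning and noise on but no external input, giving
    the weight matrix time to reach its stationary noise-driven statistics;
    the stimulation phase then starts at t = 0.  ``progress``, if given, is
    called as ``progress(t, message)`` at phase boundaries.
    """
    p = params
    rec_opt = recording or RecordingOptions()
    if paradigm.max_index() >= p.N:
        raise ValueError("paradigm references neurons outside the network")

    state = core.NetworkState.rest(p, t=-paradigm.warmup)
    rng = np.random.default_rng(seed)
    dt = p.dt
    t0 = -paradigm.warmup
    n_steps = int(round((paradigm.t_end - t0) / dt))

    record = SimulationRecord(
        params=p, seed=int(seed),
        patterns={k: v.copy() for k, v in paradigm.patterns.items()},
        t_start=t0, t_end=paradigm.t_end,
    )
    record.events.append((t0, "warmup start"))

    # pattern index grids for block statistics
    names = list(paradigm.patterns)
    groups = {name: paradigm.patterns[name] for name in names}
    in_any = np.zeros(p.N, dtype=bool)
    for idx in groups.values():
        in_any[idx] = True
    groups["bg"] = np.flatnonzero(~in_any)
    group_names = list(groups)

    w_cad_steps = max(1, int(round(rec_opt.weight_cadence / dt)))
    w_times: list[float] = []
    w_stats: dict[str, list[float]] = {}
    for gi in group_names:
        for gj in group_names:
            w_stats[f"{gi}|{gj}:mean"] = []
            w_stats[f"{gi}|{gj}:std"] = []
    w_stats["all:mean"] = []
    w_stats["all:std"] = []
    offdiag = ~np.eye(p.N, dtype=bool)

    def snapshot_weights(t: float) -> None:
        W = state.W
        w_times.append(t)
        flat = W[offdiag]
        w_stats["all:mean"].append(float(flat.mean()))
        w_stats["all:std"].append(float(flat.std()))
        for gi in group_names:
            ii = groups[gi]
            for gj in group_names:
                jj = groups[gj]
                if len(ii) == 0 or len(jj) == 0:
                    m = s = np.nan
                else:
                    block = W[np.ix_(ii, jj)]
                    if gi == gj:
                        n = len(ii)
                        if n < 2:
                            m = s = np.nan
                        else:
                            mask = ~np.eye(n, dtype=bool)
                            vals = block[mask]
                            m, s = float(vals.mean()), float(vals.std())
                    else:
                        m, s = float(block.mean()), float(block.std())
                w_stats[f"{gi}|{gj}:mean"].append(m)
                w_stats[f"{gi}|{gj}:std"].append(s)

    dense_cad = rec_opt.dense_weight_cadence
    dense_steps = max(1, int(round(dense_cad / dt))) if dense_cad else None
    dense_times: list[float] = []
    dense_within: dict[str, list[float]] = {n: [] for n in names}

    def snapshot_dense(t: float) -> None:
        dense_times.append(t)
        for name in names:
            idx = groups[name]
            n = len(idx)
            block_sum = state.W[np.ix_(idx, idx)].sum()  # diagonal is zero
            dense_within[name].append(block_sum / (n * (n - 1)))

    if rec_opt.rate_trace:
        rate_mean = np.empty(n_steps)
        rate_max = np.empty(n_steps)

    pulse_times: list[float] = []
    pulse_patterns: list[str] = []
    pulse_fields: list[np.ndarray] = []
    pulse_rates: list[np.ndarray] = []

    probes = paradigm.probe_times
    probe_i = 0

    trains = paradigm.trains
    tr_onset = np.array([tr.onset for tr in trains])
    tr_period = np.array([tr.period if tr.period > 0 else np.inf
                          for tr in trains])
    tr_dur = np.array([tr.duration for tr in trains])
    tr_amp = np.array([tr.amplitude for tr in trains])
    tr_count = np.array([tr.count for tr in trains])
    tr_idx = [paradigm.patterns[tr.pattern] for tr in trains]
    tr_name = [tr.pattern for tr in trains]

    I = np.zeros(p.N)
    noisy = p.C != 0.0
    stim_started = False

    for k in range(n_steps):
        t = t0 + k * dt

        while probe_i < len(probes) and probes[probe_i][0] <= t + _TOL:
            _, pname = probes[probe_i]
            res = probe(state, paradigm.patterns[pname], p,
                        read_window=paradigm.read_window)
            res.pattern = pname
            res.time = probes[probe_i][0]
            record.probes.append(res)
            probe_i += 1

        if not stim_started and t >= -_TOL:
            stim_started = True
            record.events.append((0.0, "stimulation start"))
            if progress is not None:
                progress(0.0, "stimulation start")

        if k % w_cad_steps == 0:
            snapshot_weights(t)
        if dense_steps is not None and k % dense_steps == 0:
            snapshot_dense(t)

        I[:] = 0.0
        readouts: list[int] = []
        for ti in range(len(trains)):
            tk = t - tr_onset[ti]
            if tk < -_TOL:
                continue
            kk = int(tk // tr_period[ti]) if np.isfinite(tr_period[ti]) else 0
            if kk >= tr_count[ti]:
                continue
            within = tk - kk * tr_period[ti]
            if within < tr_dur[ti] - _TOL:
                I[tr_idx[ti]] = tr_amp[ti]
                if abs(within - (tr_dur[ti] - dt)) < 1e-6:
                    readouts.append(ti)

        noise = rng.standard_normal(p.N) if noisy else None
        h = core.step(state, I, p, noise)

        if rec_opt.rate_trace:
            rate_mean[k] = state.r.mean()
            rate_max[k] = state.r.max()
        if readouts and rec_opt.record_fields:
            for ti in readouts:
                pulse_times.append(t)
                pulse_patterns.append(tr_name[ti])
                pulse_fields.append(h.copy())
                pulse_rates.append(state.r.copy())

    # probes scheduled exactly at the end of the horizon
    while probe_i < len(probes) and probes[probe_i][0] <= paradigm.t_end + _TOL:
        _, pname = probes[probe_i]
        res = probe(state, paradigm.patterns[pname], p,
                    read_window=paradigm.read_window)
        res.pattern = pname
        res.time = probes[probe_i][0]
        record.probes.append(res)
        probe_i += 1
    if probe_i < len(probes):
        raise ValueError(
            f"probe at t={probes[probe_i][0]} lies beyond the simulation "
            f"horizon t_end={paradigm.t_end}"
        )
    snapshot_weights(t0 + n_steps * dt)
    record.events.append((paradigm.t_end, "end"))

    record.weight_times = np.array(w_times)
    record.weight_stats = {k: np.array(v) for k, v in w_stats.items()}
    if dense_steps is not None:
        record.dense_weight_times = np.array(dense_times)
        record.dense_within = {k: np.array(v) for k, v in dense_within.items()}
    if pulse_times:
        record.pulse_times = np.array(pulse_times)
        record.pulse_patterns = pulse_patterns
        record.pulse_fields = np.array(pulse_fields)
        record.pulse_rates = np.array(pulse_rates)
    if rec_opt.rate_trace:
        record.rate_times = t0 + np.arange(1, n_steps + 1) * dt
        record.rate_mean = rate_mean
        record.rate_max = rate_max
    record.final_r = state.r.copy()
    record.final_theta = state.theta.copy()
    record.final_W = state.W.copy()
    if progress is not None:
        progress(paradigm.t_end, "end")
    return record
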