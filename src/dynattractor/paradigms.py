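"""Named experiment builders.

Each builder returns a :class:`NamedExperiment` bundling a stimulation
paradigm with its model parameters, a repetition count and a base seed
(repetition j uses ``seed_base + j``).  Builders are pure: the same name and
overrides always yield an identical experiment, which makes every study
reconstructible from a one-line description.

Multi-pattern schedules interleave the patterns round-robin: pattern k's
pulse onsets are shifted by k * (shortest period) / (number of patterns),
which maximizes the temporal separation between pulses of different
patterns; the paradigm constructor verifies that no two pulses overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Paradigm, PulseTrain, RecordingOptions
from .params import ModelParams, scale_params

PULSE_DURATION = 5.0
PULSE_AMPLITUDE = 1.0


@dataclass(frozen=True)
class NamedExperiment:
    name: str
    paradigm: Paradigm
    params: ModelParams
    reps: int = 1
    seed_base: int = 0
    recording: RecordingOptions = RecordingOptions()

    def seeds(self) -> list[int]:
        return [self.seed_base + j for j in range(self.reps)]


def _contiguous_patterns(n_patterns: int, size: int) -> dict[str, np.ndarray]:
    return {
        f"P{k + 1}": np.arange(k * size, (k + 1) * size)
        for k in range(n_patterns)
    }


def _probe_schedule(train: PulseTrain, every: int,
                    include_last: bool = True) -> list[tuple[float, str]]:
    """Probe at every ``every``-th pulse onset (always including the first
    and, optionally, the last)."""
    onsets = train.pulse_onsets()
    picks = set(range(0, len(onsets), every))
    if include_last:
        picks.add(len(onsets) - 1)
    return [(float(onsets[i]), train.pattern) for i in sorted(picks)]


def formation(count: int = 10, period: float = 30.0,
              warmup: float = 50_000.0, post: float = 10_000.0,
              reps: int = 1, seed_base: int = 0,
              params: ModelParams | None = None) -> NamedExperiment:
    """Single-pattern assembly formation: 10 of 100 neurons pulsed 10 times.

    Probes at every pulse onset; within-pattern mean weights are tracked at
    every step so the rise to the weight ceiling can be timed.
    """
    p = params or ModelParams()
    patterns = _contiguous_patterns(1, p.pattern_size)
    train = PulseTrain("P1", onset=0.0, period=period,
                       duration=PULSE_DURATION, amplitude=p.I0, count=count)
    paradigm = Paradigm(
        patterns=patterns, trains=(train,), warmup=warmup, post=post,
        probe_times=tuple(_probe_schedule(train, every=1)),
    )
    return NamedExperiment(
        "formation", paradigm, p, reps, seed_base,
        recording=RecordingOptions(dense_weight_cadence=1.0))


def evolution(frequency: float = 1.0 / 60.0, count: int = 7000,
              probe_every: int = 25, warmup: float = 50_000.0,
              post: float = 10_000.0, reps: int = 10, seed_base: int = 0,
              params: ModelParams | None = None) -> NamedExperiment:
    """Long single-pattern stimulation driving assembly growth.

    The default 7000 pulses at f = 1/60 a.u. span about 420,000 a.u.  The
    stated observation times fall on pulse onsets (2500 pulses at
    t = 150,000 a.u.; the 7000th onset at t = 419,940 a.u.), where probes
    are taken.
    """
    p = params or ModelParams()
    period = 1.0 / frequency
    patterns = _contiguous_patterns(1, p.pattern_size)
    train = PulseTrain("P1", onset=0.0, period=period,
                       duration=PULSE_DURATION, amplitude=p.I0, count=count)
    paradigm = Paradigm(
        patterns=patterns, trains=(train,), warmup=warmup, post=post,
        probe_times=tuple(_probe_schedule(train, every=probe_every)),
    )
    return NamedExperiment("evolution", paradigm, p, reps, seed_base)


def frequency_sweep(frequencies=(1 / 30, 1 / 40, 1 / 60, 1 / 120),
                    horizon: float = 420_000.0, probe_every: int = 25,
                    reps: int = 10, seed_base: int = 0,
                    params: ModelParams | None = None) -> list[NamedExperiment]:
    """One single-pattern experiment per stimulation frequency.

    Each network learns a single pattern at its own frequency; the pulse
    count is chosen so that every run spans the same horizon.
    """
    out = []
    for f in frequencies:
        count = int(round(horizon * f))
        exp = evolution(frequency=f, count=count, probe_every=probe_every,
                        reps=reps, seed_base=seed_base, params=params)
        out.append(NamedExperiment(f"evolution_f{f:.6g}", exp.paradigm,
                                   exp.params, reps, seed_base))
    return out


def _interleaved_trains(patterns: list[str], periods: list[float],
                        horizon: float, amplitude: float,
                        start: float = 0.0) -> list[PulseTrain]:
    finite = [T for T in periods if T > 0]
    if not finite:
        return []
    offset_step = min(finite) / len(patterns)
    trains = []
    for k, (name, T) in enumerate(zip(patterns, periods)):
        if T <= 0:  # frequency 0: this pattern is not stimulated
            continue
        onset = start + k * offset_step
        count = max(1, int(np.floor((horizon - (onset - start)) / T)) + 1)
        while onset + (count - 1) * T + PULSE_DURATION > start + horizon + 1e-9:
            count -= 1
        trains.append(PulseTrain(name, onset=onset, period=T,
                                 duration=PULSE_DURATION,
                                 amplitude=amplitude, count=count))
    return trains


def two_patterns(f1: float = 1 / 60, f2: float = 1 / 60,
                 horizon: float = 420_000.0, probe_cadence: float = 1500.0,
                 reps: int = 10, seed_base: int = 0,
                 params: ModelParams | None = None) -> NamedExperiment:
    """Two non-overlapping 10-neuron patterns stimulated concurrently.

    P1 = neurons 0-9, P2 = neurons 10-19; pulse onsets of the two trains are
    phase-shifted so they never coincide.  Both patterns are probed on a
    common time grid.
    """
    p = params or ModelParams()
    patterns = _contiguous_patterns(2, p.pattern_size)
    trains = _interleaved_trains(["P1", "P2"], [1 / f1, 1 / f2], horizon, p.I0)
    probe_times = []
    for t in np.arange(0.0, horizon + 1e-9, probe_cadence):
        probe_times += [(float(t), "P1"), (float(t), "P2")]
    paradigm = Paradigm(patterns=patterns, trains=tuple(trains),
                        probe_times=tuple(probe_times))
    return NamedExperiment("two_patterns", paradigm, p, reps, seed_base)


def reinforce_and_forget(phase1_count: int = 12, horizon: float = 420_000.0,
                         probe_cadence: float = 1500.0, reps: int = 10,
                         seed_base: int = 0,
                         params: ModelParams | None = None) -> NamedExperiment:
    """Three patterns: form all at f = 1/90, then reinforce two, drop one.

    Phase 1 stimulates P1, P2, P3 (neurons 0-9, 10-19, 20-29) interleaved at
    the same frequency f = 1/90 a.u. until all three assemblies have formed.
    Phase 2 continues P1 at f = 1/60 and P2 at f = 1/120; P3 receives no
    further input, so its internal weights decay with time constant
    tau_w / beta and its neurons eventually become recruitable by P1.
    """
    p = params or ModelParams()
    patterns = _contiguous_patterns(3, p.pattern_size)
    phase1 = _interleaved_trains(["P1", "P2", "P3"], [90.0, 90.0, 90.0],
                                 horizon=(phase1_count - 1) * 90.0 + PULSE_DURATION,
                                 amplitude=p.I0)
    phase1_end = max(tr.end for tr in phase1)
    start2 = 90.0 * np.ceil(phase1_end / 90.0)
    phase2 = _interleaved_trains(["P1", "P2", "P3"], [60.0, 120.0, 0.0],
                                 horizon=horizon - start2, amplitude=p.I0,
                                 start=start2)
    probe_times = []
    for t in np.arange(0.0, horizon + 1e-9, probe_cadence):
        probe_times += [(float(t), name) for name in patterns]
    paradigm = Paradigm(patterns=patterns,
                        trains=tuple(phase1 + phase2),
                        probe_times=tuple(probe_times))
    return NamedExperiment("reinforce_and_forget", paradigm, p, reps, seed_base)


def noise_and_learning_demo(with_noise: bool = True, count: int = 15,
                            warmup: float = 0.0,
                            reps: int = 1, seed_base: int = 0) -> NamedExperiment:
    """Minimal demonstration of noise-driven recruitment.

    Uses the reduced parameter set of the model-construction stage: no input
    normalizations, low weight ceiling, and noise either on or off.  With
    noise off, no neuron outside the stimulated pattern can ever be
    recruited.
    """
    p = ModelParams(alpha_w=0.0, alpha_r=0.0, w_max=0.1, w_min=-0.05,
                    w_thr_override=0.1 / 6.0, C=0.006 if with_noise else 0.0,
                    beta=0.0)
    exp = formation(count=count, warmup=warmup, params=p,
                    reps=reps, seed_base=seed_base)
    name = "noise_demo" if with_noise else "noise_demo_noiseless"
    return NamedExperiment(name, exp.paradigm, p, reps, seed_base,
                           recording=exp.recording)


def scalability_suite(frequencies=(1 / 30, 1 / 60),
                      horizon: float = 200_000.0, reps: int = 3,
                      seed_base: int = 0) -> list[NamedExperiment]:
    """Single-pattern growth in larger networks.

    Covers (N, pattern size) in {500, 1000} x {10, 50} with the weight
    ceiling and noise coupling rescaled inversely with the pattern size.
    """
    base = ModelParams()
    out = []
    for N in (500, 1000):
        for size in (10, 50):
            p = scale_params(base, N, size)
            for f in frequencies:
                count = int(round(horizon * f))
                exp = evolution(frequency=f, count=count, params=p,
                                reps=reps, seed_base=seed_base)
                out.append(NamedExperiment(
                    f"scal_N{N}_M{size}_f{f:.6g}", exp.paradigm, p,
                    reps, seed_base))
    return out


def multi_assembly(n_assemblies: int = 2, size: int = 10,
                   horizon: float = 350_000.0, reps: int = 3,
                   seed_base: int = 0) -> NamedExperiment:
    """Many assemblies in a network of 1000, at two low frequencies.

    Half of the assemblies are stimulated at f = 1/600 a.u. and half at
    f = 1/1200 a.u.; the forgetting rate is slowed 20-fold (beta = 0.000125)
    to match the lower stimulation frequencies.
    """
    p = scale_params(ModelParams(), 1000, size, low_frequency=True)
    names = [f"P{k + 1}" for k in range(n_assemblies)]
    periods = [600.0 if k < (n_assemblies + 1) // 2 else 1200.0
               for k in range(n_assemblies)]
    patterns = _contiguous_patterns(n_assemblies, size)
    trains = _interleaved_trains(names, periods, horizon, p.I0)
    probe_times = []
    for t in np.arange(0.0, horizon + 1e-9, 6000.0):
        probe_times += [(float(t), n) for n in names]
    paradigm = Paradigm(patterns=patterns, trains=tuple(trains),
                        probe_times=tuple(probe_times))
    return NamedExperiment(f"multi_{n_assemblies}x{size}", paradigm, p,
                           reps, seed_base)


def ablation_suite(stim_horizon: float = 60_000.0,
                   seed_base: int = 0) -> list[NamedExperiment]:
    """Stability-mechanism removals, each violating one named property.

    - ``no_bounds``: weight ceiling removed (the heterosynaptic threshold is
      pinned at its default value); weights exceed the default ceiling.
    - ``no_decay``: beta = 0 under noise alone; std(W) grows without plateau.
    - ``no_syn_norm``: alpha_w = 0; assembly activity fails to return to
      baseline after the stimulation offset.
    - ``no_div_norm``: alpha_r = 0 (with alpha_w = 2); removes the
      sparseness-promoting divisive scaling.
    """
    base = ModelParams()
    out = []

    p_nb = base.replace(w_max=np.inf, w_thr_override=base.w_max / 6.0)
    exp = formation(count=10, params=p_nb, seed_base=seed_base)
    out.append(NamedExperiment("no_bounds", exp.paradigm, p_nb, 1, seed_base))

    p_nd = base.replace(beta=0.0)
    quiet = Paradigm(patterns={}, trains=(), warmup=0.0, post=stim_horizon)
    out.append(NamedExperiment("no_decay", quiet, p_nd, 1, seed_base))

    for name, p_ab in (("no_syn_norm", base.replace(alpha_w=0.0, alpha_r=2.0)),
                       ("no_div_norm", base.replace(alpha_w=2.0, alpha_r=0.0))):
        count = int(stim_horizon / 30.0)
        exp = evolution(frequency=1 / 30, count=count, probe_every=50,
                        params=p_ab, reps=1, seed_base=seed_base)
        out.append(NamedExperiment(name, exp.paradigm, p_ab, 1, seed_base))
    return out


#: Registry used by the command-line interface.
EXPERIMENTS = {
    "formation": formation,
    "evolution": evolution,
    "two_patterns": two_patterns,
    "reinforce_and_forget": reinforce_and_forget,
    "noise_demo": noise_and_learning_demo,
}


def build(name: str, **overrides) -> NamedExperiment:
    """Build a registered experiment by name with keyword overrides."""
    if name not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {name!r}; available: {sorted(EXPERIMENTS)}")
    return EXPERIMENTS[name](**overrides)
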