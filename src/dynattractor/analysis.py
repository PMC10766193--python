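"""Assembly detection and summary statistics over simulation records.

Membership is read from probe trajectories: a neuron belongs to the probed
assembly if its rate exceeds r_thr = 0.5 at 2 a.u. (twice the 1 a.u. test
pulse) after probe onset.  An alternative criterion takes the maximum rate
over the tail of the read window instead of the single read-out sample.
Assembly size counts every neuron passing the criterion, including the
originally stimulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import PROBE_READ_TIME, ProbeResult, SimulationRecord
from .params import ModelParams

R_THRESHOLD = 0.5


@dataclass
class AssemblySnapshot:
    """Probe-based membership of one pattern at one time."""

    time: float
    pattern: str
    members: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class FieldDistribution:
    """Input-field samples at stimulation read-outs, split by neuron class.

    ``other_assembly`` collects the fields of neurons originally belonging
    to a *different* pattern than the one being stimulated;``non_pattern``
    those of neurons belonging to no pattern.  For the non-pattern class,
    samples from pulses at or after a neuron's recruitment time are
    excluded, so the distribution describes not-yet-recruited neurons only.
    """

    other_assembly: np.ndarray
    non_pattern: np.ndarray


def membership(probe: ProbeResult, params: ModelParams | None = None,
               r_thr: float = R_THRESHOLD,
               criterion: str = "read_at_2") -> AssemblySnapshot:
    """Classify neurons as assembly members from one probe trajectory.

    ``criterion`` is ``"read_at_2"`` (rate at exactly 2 a.u. after probe
    onset) or ``"max_after_2"`` (maximum rate over times > 2 a.u.).
    """
    times = probe.times
    if criterion == "read_at_2":
        idx = np.flatnonzero(np.isclose(times, PROBE_READ_TIME))
        if len(idx) == 0:
            raise ValueError(
                f"probe read window {times[-1]} a.u. does not cover the "
                f"read-out time {PROBE_READ_TIME} a.u.")
        values = probe.rates[idx[0]]
    elif criterion == "max_after_2":
        sel = times > PROBE_READ_TIME
        if not np.any(sel):
            raise ValueError("probe read window ends before 2 a.u.")
        values = probe.rates[sel].max(axis=0)
    else:
        raise ValueError(f"unknown membership criterion {criterion!r}")
    return AssemblySnapshot(time=probe.time, pattern=probe.pattern,
                            members=np.flatnonzero(values > r_thr))


def snapshots(record: SimulationRecord, pattern: str,
              **kw) -> list[AssemblySnapshot]:
    """Membership snapshots for one pattern, in probe-time order."""
    return [membership(p, record.params, **kw)
            for p in record.probes_for(pattern)]


def size_timeseries(record: SimulationRecord, **kw) -> pd.DataFrame:
    """Assembly size versus probe time for every pattern.

    Returns columns ``time``, ``pattern``, ``size``.
    """
    rows = []
    for name in record.patterns:
        for snap in snapshots(record, name, **kw):
            rows.append((snap.time, name, snap.size))
    return pd.DataFrame(rows, columns=["time", "pattern", "size"])


def weight_groups(record: SimulationRecord) -> pd.DataFrame:
    """Recorded block-wise weight statistics as a tidy table.

    One row per snapshot time and ordered group pair (pattern names plus
    ``bg`` for the never-stimulated rest); ``within`` marks the
    within-group blocks.
    """
    if record.weight_times is None:
        raise ValueError("record carries no weight statistics")
    rows = []
    for key, vals in record.weight_stats.items():
        if key.startswith("all:") or not key.endswith(":mean"):
            continue
        pair = key[:-len(":mean")]
        gi, gj = pair.split("|")
        stds = record.weight_stats[f"{pair}:std"]
        for t, m, s in zip(record.weight_times, vals, stds):
            rows.append((t, gi, gj, m, s, gi == gj))
    return pd.DataFrame(
        rows, columns=["time", "to_group", "from_group", "mean", "std",
                       "within"])


def recruitment_times(record: SimulationRecord, pattern: str,
                      debounce: int = 2, **kw) -> dict[int, float]:
    """First sustained membership time per neuron for one pattern.

    A neuron counts as recruited at the first probe where it is a member
    and remains one for ``debounce`` consecutive probes (a membership at the
    final probe alone satisfies any debounce, as no later probe exists to
    contradict it).  Originally stimulated neurons are included; their
    recruitment time is simply when they first pass the criterion.
    """
    snaps = snapshots(record, pattern, **kw)
    member_sets = [set(s.members.tolist()) for s in snaps]
    out: dict[int, float] = {}
    for i, s in enumerate(member_sets):
        window = member_sets[i:i + debounce]
        sustained = set.intersection(*window) if window else set()
        for j in sustained:
            out.setdefault(j, snaps[i].time)
    return out


def overlap(a: AssemblySnapshot, b: AssemblySnapshot) -> int:
    """Number of neurons shared by two assemblies."""
    return len(np.intersect1d(a.members, b.members))


def pairwise_overlaps(record: SimulationRecord, **kw) -> pd.DataFrame:
    """Shared-neuron counts for every pattern pair at every common probe time."""
    names = list(record.patterns)
    by_pattern = {n: {s.time: s for s in snapshots(record, n, **kw)}
                  for n in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            common = sorted(set(by_pattern[a]) & set(by_pattern[b]))
            for t in common:
                rows.append((t, a, b,
                             overlap(by_pattern[a][t], by_pattern[b][t])))
    return pd.DataFrame(rows, columns=["time", "pattern_a", "pattern_b",
                                       "overlap"])


def field_distributions(record: SimulationRecord, pattern_names=None,
                        debounce: int = 2) -> FieldDistribution:
    """Input fields at stimulation read-outs, split by neuron class.

    For each recorded pulse of a stimulated pattern, the input fields of
    (i) original members of the *other* patterns and (ii) neurons outside
    every pattern are collected; class (ii) drops, per neuron, all pulses at
    or after its recruitment into any pattern.
    """
    if record.pulse_fields is None or len(record.pulse_patterns) == 0:
        raise ValueError("record carries no stimulation read-outs")
    names = list(pattern_names or record.patterns)
    N = record.params.N
    in_pattern = {n: np.zeros(N, dtype=bool) for n in names}
    any_pattern = np.zeros(N, dtype=bool)
    for n in names:
        in_pattern[n][record.patterns[n]] = True
        any_pattern[record.patterns[n]] = True

    recruited_at = np.full(N, np.inf)
    for n in names:
        for j, t in recruitment_times(record, n, debounce=debounce).items():
            recruited_at[j] = min(recruited_at[j], t)

    other, nonpat = [], []
    for t, pname, h in zip(record.pulse_times, record.pulse_patterns,
                           record.pulse_fields):
        if pname not in in_pattern:
            continue
        other_mask = any_pattern & ~in_pattern[pname]
        other.append(h[other_mask])
        np_mask = ~any_pattern & (recruited_at > t)
        nonpat.append(h[np_mask])
    return FieldDistribution(
        other_assembly=np.concatenate(other) if other else np.array([]),
        non_pattern=np.concatenate(nonpat) if nonpat else np.array([]),
    )


def recruitment_provenance(record: SimulationRecord, pattern: str,
                           debounce: int = 2) -> dict[str, float]:
    """Where a pattern's recruits originally came from.

    Classifies every neuron recruited into ``pattern`` (excluding its own
    original members) by its initial partition: one of the other pattern
    names, or ``"NP"`` for neurons that started outside every pattern.
    Returns proportions summing to 1 (empty dict if nothing was recruited).
    """
    own = set(record.patterns[pattern].tolist())
    rec = {j for j in recruitment_times(record, pattern, debounce=debounce)
           if j not in own}
    if not rec:
        return {}
    origin = {}
    for name, idx in record.patterns.items():
        if name == pattern:
            continue
        origin.update({int(j): name for j in idx})
    counts: dict[str, int] = {}
    for j in rec:
        cls = origin.get(j, "NP")
        counts[cls] = counts.get(cls, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def compare_groups(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA plus pairwise two-sided Welch t-tests across groups.

    ``groups`` maps labels to per-repetition samples (e.g. final assembly
    sizes per seed).  The p-values depend on the random repetitions and are
    reported for orientation, not as a calibrated acceptance quantity.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 repetitions")
    f, p = sps.f_oneway(*arrays.values())
    pairwise = {}
    labels = list(arrays)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            t, pt = sps.ttest_ind(arrays[a], arrays[b], equal_var=False)
            pairwise[(a, b)] = {"t": float(t), "p": float(pt)}
    return {"anova": {"F": float(f), "p": float(p)}, "pairwise": pairwise}
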