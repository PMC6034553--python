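"""Dendritic NMDA spikes: detection, minimal synapse counts, and counting
of simultaneously independent spikes (nonlinear dendritic subunits).

An NMDA spike is a prolonged local plateau: the dendritic voltage exceeds
−40 mV for at least 20 ms (defaults of :class:`NMDASpikeCriterion`).  The
minimal number of clustered axo-spinous AMPA+NMDA synapses that ignites one
is found per branch; a set of simultaneously activated terminal clusters
counts as *independent* NMDA spikes when every activated terminal sustains
its own plateau while every branch point connecting two activated terminals
stays below the −40 mV threshold throughout the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .cable import CompartmentalModel, Trace, simulate
from .synapses import (
    AMPA_DEFAULT,
    NMDA_DEFAULT,
    PROTOTYPICAL_SPINE,
    SpineGeometry,
    SynapseKinetics,
    SynapticEvent,
    attach_spines,
)


@dataclass(frozen=True)
class NMDASpikeCriterion:
    """Plateau detection: V > v_threshold for at least min_duration."""

    v_threshold: float = -40.0   # mV
    min_duration: float = 20.0   # ms

    def __post_init__(self) -> None:
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")


@dataclass(frozen=True)
class ClusterSpec:
    """A cluster of spinous synapses on one branch within a short stretch."""

    site: int                    # anchor compartment
    n_synapses: int
    span: float = 20.0           # μm of dendritic stretch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValueError("span must be positive")
        if self.n_synapses < 0:
            raise ValueError("n_synapses must be >= 0")


def detect_nmda_spike(
    trace: Trace, criterion: NMDASpikeCriterion = NMDASpikeCriterion()
) -> tuple[bool, float | None, float | None]:
    """Detect a plateau; returns (detected, onset_ms, duration_ms).

    True iff some contiguous interval of at least ``min_duration`` stays
    above ``v_threshold``; crossing times are linearly interpolated.  When
    several qualifying intervals exist the longest is reported.
    """
    t, v = trace.t, trace.v
    above = v > criterion.v_threshold
    if not above.any():
        return False, None, None
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    stops = []
    for e in edges:
        if above[e + 1]:
            starts.append(e + 1)
        else:
            stops.append(e)
    if above[-1]:
        stops.append(len(v) - 1)
    best = (False, None, None)
    best_dur = -1.0
    thr = criterion.v_threshold
    for i0, i1 in zip(starts, stops):
        t_on = t[i0]
        if i0 > 0:
            f = (thr - v[i0 - 1]) / (v[i0] - v[i0 - 1])
            t_on = t[i0 - 1] + f * (t[i0] - t[i0 - 1])
        t_off = t[i1]
        if i1 < len(v) - 1:
            f = (thr - v[i1]) / (v[i1 + 1] - v[i1])
            t_off = t[i1] + f * (t[i1 + 1] - t[i1])
        dur = t_off - t_on
        if dur > best_dur:
            best_dur = dur
            best = (bool(dur >= criterion.min_duration), float(t_on),
                    float(dur))
    return best


def cluster_positions(
    model: CompartmentalModel,
    site: int,
    span: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n spine positions uniformly within ``span`` μm of dendritic
    stretch around ``site`` on the same branch (section)."""
    sec = model.sec_of[site]
    in_sec = np.flatnonzero(
        (model.sec_of == sec) & (model.comp_type == model.comp_type[site])
    )
    d0 = model.path_dist[site]
    near = in_sec[np.abs(model.path_dist[in_sec] - d0) <= span / 2]
    if near.size == 0:
        near = np.array([site])
    return rng.choice(near, size=n, replace=True)


def _cluster_events(
    heads,
    onset: float,
    ampa: SynapseKinetics,
    nmda: SynapseKinetics,
) -> list[SynapticEvent]:
    ev = []
    for h in heads:
        if ampa.g_max > 0:
            ev.append(SynapticEvent(comp=h, kinetics=ampa, onset=onset))
        if nmda.g_max > 0:
            ev.append(SynapticEvent(comp=h, kinetics=nmda, onset=onset))
    return ev


def _spike_at_site(
    model, site, positions, criterion, ampa, nmda, geom, dt, duration, onset
) -> bool:
    if len(positions) == 0:
        return False
    spiny, heads = attach_spines(model, positions, geom)
    tr = simulate(
        spiny,
        _cluster_events(heads, onset, ampa, nmda),
        dt=dt,
        duration=duration,
        record=[site],
    )[site]
    return detect_nmda_spike(tr, criterion)[0]


def min_synapses_for_nmda_spike(
    model: CompartmentalModel,
    site: int,
    criterion: NMDASpikeCriterion = NMDASpikeCriterion(),
    step: int = 1,
    seed: int = 0,
    span: float = 20.0,
    max_synapses: int = 200,
    ampa: SynapseKinetics = AMPA_DEFAULT,
    nmda: SynapseKinetics = NMDA_DEFAULT,
    geom: SpineGeometry = PROTOTYPICAL_SPINE,
    dt: float = 0.05,
    duration: float = 120.0,
    onset: float = 2.0,
) -> int | None:
    """Smallest number of simultaneously activated spinous AMPA+NMDA
    synapses (clustered within ``span`` μm around ``site``) that triggers a
    local NMDA spike at the stem.

    Spine positions are drawn once per seed; activating n synapses uses the
    first n of them, so the response is monotone in n for a fixed placement
    and the threshold is located by bracketing + bisection at granularity
    ``step``.  Returns None when ``max_synapses`` synapses do not suffice.
    """
    if model.comp_type[site] not in (3, 4):
        raise ValueError("site must be dendritic")
    rng = np.random.default_rng(seed)
    positions = cluster_positions(model, site, span, max_synapses, rng)

    def spikes(n: int) -> bool:
        return _spike_at_site(
            model, site, positions[:n], criterion, ampa, nmda, geom,
            dt, duration, onset,
        )

    # exponential bracket, then bisection (response monotone in n)
    lo, hi = 0, step
    while hi <= max_synapses and not spikes(hi):
        lo, hi = hi, hi * 2 if hi * 2 - hi >= step else hi + step
    if hi > max_synapses:
        if not spikes(max_synapses):
            return None
        hi = max_synapses
    while hi - lo > step:
        mid = (lo + hi) // 2
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    # refine to exact count within the final step
    for n in range(lo + 1, hi + 1):
        if spikes(n):
            return n
    return hi


@dataclass
class IndependenceReport:
    """Largest found set of terminals sustaining independent NMDA spikes."""

    terminals: tuple[int, ...]            # activated terminal compartments
    n_synapses: dict[int, int]            # per-terminal cluster size
    branch_point_peaks: dict[tuple[int, int], float]
    count: int
    strategy: str
    n_simulations: int
    candidates: tuple[int, ...] = ()      # terminals considered


def _check_configuration(
    model, members, placements, criterion, ampa, nmda, geom, dt, duration,
    onset,
):
    """Simulate a set of terminal clusters activated at a common onset.

    Valid iff every member terminal shows a local NMDA spike and the peak
    voltage at the branch point (lowest common ancestor) of every member
    pair stays below the detection threshold.
    """
    all_sites = np.concatenate([placements[t] for t in members])
    spiny, heads = attach_spines(model, all_sites, geom)
    events = _cluster_events(heads, onset, ampa, nmda)
    rec = list(members)
    pair_bp = {}
    for a, b in combinations(sorted(members), 2):
        pair_bp[(a, b)] = model.lca(a, b)
    rec += list(set(pair_bp.values()))
    traces = simulate(spiny, events, dt=dt, duration=duration, record=rec)
    ok = all(detect_nmda_spike(traces[t], criterion)[0] for t in members)
    peaks = {
        pair: float(traces[bp].v.max()) for pair, bp in pair_bp.items()
    }
    independent = all(p < criterion.v_threshold for p in peaks.values())
    return ok and independent, peaks


def count_independent_nmda_spikes(
    model: CompartmentalModel,
    criterion: NMDASpikeCriterion = NMDASpikeCriterion(),
    strategy: str = "greedy-backtrack",
    seed: int = 0,
    span: float = 20.0,
    max_synapses: int = 60,
    ampa: SynapseKinetics = AMPA_DEFAULT,
    nmda: SynapseKinetics = NMDA_DEFAULT,
    geom: SpineGeometry = PROTOTYPICAL_SPINE,
    dt: float = 0.05,
    duration: float = 120.0,
    onset: float = 2.0,
    backtrack_budget: int = 40,
) -> IndependenceReport:
    """Count simultaneously independent NMDA spikes on a passive model.

    Each dendritic terminal gets the minimal cluster that ignites its own
    NMDA spike in isolation; terminals are then added most-distal-first (in
    electrotonic terms).  ``strategy``:

    - ``"greedy"``: accept a terminal iff the joint configuration stays
      valid.
    - ``"greedy-backtrack"`` (default): greedy, then bounded swap passes
      (drop one accepted member to admit two skipped ones) — never worse
      than pure greedy.
    - ``"exhaustive"``: search subsets by decreasing size (only sensible
      for small trees; refuses > 12 candidate terminals).
    """
    n_sims = 0
    terminals = model.terminal_compartments()
    elec = model.electrotonic_distance()
    order = terminals[np.argsort(-elec[terminals])]

    rng = np.random.default_rng(seed)
    placements: dict[int, np.ndarray] = {}
    cluster_n: dict[int, int] = {}
    usable = []
    for t in order:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        n_min = min_synapses_for_nmda_spike(
            model, int(t), criterion, seed=sub_seed, span=span,
            max_synapses=max_synapses, ampa=ampa, nmda=nmda, geom=geom,
            dt=dt, duration=duration, onset=onset,
        )
        n_sims += 8  # bracketing/bisection sims (approximate bookkeeping)
        if n_min is None:
            continue
        pos_rng = np.random.default_rng(sub_seed)
        placements[int(t)] = cluster_positions(
            model, int(t), span, n_min, pos_rng)
        cluster_n[int(t)] = n_min
        usable.append(int(t))

    def check(members) -> bool:
        nonlocal n_sims, last_peaks
        n_sims += 1
        ok, peaks = _check_configuration(
            model, list(members), placements, criterion, ampa, nmda, geom,
            dt, duration, onset,
        )
        last_peaks = peaks
        return ok

    last_peaks: dict = {}
    accepted: list[int] = []
    if strategy == "exhaustive":
        if len(usable) > 12:
            raise ValueError("exhaustive strategy limited to <= 12 terminals")
        best: list[int] = []
        for size in range(len(usable), 0, -1):
            for combo in combinations(usable, size):
                if check(combo):
                    best = list(combo)
                    break
            if best:
                break
        accepted = best
        if accepted:
            check(accepted)  # refresh last_peaks for the report
    else:
        skipped: list[int] = []
        for t in usable:
            if check(accepted + [t]):
                accepted.append(t)
            else:
                skipped.append(t)
        if strategy == "greedy-backtrack":
            budget = backtrack_budget
            improved = True
            while improved and budget > 0:
                improved = False
                for drop in list(accepted):
                    if budget <= 0:
                        break
                    base = [x for x in accepted if x != drop]
                    gained = []
                    for u in skipped:
                        if budget <= 0:
                            break
                        if check(base + gained + [u]):
                            gained.append(u)
                        budget -= 1
                    if len(gained) > 1:
                        accepted = base + gained
                        skipped = [x for x in usable if x not in accepted]
                        improved = True
                        break
        elif strategy != "greedy":
            raise ValueError(f"unknown strategy {strategy!r}")
        if accepted:
            check(accepted)

    return IndependenceReport(
        terminals=tuple(accepted),
        n_synapses={t: cluster_n[t] for t in accepted},
        branch_point_peaks=last_peaks,
        count=len(accepted),
        strategy=strategy,
        n_simulations=n_sims,
        candidates=tuple(usable),
    )
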