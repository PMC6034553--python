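"""Somatic EPSP analysis: shape indices, time-constant peeling,
synapse localization and conductance fitting.

The shape index of an EPSP is its (rise time, half-width) pair.  Proximal
synapses produce brief, narrow somatic EPSPs; distal ones slow and broad —
so the theoretical shape-index curve of a model cell, built by activating
one AMPA synapse per dendritic compartment, localizes an experimental EPSP
to the set of compartments whose shape index falls within a radius (default
1 ms) of the experimental one.  Peak conductances are then fitted by
derivative-free least squares on the full somatic waveform, assuming five
synaptic contacts per connection.

The NMDA kinetics fit is two-staged: stage 1 fits rise/decay time
constants, Mg-block steepness γ and conductances to the EPSP recorded with
AMPA blockers (a residual AMPA conductance is allowed, since the blocker is
competitive); stage 2 freezes those and fits the unblocked AMPA
conductance, constrained to at least five times the blocked one.
Candidates are ranked by summed RMSD against both target EPSPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .cable import CompartmentalModel, Trace, simulate
from .synapses import (
    AMPA_DEFAULT,
    SynapseKinetics,
    SynapticEvent,
    attach_spines,
)


class EPSPAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class ShapeIndex:
    """EPSP rise time (10–90%) and half-width (duration above 50%), ms."""

    rise_time: float
    half_width: float

    def __post_init__(self) -> None:
        if self.rise_time <= 0 or self.half_width <= 0:
            raise EPSPAnalysisError("shape index components must be positive")
        if self.half_width <= 0.5 * self.rise_time:
            warnings.warn(
                "half_width <= 0.5 * rise_time: implausible EPSP shape",
                stacklevel=2,
            )

    def distance(self, other: "ShapeIndex") -> float:
        return float(
            np.hypot(self.rise_time - other.rise_time,
                     self.half_width - other.half_width)
        )


def _cross_time(t: np.ndarray, v: np.ndarray, level: float, rising: bool) -> float:
    """First (rising) / last (falling) linear-interpolated crossing of level."""
    above = v >= level
    idx = np.flatnonzero(above[1:] != above[:-1])
    if idx.size == 0:
        raise EPSPAnalysisError("trace never crosses the requested level")
    if rising:
        i = idx[0]
    else:
        i = idx[-1]
    f = (level - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + f * (t[i + 1] - t[i]))


def shape_index(trace: Trace, baseline_t: float | None = None) -> ShapeIndex:
    """Measure the shape index of a single EPSP-like transient.

    ``baseline_t``: end of the pre-onset window used for the baseline mean;
    default is the first sample.  Rise time is 10→90% of peak on the rising
    phase; half-width is the time spent above 50% of peak.
    """
    t, v = trace.t, trace.v
    if baseline_t is None:
        base = float(v[0])
        i0 = 0
    else:
        mask = t <= baseline_t
        if not mask.any():
            raise EPSPAnalysisError("baseline window is empty")
        base = float(v[mask].mean())
        i0 = int(mask.sum()) - 1
    vv = v[i0:] - base
    tt = t[i0:]
    ipk = int(np.argmax(vv))
    peak = float(vv[ipk])
    if peak <= 0:
        raise EPSPAnalysisError("non-positive EPSP peak")
    rise = vv[: ipk + 1]
    tr10 = _cross_time(tt[: ipk + 1], rise, 0.1 * peak, rising=True)
    tr90 = _cross_time(tt[: ipk + 1], rise, 0.9 * peak, rising=True)
    t_up = _cross_time(tt[: ipk + 1], rise, 0.5 * peak, rising=True)
    t_dn = _cross_time(tt[ipk:], vv[ipk:], 0.5 * peak, rising=False)
    return ShapeIndex(rise_time=tr90 - tr10, half_width=t_dn - t_up)


def peel_time_constant(
    trace: Trace,
    tail_window: tuple[float, float],
    baseline: float | None = None,
) -> float:
    """Slowest membrane time constant by 'peeling' the EPSP tail (ms).

    Least-squares slope of ln(V − baseline) over ``tail_window``; the tail
    must be strictly positive there.
    """
    t, v = trace.t, trace.v
    base = float(v[0]) if baseline is None else baseline
    mask = (t >= tail_window[0]) & (t <= tail_window[1])
    if mask.sum() < 3:
        raise EPSPAnalysisError("tail window holds fewer than 3 samples")
    tail = v[mask] - base
    if np.any(tail <= 0):
        raise EPSPAnalysisError("tail is not strictly positive over the window")
    slope = np.polyfit(t[mask], np.log(tail), 1)[0]
    if slope >= 0:
        raise EPSPAnalysisError("tail does not decay over the window")
    return float(-1.0 / slope)


@dataclass
class ShapeIndexCurve:
    """Per-compartment somatic shape indices of a model cell."""

    comp: np.ndarray          # compartment index
    path_dist: np.ndarray     # μm
    subtree: np.ndarray       # SWC type code (3 basal / 4 apical)
    rise_time: np.ndarray     # ms
    half_width: np.ndarray    # ms

    def __len__(self) -> int:
        return int(self.comp.size)


def build_shape_index_curve(
    model: CompartmentalModel,
    ampa_kin: SynapseKinetics = AMPA_DEFAULT,
    dt: float = 0.025,
    duration: float = 120.0,
    onset: float = 1.0,
    comps: np.ndarray | None = None,
) -> ShapeIndexCurve:
    """Somatic shape index for a single AMPA synapse on every dendritic
    compartment (or the subset ``comps``)."""
    if model.active is not None:
        raise ValueError("shape-index curves are a passive-model analysis")
    if comps is None:
        comps = np.flatnonzero(model.dendritic_mask())
    rt, hw = np.empty(comps.size), np.empty(comps.size)
    soma = model.soma_index
    for k, c in enumerate(comps):
        tr = simulate(
            model,
            [SynapticEvent(comp=int(c), kinetics=ampa_kin, onset=onset)],
            dt=dt,
            duration=duration,
            record=[soma],
        )[soma]
        si = shape_index(tr, baseline_t=onset)
        rt[k], hw[k] = si.rise_time, si.half_width
    return ShapeIndexCurve(
        comp=comps.copy(),
        path_dist=model.path_dist[comps],
        subtree=model.comp_type[comps],
        rise_time=rt,
        half_width=hw,
    )


def putative_locations(
    curve: ShapeIndexCurve,
    experimental_si: ShapeIndex,
    radius: float = 1.0,
) -> np.ndarray:
    """Compartments whose shape index lies within ``radius`` ms (Euclidean
    in the rise-time/half-width plane) of the experimental shape index."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = np.hypot(
        curve.rise_time - experimental_si.rise_time,
        curve.half_width - experimental_si.half_width,
    )
    return curve.comp[d <= radius]


def _resample(target: Trace, t: np.ndarray) -> np.ndarray:
    return np.interp(t, target.t, target.v)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class ConnectionFit:
    """Fitted shared per-contact AMPA conductance for one connection."""

    g_mean: float            # nS
    g_sd: float
    g_samples: np.ndarray    # per repeat
    rmsd: np.ndarray         # per repeat, mV
    sites: list[tuple[int, ...]]
    repeats: int
    seed: int


def fit_connection(
    model: CompartmentalModel,
    target_epsp: Trace,
    site_pool: np.ndarray,
    contacts_per_connection: int = 5,
    repeats: int = 100,
    seed: int = 0,
    dt: float = 0.05,
    onset: float = 1.0,
    g_max_bound: float = 5.0,
) -> ConnectionFit:
    """Fit one shared per-contact peak AMPA conductance to a somatic EPSP.

    Per repeat, ``contacts_per_connection`` sites are drawn uniformly
    without replacement from ``site_pool``, activated simultaneously, and a
    single shared g_AMPA is fitted by bounded derivative-free least squares
    over the full waveform.
    """
    site_pool = np.asarray(site_pool, dtype=int)
    if site_pool.size < contacts_per_connection:
        raise ValueError("site pool smaller than contacts_per_connection")
    rng = np.random.default_rng(seed)
    duration = float(target_epsp.t[-1])
    soma = model.soma_index
    t_ref = np.arange(int(round(duration / dt)) + 1) * dt
    tgt = _resample(target_epsp, t_ref)

    gs, rs, site_log = np.empty(repeats), np.empty(repeats), []
    for rep in range(repeats):
        sites = rng.choice(site_pool, size=contacts_per_connection, replace=False)
        site_log.append(tuple(int(s) for s in sites))

        def objective(g: float) -> float:
            kin = SynapseKinetics(
                g_max=g,
                tau_rise=AMPA_DEFAULT.tau_rise,
                tau_decay=AMPA_DEFAULT.tau_decay,
            )
            events = [SynapticEvent(comp=int(s), kinetics=kin, onset=onset)
                      for s in sites]
            tr = simulate(model, events, dt=dt, duration=duration,
                          record=[soma])[soma]
            return _rmsd(tr.v, tgt)

        res = minimize_scalar(objective, bounds=(0.0, g_max_bound),
                              method="bounded",
                              options={"xatol": 1e-3})
        gs[rep], rs[rep] = float(res.x), float(res.fun)
    return ConnectionFit(
        g_mean=float(gs.mean()),
        g_sd=float(gs.std(ddof=1)) if repeats > 1 else 0.0,
        g_samples=gs,
        rmsd=rs,
        sites=site_log,
        repeats=repeats,
        seed=seed,
    )


@dataclass
class NMDAFit:
    """One candidate synaptic configuration with fitted NMDA kinetics."""

    sites: tuple[int, ...]
    tau_rise: float
    tau_decay: float
    gamma: float
    g_nmda: float            # nS per contact
    g_ampa: float            # nS, unblocked (stage 2)
    g_ampa_blocked: float    # nS, residual under blocker (stage 1)
    rmsd_blocked: float
    rmsd_unblocked: float
    seed: int
    flagged: bool = False    # stage-2 constraint bound at zero improvement

    @property
    def rmsd_total(self) -> float:
        return self.rmsd_blocked + self.rmsd_unblocked


@dataclass
class NMDAFitResult:
    fits: list[NMDAFit] = field(default_factory=list)   # ranked by rmsd_total
    best_typical: NMDAFit | None = None


# stage-1 bounds: bracket the reported human values and the rodent range
_NMDA_BOUNDS = {
    "tau_rise": (1.0, 20.0),
    "tau_decay": (20.0, 100.0),
    "gamma": (0.03, 0.12),
    "g_nmda": (0.0, 5.0),
    "g_ampa_blocked": (0.0, 1.0),
}
_NMDA_X0 = np.array([10.0, 60.0, 0.075, 1.0, 0.3])




def fit_nmda_kinetics(
    model: CompartmentalModel,
    blocked_epsp: Trace,
    unblocked_epsp: Trace,
    region: np.ndarray,
    n_syn_range: tuple[int, int] = (15, 30),
    n_seeds: int = 200,
    seed: int = 0,
    dt: float = 0.05,
    onset: float = 1.0,
    maxfev: int = 160,
    top_keep: int = 100,
) -> NMDAFitResult:
    """Two-stage fit of NMDA kinetics and conductances to a blocked /
    unblocked pair of composite somatic EPSPs.

    Stage 1: per candidate seed, draw a synapse count from ``n_syn_range``
    and spine-head locations from ``region``, then fit (τ_rise, τ_decay, γ,
    g_NMDA, g_AMPA_blocked) to the blocked EPSP by Nelder–Mead within
    bounds.  Stage 2: freeze stage-1 parameters and fit the unblocked
    g_AMPA ≥ 5·g_AMPA_blocked.  Candidates are ranked by summed RMSD; the
    *best typical* fit is the ranked candidate whose parameters are nearest
    (in bound-normalized space) to the mean of the best ``top_keep``.
    """
    if blocked_epsp.t[-1] != unblocked_epsp.t[-1]:
        raise ValueError("blocked and unblocked EPSPs must share a time base")
    region = np.asarray(region, dtype=int)
    if region.size == 0:
        raise ValueError("empty candidate region")
    rng = np.random.default_rng(seed)
    duration = float(blocked_epsp.t[-1])
    t_ref = np.arange(int(round(duration / dt)) + 1) * dt
    tgt_b = _resample(blocked_epsp, t_ref)
    tgt_u = _resample(unblocked_epsp, t_ref)
    soma = model.soma_index

    lo = np.array([b[0] for b in _NMDA_BOUNDS.values()])
    hi = np.array([b[1] for b in _NMDA_BOUNDS.values()])

    fits: list[NMDAFit] = []
    for cand in range(n_seeds):
        n_syn = int(rng.integers(n_syn_range[0], n_syn_range[1] + 1))
        sites = rng.choice(region, size=n_syn, replace=region.size < n_syn)
        spiny, heads = attach_spines(model, sites)

        def simulate_soma(tau_r, tau_d, gam, g_n, g_a):
            events = []
            if g_n > 0:
                nmda = SynapseKinetics(
                    g_max=g_n, tau_rise=tau_r, tau_decay=tau_d,
                    voltage_dependent=True, gamma=gam,
                )
                events += [SynapticEvent(comp=h, kinetics=nmda, onset=onset)
                           for h in heads]
            if g_a > 0:
                ampa = SynapseKinetics(
                    g_max=g_a,
                    tau_rise=AMPA_DEFAULT.tau_rise,
                    tau_decay=AMPA_DEFAULT.tau_decay,
                )
                events += [SynapticEvent(comp=h, kinetics=ampa, onset=onset)
                           for h in heads]
            return simulate(spiny, events, dt=dt, duration=duration,
                            record=[soma])[soma].v

        def stage1_obj(x: np.ndarray) -> float:
            xc = np.clip(x, lo, hi)
            penalty = float(np.sum(np.abs(x - xc)))
            if xc[0] >= xc[1] - 1e-6:  # tau_rise must stay below tau_decay
                return 1e3 + penalty
            v = simulate_soma(xc[0], xc[1], xc[2], xc[3], xc[4])
            return _rmsd(v, tgt_b) + 10.0 * penalty

        res = minimize(
            stage1_obj, _NMDA_X0, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-5},
        )
        x1 = np.clip(res.x, lo, hi)
        tau_r, tau_d, gam, g_n, g_ab = (float(v) for v in x1)
        rmsd_b = float(stage1_obj(x1))

        # stage 2: only the unblocked AMPA conductance is free
        g_lo = 5.0 * g_ab

        def stage2_obj(g_a: float) -> float:
            return _rmsd(simulate_soma(tau_r, tau_d, gam, g_n, g_a), tgt_u)

        res2 = minimize_scalar(
            stage2_obj, bounds=(g_lo, max(g_lo + 1e-6, 20.0)),
            method="bounded", options={"xatol": 1e-3},
        )
        g_a = float(res2.x)
        rmsd_u = float(res2.fun)
        flagged = (
            abs(g_a - g_lo) < 2e-3
            and stage2_obj(g_lo) <= stage2_obj(g_lo * 1.05 + 1e-3) + 1e-9
        )
        fits.append(NMDAFit(
            sites=tuple(int(s) for s in sites),
            tau_rise=tau_r, tau_decay=tau_d, gamma=gam,
            g_nmda=g_n, g_ampa=g_a, g_ampa_blocked=g_ab,
            rmsd_blocked=rmsd_b, rmsd_unblocked=rmsd_u,
            seed=cand, flagged=flagged,
        ))

    fits.sort(key=lambda f: f.rmsd_total)
    top = fits[: min(top_keep, len(fits))]

    def norm_params(f: NMDAFit) -> np.ndarray:
        x = np.array([f.tau_rise, f.tau_decay, f.gamma, f.g_nmda,
                      f.g_ampa_blocked])
        return (x - lo) / (hi - lo)

    center = np.mean([norm_params(f) for f in top], axis=0)
    best_typical = min(
        fits[: max(5, len(top) // 20)],
        key=lambda f: float(np.linalg.norm(norm_params(f) - center)),
    )
    return NMDAFitResult(fits=fits, best_typical=best_typical)
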