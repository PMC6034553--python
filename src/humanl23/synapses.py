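"""Kinetic AMPA/NMDA synapses and two-compartment dendritic spines.

The synaptic conductance follows a two-state kinetic scheme,

    g(t, V) = B(V) · g_max · N · (exp(−t/τ_decay) − exp(−t/τ_rise)),

normalized by N so that the peak equals B·g_max at

    t_peak = τ_rise·τ_decay/(τ_decay − τ_rise) · ln(τ_decay/τ_rise).

For NMDA receptors the magnesium-block factor is the Jahr–Stevens form
B(V) = 1/(1 + n·[Mg²⁺]·exp(−γV)); for AMPA, B ≡ 1.

Defaults are the human L2/L3 estimates: AMPA τ 0.3/1.8 ms with
g_max 0.88 nS per contact; NMDA τ 8.02/34.99 ms, γ = 0.0771 mV⁻¹,
n = 0.28 mM⁻¹, [Mg²⁺] = 1 mM, g_max 1.31 nS.  The prototypical spine has a
1.35 μm × 0.25 μm neck and a 2.8 μm² isopotential head, giving a neck
resistance of 50–80 MΩ at an axial resistivity of 200–300 Ω·cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cable import (
    CompartmentalModel,
    simulate,
    SPINE_NECK,
    SPINE_HEAD,
    _G_PAS,
    _CM,
    _R_AX,
)
from .morphology import AXON, DENDRITE_TYPES


@dataclass(frozen=True)
class SynapseKinetics:
    """Two-state kinetic conductance, optionally Mg-blocked (NMDA)."""

    g_max: float               # nS, peak conductance
    tau_rise: float            # ms
    tau_decay: float           # ms
    e_syn: float = 0.0         # mV
    voltage_dependent: bool = False
    gamma: float = 0.0771      # 1/mV, Mg-block steepness
    n: float = 0.28            # 1/mM, Mg sensitivity
    mg: float = 1.0            # mM

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if self.voltage_dependent and (self.gamma <= 0 or self.n <= 0 or self.mg < 0):
            raise ValueError("voltage-dependent kinetics need gamma, n > 0 and mg >= 0")


AMPA_DEFAULT = SynapseKinetics(g_max=0.88, tau_rise=0.3, tau_decay=1.8)
NMDA_DEFAULT = SynapseKinetics(
    g_max=1.31, tau_rise=8.02, tau_decay=34.99, voltage_dependent=True
)


@dataclass(frozen=True)
class CurrentStep:
    """Step current injection: ``amplitude`` nA on [start, end) ms."""

    comp: int
    amplitude: float
    start: float = 0.0
    end: float = np.inf


@dataclass(frozen=True)
class SynapticEvent:
    """One synapse activation at compartment ``comp`` starting at ``onset`` ms."""

    comp: int
    kinetics: SynapseKinetics
    onset: float = 0.0


def t_peak(kin: SynapseKinetics) -> float:
    """Time of peak conductance (ms)."""
    tr, td = kin.tau_rise, kin.tau_decay
    return tr * td / (td - tr) * np.log(td / tr)


def normalization_factor(kin: SynapseKinetics) -> float:
    """N such that the double exponential peaks at exactly 1."""
    tp = t_peak(kin)
    return 1.0 / (np.exp(-tp / kin.tau_decay) - np.exp(-tp / kin.tau_rise))


def mg_block(kin: SynapseKinetics, v) -> np.ndarray | float:
    """Magnesium-block factor B(V) ∈ (0, 1], increasing in V."""
    if not kin.voltage_dependent:
        raise ValueError("mg_block requires voltage-dependent kinetics")
    return 1.0 / (1.0 + kin.n * kin.mg * np.exp(-kin.gamma * np.asarray(v, dtype=float)))


def conductance_waveform(kin: SynapseKinetics, t, v: float | None = None):
    """Conductance g(t) in nS; for NMDA, at clamped voltage ``v`` (mV)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    b = 1.0
    if kin.voltage_dependent:
        b = mg_block(kin, -86.0 if v is None else v)
    g = (
        b
        * kin.g_max
        * normalization_factor(kin)
        * (np.exp(-t / kin.tau_decay) - np.exp(-t / kin.tau_rise))
    )
    return g


def synaptic_current(kin: SynapseKinetics, v, t):
    """I = g(t, V)·(V − E_syn) in nA; inward (negative) below reversal."""
    v = np.asarray(v, dtype=float)
    g = conductance_waveform(kin, t, v=v)  # nS
    return g * 1e-3 * (v - kin.e_syn)  # μS·mV = nA


@dataclass(frozen=True)
class SpineGeometry:
    """Neck cylinder plus isopotential head."""

    head_area: float = 2.8      # μm²
    neck_length: float = 1.35   # μm
    neck_diameter: float = 0.25  # μm

    def __post_init__(self) -> None:
        if min(self.head_area, self.neck_length, self.neck_diameter) <= 0:
            raise ValueError("spine geometry must be positive")


PROTOTYPICAL_SPINE = SpineGeometry()


def neck_resistance(geom: SpineGeometry, r_a: float) -> float:
    """Spine neck axial resistance (MΩ): 4·R_a·L/(π·d²)."""
    if geom.neck_diameter <= 0:
        raise ValueError("neck diameter must be positive")
    return 4.0 * r_a * geom.neck_length / (np.pi * geom.neck_diameter**2) * _R_AX


def attach_spines(
    model: CompartmentalModel,
    sites,
    geom: SpineGeometry | list[SpineGeometry] = PROTOTYPICAL_SPINE,
) -> tuple[CompartmentalModel, list[int]]:
    """Attach one two-compartment spine (neck + head) per dendritic site.

    The neck compartment carries its own membrane (capacitance and leak)
    and sits mid-neck: half the neck resistance links shaft to neck, the
    other half links neck to head.  Passive parameters are inherited from
    the host model (no spine-area correction is applied to explicit
    spines).  Returns (model', head_indices); the input model is not
    modified.  ``geom`` may be a single geometry or one per site.
    """
    sites = [int(s) for s in np.atleast_1d(np.asarray(sites, dtype=int))]
    geoms = geom if isinstance(geom, (list, tuple)) else [geom] * len(sites)
    if len(geoms) != len(sites):
        raise ValueError("need one geometry per site")
    for s in sites:
        if model.comp_type[s] == AXON or model.comp_type[s] not in (
            *DENDRITE_TYPES, SPINE_NECK, SPINE_HEAD
        ):
            raise ValueError("spines attach to dendritic compartments only")
        if model.comp_type[s] in (SPINE_NECK, SPINE_HEAD):
            raise ValueError("cannot attach a spine onto another spine")

    out = model.copy()
    p = out.params
    n0 = out.parent.size
    parent_l, gax_l, area_l, ctype_l, pdist_l, slen_l, secof_l = (
        [], [], [], [], [], [], [])
    heads = []
    for k, (s, g) in enumerate(zip(sites, geoms)):
        r_half = neck_resistance(g, p.r_a) / 2.0
        neck_area = np.pi * g.neck_diameter * g.neck_length
        neck_idx = n0 + 2 * k
        parent_l += [s, neck_idx]
        gax_l += [1.0 / r_half, 1.0 / r_half]
        area_l += [neck_area, g.head_area]
        ctype_l += [SPINE_NECK, SPINE_HEAD]
        pdist_l += [float(out.path_dist[s]) + g.neck_length / 2,
                    float(out.path_dist[s]) + g.neck_length]
        head_len = np.sqrt(g.head_area / np.pi)  # nominal, for bookkeeping
        slen_l += [g.neck_length, head_len]
        secof_l += [int(out.sec_of[s])] * 2
        heads.append(neck_idx + 1)

    area = np.array(area_l)
    out.parent = np.concatenate([out.parent, np.array(parent_l, dtype=np.int64)])
    out.g_axial = np.concatenate([out.g_axial, np.array(gax_l)])
    out.area = np.concatenate([out.area, area])
    out.cm = np.concatenate([out.cm, area * p.c_m * _CM])
    out.g_pas = np.concatenate([out.g_pas, area * _G_PAS / p.r_m])
    out.e_pas = np.concatenate([out.e_pas, np.full(area.size, p.e_rest)])
    out.comp_type = np.concatenate(
        [out.comp_type, np.array(ctype_l, dtype=np.int8)])
    out.path_dist = np.concatenate([out.path_dist, np.array(pdist_l)])
    out.seg_len = np.concatenate([out.seg_len, np.array(slen_l)])
    out.sec_of = np.concatenate(
        [out.sec_of, np.array(secof_l, dtype=np.int64)])
    return out, heads


def attach_spine(
    model: CompartmentalModel,
    site: int,
    geom: SpineGeometry = PROTOTYPICAL_SPINE,
) -> tuple[CompartmentalModel, int, int]:
    """Attach a single spine; returns (model', neck_index, head_index)."""
    out, heads = attach_spines(model, [site], geom)
    return out, heads[0] - 1, heads[0]


def activate_spinous_synapse(
    model: CompartmentalModel,
    site: int,
    kin: SynapseKinetics = AMPA_DEFAULT,
    geom: SpineGeometry = PROTOTYPICAL_SPINE,
    dt: float = 0.025,
    duration: float = 100.0,
    onset: float = 1.0,
    extra_kinetics: tuple[SynapseKinetics, ...] = (),
) -> dict:
    """Activate one synapse on a spine head; report EPSP peaks and ratios.

    Returns peak depolarizations (mV, relative to rest) at the spine head,
    the spine base (host compartment) and the soma, with head/base and
    head/soma attenuation ratios, plus the three traces.
    """
    spiny, _neck, head = attach_spine(model, site, geom)
    events = [SynapticEvent(comp=head, kinetics=kin, onset=onset)]
    events += [SynapticEvent(comp=head, kinetics=k, onset=onset) for k in extra_kinetics]
    rec = [head, site, spiny.soma_index]
    traces = simulate(spiny, events, dt=dt, duration=duration, record=rec)
    rest = spiny.params.e_rest
    peak = {k: float(tr.v.max() - rest) for k, tr in traces.items()}
    head_p, base_p, soma_p = peak[head], peak[site], peak[spiny.soma_index]
    return {
        "epsp_head": head_p,
        "epsp_base": base_p,
        "epsp_soma": soma_p,
        "head_to_base": head_p / base_p if base_p > 0 else np.inf,
        "head_to_soma": head_p / soma_p if soma_p > 0 else np.inf,
        "traces": {"head": traces[head], "base": traces[site],
                   "soma": traces[spiny.soma_index]},
    }
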