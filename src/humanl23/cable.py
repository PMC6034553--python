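"""Passive compartmental cable models.

A :class:`Morphology` is discretized into cylindrical compartments that are
integrated with an unconditionally stable backward-Euler scheme solved by a
single-pass tree-ordered (Hines) elimination per time step.  Spine membrane
is folded into distal dendrites through the F_spines area factor: C_m is
multiplied and R_m divided by the same factor, so the local membrane time
constant is untouched.

Units (fixed convention across the package):
  mV, ms, nA, μm, μm², MΩ, μS, nF; specific constants in μF/cm², Ω·cm²,
  Ω·cm.  All conversions happen here at model-building time.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .morphology import Morphology, SOMA, DENDRITE_TYPES

# comp_type codes beyond the SWC ones
SPINE_NECK, SPINE_HEAD = 5, 6

# unit-conversion factors
_G_PAS = 1e-2   # μS per (μm² / Ω·cm²)
_CM = 1e-5      # nF per (μm² · μF/cm²)
_R_AX = 1e-2    # MΩ per (Ω·cm · μm / μm²)


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane and cytoplasm parameters.

    Defaults are the human L2/L3 values: a distinctively low specific
    capacitance of 0.5 μF/cm², R_m fitted per cell (order 10⁴ Ω·cm²),
    axial resistivity 200 Ω·cm and resting potential −86 mV.  F_spines
    folds total spine membrane into dendrites at least ``spine_min_dist``
    μm from the soma.
    """

    c_m: float = 0.5          # μF/cm²
    r_m: float = 15000.0      # Ω·cm²
    r_a: float = 200.0        # Ω·cm
    e_rest: float = -86.0     # mV
    f_spines: float = 1.9
    spine_min_dist: float = 60.0  # μm

    def __post_init__(self) -> None:
        if self.c_m <= 0 or self.r_m <= 0 or self.r_a <= 0:
            raise ValueError("C_m, R_m and R_a must be positive")
        if self.f_spines < 1:
            raise ValueError("F_spines must be >= 1")
        if self.spine_min_dist < 0:
            raise ValueError("spine_min_dist must be >= 0")


@dataclass
class Trace:
    """A uniformly sampled time series at one recording site."""

    t: np.ndarray        # ms
    v: np.ndarray        # mV (or nA for current traces)
    site: int = 0        # compartment index

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("time base and values differ in length")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time base must be uniform and increasing")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("non-finite trace values")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0

    def to_csv(self, path) -> None:
        header = f"site={self.site}\nt_ms,V_mV"
        np.savetxt(path, np.column_stack([self.t, self.v]), delimiter=",",
                   header=header, comments="# ")

    @classmethod
    def from_csv(cls, path) -> "Trace":
        site = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "site=" in line:
                    site = int(line.split("site=")[1].strip())
                if not line.startswith("#"):
                    break
        data = np.loadtxt(path, delimiter=",", comments="#")
        return cls(t=data[:, 0], v=data[:, 1], site=site)


class SimulationError(RuntimeError):
    pass


@dataclass
class CompartmentalModel:
    """Discretized neuron: arrays indexed by compartment, parents first.

    ``parent[i] < i`` for every non-root compartment, which admits the
    single-sweep tree elimination used by the integrator.
    """

    parent: np.ndarray        # int64, parent[0] == -1
    g_axial: np.ndarray       # μS conductance to parent (0 at root)
    area: np.ndarray          # μm²
    cm: np.ndarray            # nF
    g_pas: np.ndarray         # μS
    e_pas: np.ndarray         # mV
    comp_type: np.ndarray     # int8 SWC-style codes (5/6 = spine neck/head)
    path_dist: np.ndarray     # μm from soma center
    seg_len: np.ndarray       # μm arc length of the compartment
    sec_of: np.ndarray        # morphology section id per compartment
    sections: dict[int, tuple[int, int]] = field(default_factory=dict)
    params: PassiveParams = field(default_factory=PassiveParams)
    active: object | None = None   # ActiveMechanisms, set by active.attach_active
    spine_corrected: bool = False

    @property
    def n(self) -> int:
        return int(self.parent.size)

    @property
    def soma_index(self) -> int:
        return 0

    def dendritic_mask(self) -> np.ndarray:
        return np.isin(self.comp_type, DENDRITE_TYPES)

    def children_count(self) -> np.ndarray:
        cnt = np.zeros(self.n, dtype=np.int64)
        for p in self.parent[1:]:
            cnt[p] += 1
        return cnt

    def terminal_compartments(self) -> np.ndarray:
        """Most distal compartment of each dendritic terminal branch."""
        cnt = self.children_count()
        mask = (cnt == 0) & self.dendritic_mask()
        return np.flatnonzero(mask)

    def electrotonic_distance(self) -> np.ndarray:
        """Path distance from soma in DC space constants λ = √(R_m·d / 4R_a)."""
        g = self.g_pas.copy()
        # effective R_m (Ω·cm²) per compartment from its leak conductance
        with np.errstate(divide="ignore"):
            rm_eff = self.area * _G_PAS / g
        diam = self.area / (np.pi * np.maximum(self.seg_len, 1e-9))  # μm
        lam = 100.0 * np.sqrt(rm_eff * diam / (4.0 * self.params.r_a))  # μm
        out = np.zeros(self.n)
        for i in range(1, self.n):
            out[i] = out[self.parent[i]] + self.seg_len[i] / max(lam[i], 1e-9)
        return out

    def copy(self) -> "CompartmentalModel":
        return _copy.deepcopy(self)

    def lca(self, i: int, j: int) -> int:
        """Lowest common ancestor compartment of i and j."""
        anc = set()
        a = i
        while a != -1:
            anc.add(a)
            a = int(self.parent[a]) if a != 0 else -1
        b = j
        while b not in anc:
            b = int(self.parent[b])
        return int(b)


def _lambda_f(diam: float, params: PassiveParams, freq: float = 100.0) -> float:
    """AC length constant (μm) at ``freq`` Hz for a cylinder of ``diam`` μm."""
    return 1e5 * np.sqrt(diam / (4.0 * np.pi * freq * params.r_a * params.c_m))


def build_compartmental_model(
    morph: Morphology,
    params: PassiveParams | None = None,
    d_lambda: float = 0.02,
    freq: float = 100.0,
    max_nseg: int = 400,
) -> CompartmentalModel:
    """Discretize a morphology.

    Each section is split into ``nseg`` equal-arc-length compartments so
    that no compartment exceeds ``d_lambda`` AC space constants at ``freq``
    Hz (minimum one per section).  The soma becomes a single isopotential
    compartment whose area equals the equivalent sphere; neurites attach at
    the soma center through their own half-segment axial resistance.
    """
    params = params or PassiveParams()
    parent_l, g_ax_l, area_l, ctype_l, pdist_l, slen_l, secof_l = (
        [], [], [], [], [], [], [])
    sections: dict[int, tuple[int, int]] = {}

    root = morph.root
    soma_d = float(root.points[0, 3])
    soma_area = np.pi * soma_d**2  # sphere
    parent_l.append(-1)
    g_ax_l.append(0.0)
    area_l.append(soma_area)
    ctype_l.append(SOMA)
    pdist_l.append(0.0)
    slen_l.append(soma_d)
    secof_l.append(root.id)
    sections[root.id] = (0, 1)

    # bookkeeping: distal comp index + its outward half resistance + distal path dist
    distal: dict[int, tuple[int, float, float]] = {root.id: (0, 0.0, 0.0)}

    for sec in morph.topological_order():
        if sec.parent_id is None:
            continue
        pts = sec.points
        seg_d = np.sqrt((np.diff(pts[:, :3], axis=0) ** 2).sum(axis=1))
        arc = np.concatenate([[0.0], np.cumsum(seg_d)])
        L = arc[-1]
        dmean = float(np.mean(pts[:, 3]))
        lam = _lambda_f(dmean, params, freq)
        nseg = int(min(max_nseg, max(1, np.ceil(L / (d_lambda * lam)))))
        delta = L / nseg

        def diam_at(s: float) -> float:
            return float(np.interp(s, arc, pts[:, 3]))

        p_idx, p_half_out, p_dist = distal[sec.parent_id]
        start = len(parent_l)
        for j in range(nseg):
            s0, s1 = j * delta, (j + 1) * delta
            sm = 0.5 * (s0 + s1)
            # frustum area over the span, sampled at quarter points
            ss = np.linspace(s0, s1, 5)
            dd = np.array([diam_at(s) for s in ss])
            rr = dd / 2
            dl = np.diff(ss)
            slant = np.sqrt(dl**2 + np.diff(rr) ** 2)
            a = float(np.pi * ((rr[:-1] + rr[1:]) * slant).sum())
            # half-segment axial resistances (MΩ)
            d_in = diam_at(0.5 * (s0 + sm))
            d_out = diam_at(0.5 * (sm + s1))
            r_in = params.r_a * (delta / 2) / (np.pi * d_in**2 / 4) * _R_AX
            r_out = params.r_a * (delta / 2) / (np.pi * d_out**2 / 4) * _R_AX
            r_tot = r_in + p_half_out
            parent_l.append(p_idx)
            g_ax_l.append(1.0 / r_tot)
            area_l.append(max(a, 1e-6))
            ctype_l.append(sec.type)
            pdist_l.append(p_dist + (j + 0.5) * delta)  # compartment center
            slen_l.append(delta)
            secof_l.append(sec.id)
            p_idx = len(parent_l) - 1
            p_half_out = r_out
        distal[sec.id] = (p_idx, p_half_out, p_dist + L)
        sections[sec.id] = (start, start + nseg)

    area = np.array(area_l)
    model = CompartmentalModel(
        parent=np.array(parent_l, dtype=np.int64),
        g_axial=np.array(g_ax_l),
        area=area,
        cm=area * params.c_m * _CM,
        g_pas=area * _G_PAS / params.r_m,
        e_pas=np.full(len(parent_l), params.e_rest),
        comp_type=np.array(ctype_l, dtype=np.int8),
        path_dist=np.array(pdist_l),
        seg_len=np.array(slen_l),
        sec_of=np.array(secof_l, dtype=np.int64),
        sections=sections,
        params=params,
    )
    # per-section area consistency (0.1%) is checked in tests via frustum sums
    return model


def compute_f_spines(dendritic_area: float, total_spine_area: float) -> float:
    """Spine-area factor: (dendritic area + total spine area) / dendritic area."""
    if dendritic_area <= 0:
        raise ValueError("dendritic_area must be positive")
    if total_spine_area < 0:
        raise ValueError("total_spine_area must be >= 0")
    return (dendritic_area + total_spine_area) / dendritic_area


def apply_spine_correction(
    model: CompartmentalModel, params: PassiveParams | None = None
) -> CompartmentalModel:
    """Fold spine membrane into distal dendrites (returns a corrected copy).

    Every dendritic compartment whose path distance from the soma center is
    at least ``spine_min_dist`` gets C_m·F_spines and R_m/F_spines; soma,
    axon and proximal dendrites are untouched.  The R_m·C_m product — the
    membrane time constant — is conserved compartment by compartment.
    """
    params = params or model.params
    if np.any(model.path_dist < 0):
        raise RuntimeError("negative path distance")
    out = model.copy()
    mask = out.dendritic_mask() & (out.path_dist >= params.spine_min_dist)
    out.cm = out.cm.copy()
    out.g_pas = out.g_pas.copy()
    out.cm[mask] *= params.f_spines
    out.g_pas[mask] *= params.f_spines   # g = area/R_m, so R_m / F_spines
    out.spine_corrected = True
    return out


def _conductance_matrix(model: CompartmentalModel) -> csc_matrix:
    n = model.n
    rows, cols, vals = [], [], []
    diag = model.g_pas.copy()
    for i in range(1, n):
        p = int(model.parent[i])
        g = model.g_axial[i]
        diag[i] += g
        diag[p] += g
        rows += [i, p]
        cols += [p, i]
        vals += [-g, -g]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    return csc_matrix((vals, (rows, cols)), shape=(n, n))


def resistance_map(model: CompartmentalModel, sites=None) -> np.ndarray:
    """Steady-state transfer-resistance matrix R (MΩ) over ``sites``.

    R[i, j] is the voltage at site j per unit steady current at site i;
    the diagonal is the input resistance.  Passive models only — by
    reciprocity the matrix is symmetric.
    """
    if model.active is not None:
        raise ValueError("resistance_map requires a passive model")
    sites = np.arange(model.n) if sites is None else np.asarray(sites, dtype=int)
    lu = splu(_conductance_matrix(model))
    out = np.empty((sites.size, sites.size))
    for k, i in enumerate(sites):
        rhs = np.zeros(model.n)
        rhs[i] = 1.0  # nA
        v = lu.solve(rhs)  # mV -> MΩ per nA
        out[k, :] = v[sites]
    return out


def simulate(
    model: CompartmentalModel,
    stimuli,
    dt: float = 0.025,
    duration: float = 100.0,
    record="all",
    v_init: float | None = None,
) -> dict[int, Trace]:
    """Integrate the model and return voltage traces.

    ``stimuli`` is an iterable of :class:`~humanl23.synapses.CurrentStep`
    and :class:`~humanl23.synapses.SynapticEvent`.  Backward-Euler with a
    Hines tree solve per step; voltage-dependent (NMDA) synapse block
    factors are evaluated at the previous step's voltage (semi-implicit).
    With no stimulus every compartment stays at its resting potential.
    """
    from . import synapses as _syn
    from . import _kernels

    if dt <= 0:
        raise ValueError("dt must be positive")
    nsteps = int(round(duration / dt))
    n = model.n

    stim_c, stim_a, stim_t0, stim_t1 = [], [], [], []
    syn_c, syn_g, syn_tr, syn_td, syn_on, syn_e = [], [], [], [], [], []
    syn_vd, syn_gam, syn_nmg = [], [], []
    for s in stimuli:
        if isinstance(s, _syn.CurrentStep):
            if not (0 <= s.comp < n):
                raise ValueError(f"stimulus site {s.comp} out of range")
            stim_c.append(s.comp)
            stim_a.append(s.amplitude)
            stim_t0.append(s.start)
            stim_t1.append(s.end)
        elif isinstance(s, _syn.SynapticEvent):
            if not (0 <= s.comp < n):
                raise ValueError(f"synapse site {s.comp} out of range")
            k = s.kinetics
            syn_c.append(s.comp)
            syn_g.append(k.g_max * 1e-3 * _syn.normalization_factor(k))  # μS·N
            syn_tr.append(k.tau_rise)
            syn_td.append(k.tau_decay)
            syn_on.append(s.onset)
            syn_e.append(k.e_syn)
            syn_vd.append(1 if k.voltage_dependent else 0)
            syn_gam.append(k.gamma)
            syn_nmg.append(k.n * k.mg)
        else:
            raise TypeError(f"unknown stimulus type {type(s)!r}")

    v0 = float(model.params.e_rest if v_init is None else v_init)
    arrs = dict(
        parent=model.parent,
        g_ax=model.g_axial,
        cm=model.cm,
        g_pas=model.g_pas,
        e_pas=model.e_pas,
        dt=float(dt),
        nsteps=nsteps,
        stim_comp=np.array(stim_c, dtype=np.int64),
        stim_amp=np.array(stim_a, dtype=float),
        stim_t0=np.array(stim_t0, dtype=float),
        stim_t1=np.array(stim_t1, dtype=float),
        syn_comp=np.array(syn_c, dtype=np.int64),
        syn_g=np.array(syn_g, dtype=float),
        syn_taur=np.array(syn_tr, dtype=float),
        syn_taud=np.array(syn_td, dtype=float),
        syn_on=np.array(syn_on, dtype=float),
        syn_e=np.array(syn_e, dtype=float),
        syn_vdep=np.array(syn_vd, dtype=np.int8),
        syn_gamma=np.array(syn_gam, dtype=float),
        syn_nmg=np.array(syn_nmg, dtype=float),
        v0=v0,
    )

    if record == "all":
        rec_idx = np.arange(n, dtype=np.int64)
    else:
        rec_idx = np.asarray(record, dtype=np.int64)

    if model.active is None:
        vrec = _kernels.run_passive(rec_idx=rec_idx, **arrs)
    else:
        act = model.active
        vrec = _kernels.run_active(
            rec_idx=rec_idx,
            act_comp=act.comp,
            gbar=act.gbar,
            chan_erev=act.chan_erev,
            chan_is_ca=act.chan_is_ca,
            chan_ca_gated=act.chan_ca_gated,
            gate_kind=act.gate_kind,
            gate_pow=act.gate_pow,
            gate_p=act.gate_p,
            ca_gamma=act.ca_gamma,
            ca_tau=act.ca_tau,
            **arrs,
        )
    if not np.all(np.isfinite(vrec)):
        bad = np.argwhere(~np.isfinite(vrec))
        raise SimulationError(f"non-finite state at step {bad[0][1]}")
    t = np.arange(nsteps + 1) * dt
    return {int(i): Trace(t=t, v=vrec[k], site=int(i)) for k, i in enumerate(rec_idx)}
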