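"""Synthetic data generators: morphologies, spine geometries, EPSP and
spike-train targets with planted ground truth.

These stand in for the experimental inputs of the human L2/L3 study so
every pipeline stage has a self-contained, seed-reproducible test bed:

* branched human-like trees (many electrotonically elongated basal
  terminals: 44.5 ± 8.1 terminal branches) vs rat-like trees (31.4 ± 8.6,
  shorter terminals);
* spine geometry draws around the measured 2.88 ± 1.37 μm² head area,
  1.34 ± 0.50 μm neck length, 0.24 ± 0.08 μm neck diameter;
* somatic EPSPs from five-contact connections planted 140 ± 78 μm from the
  soma;
* blocked/unblocked composite EPSP pairs with known NMDA kinetics;
* supra-threshold spike trains from a known ground-truth active model,
  jittered across repeats to yield feature means ± SDs (SD floor 1e-3
  keeps SD-normalized objectives finite at low jitter).

Every generator is a pure function of its seed and ships a
:class:`GroundTruth` alongside its data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .active import (
    ActiveParams,
    DEFAULT_ACTIVE,
    FeatureTargets,
    attach_active,
)
from .cable import (
    CompartmentalModel,
    PassiveParams,
    Trace,
    build_compartmental_model,
    simulate,
)
from .features import FEATURE_NAMES, IFCurve, extract_features, normalize_if_curve
from .morphology import APICAL, BASAL, SOMA, Morphology, Section
from .synapses import (
    AMPA_DEFAULT,
    SpineGeometry,
    SynapseKinetics,
    SynapticEvent,
    CurrentStep,
    attach_spines,
)

logger = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """Planted parameters behind a synthetic dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "seed": self.seed,
                       "params": self.params}, fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _trunc_normal(rng, mean, sd, lo, size=None):
    """Normal draw re-sampled until above ``lo`` (truncated sampling)."""
    x = rng.normal(mean, sd, size=size)
    bad = x <= lo
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
        bad = x <= lo
    return x


@dataclass(frozen=True)
class TreeRecipe:
    """Gross statistics of a generated dendritic tree.

    The defaults are the human-like conditions; :data:`RAT_RECIPE` holds
    the rat-like ones.  Terminal branches are longer than inner branches by
    ``terminal_elongation`` — the distinctive cable elongation of human
    basal terminals.
    """

    n_basal_terminals_mean: float = 44.5
    n_basal_terminals_sd: float = 8.1
    inner_length_mean: float = 35.0      # μm, non-terminal branch
    inner_length_sd: float = 10.0
    terminal_length_mean: float = 90.0   # μm before elongation
    terminal_length_sd: float = 25.0
    terminal_elongation: float = 1.7     # human > rat
    trunk_diameter: float = 2.2          # μm, basal stem
    taper: float = 0.82                  # child/parent diameter ratio
    min_diameter: float = 0.55           # μm
    soma_diameter: float = 16.0          # μm
    apical_trunk_length: float = 450.0   # μm
    apical_trunk_diameter: float = 3.0
    n_obliques: int = 6
    oblique_length_mean: float = 120.0
    n_tuft_branches: int = 2
    tuft_length_mean: float = 160.0

    def __post_init__(self) -> None:
        if self.n_basal_terminals_mean < 2:
            raise ValueError("need at least 2 basal terminals on average")


HUMAN_RECIPE = TreeRecipe()
RAT_RECIPE = TreeRecipe(
    n_basal_terminals_mean=31.4,
    n_basal_terminals_sd=8.6,
    terminal_elongation=1.0,
    apical_trunk_length=300.0,
    n_obliques=4,
    oblique_length_mean=90.0,
    tuft_length_mean=120.0,
)


def _random_direction(rng, bias: np.ndarray, spread: float = 0.6) -> np.ndarray:
    v = bias + spread * rng.standard_normal(3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def generate_morphology(
    recipe: TreeRecipe = HUMAN_RECIPE, seed: int = 0
) -> Morphology:
    """Grow a random tree with the recipe's gross statistics.

    Basal topology: a drawn number of terminals is realized by repeatedly
    splitting random leaves of an initial set of stem branches (a simple
    recursive branching process — only terminal counts, elongation and
    total length matter to the downstream analyses).  An apical trunk with
    obliques and a small tuft completes the cell.  Pure function of the
    seed.
    """
    rng = np.random.default_rng(seed)
    sections: dict[int, Section] = {}
    soma = Section(
        id=1, parent_id=None, type=SOMA,
        points=np.array([[0.0, 0.0, 0.0, recipe.soma_diameter]]),
    )
    sections[1] = soma
    next_id = 2

    def add_section(parent_id, start, direction, length, d0, d1, sec_type):
        nonlocal next_id
        end = start + direction * length
        sec = Section(
            id=next_id, parent_id=parent_id, type=sec_type,
            points=np.array([[*start, d0], [*end, d1]]),
        )
        sections[next_id] = sec
        next_id += 1
        return sec

    # --- basal tree: leaf-splitting to the drawn terminal count
    n_term = max(2, int(round(_trunc_normal(rng, recipe.n_basal_terminals_mean,
                                            recipe.n_basal_terminals_sd, 2.0))))
    n_trunks = int(np.clip(round(n_term / 7), 3, n_term))
    # topology as a list of nodes: (node_id, parent_node, depth)
    topo_children: dict[int, list[int]] = {}
    node_parent = {}
    leaves = []
    for k in range(n_trunks):
        node_parent[k] = -1
        leaves.append(k)
    nid = n_trunks
    while len(leaves) < n_term:
        split = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            node_parent[nid] = split
            topo_children.setdefault(split, []).append(nid)
            leaves.append(nid)
            nid += 1

    # realize geometry depth-first
    soma_center = np.zeros(3)
    down = np.array([0.0, 0.0, -1.0])
    trunk_dirs = [
        _random_direction(rng, down + np.array(
            [np.cos(2 * np.pi * k / n_trunks),
             np.sin(2 * np.pi * k / n_trunks), 0.0]), spread=0.3)
        for k in range(n_trunks)
    ]

    def grow(node, parent_sec, start, direction, diam):
        kids = topo_children.get(node, [])
        is_term = not kids
        if is_term:
            length = float(_trunc_normal(
                rng, recipe.terminal_length_mean * recipe.terminal_elongation,
                recipe.terminal_length_sd * recipe.terminal_elongation, 15.0))
        else:
            length = float(_trunc_normal(
                rng, recipe.inner_length_mean, recipe.inner_length_sd, 8.0))
        d1 = max(recipe.min_diameter, diam * (0.8 if is_term else 1.0))
        sec = add_section(parent_sec, start, direction, length, diam, d1, BASAL)
        end = sec.points[-1, :3]
        for kid in kids:
            child_d = max(recipe.min_diameter, d1 * recipe.taper)
            grow(kid, sec.id, end,
                 _random_direction(rng, direction, spread=0.8), child_d)

    for k in range(n_trunks):
        grow(k, 1, soma_center, trunk_dirs[k], recipe.trunk_diameter)

    # --- apical trunk with obliques and a small tuft
    up = np.array([0.0, 0.0, 1.0])
    n_seg = max(recipe.n_obliques, 1)
    seg_len = recipe.apical_trunk_length / n_seg
    prev, start = 1, soma_center
    d = recipe.apical_trunk_diameter
    for k in range(n_seg):
        d_next = max(recipe.min_diameter, d * 0.93)
        sec = add_section(prev, start, _random_direction(rng, up, 0.1),
                          seg_len, d, d_next, APICAL)
        start, prev, d = sec.points[-1, :3], sec.id, d_next
        ob_len = float(_trunc_normal(
            rng, recipe.oblique_length_mean, recipe.oblique_length_mean * 0.3,
            15.0))
        ob_dir = _random_direction(
            rng, np.array([np.cos(2.4 * k), np.sin(2.4 * k), 0.3]), 0.4)
        od = max(recipe.min_diameter, d * 0.5)
        add_section(sec.id, start, ob_dir, ob_len, od,
                    max(recipe.min_diameter, od * recipe.taper), APICAL)
    for k in range(recipe.n_tuft_branches):
        tuft_len = float(_trunc_normal(
            rng, recipe.tuft_length_mean, recipe.tuft_length_mean * 0.25, 20.0))
        td = max(recipe.min_diameter, d * 0.7)
        add_section(prev, start, _random_direction(rng, up, 0.5), tuft_len,
                    td, recipe.min_diameter, APICAL)

    return Morphology(sections=sections)


@dataclass(frozen=True)
class SpineSampler:
    """Truncated-normal sampler of measured human spine geometry."""

    head_area_mean: float = 2.88   # μm²
    head_area_sd: float = 1.37
    neck_length_mean: float = 1.34  # μm
    neck_length_sd: float = 0.50
    neck_diameter_mean: float = 0.24  # μm
    neck_diameter_sd: float = 0.08

    def sample(self, n: int, seed: int = 0) -> list[SpineGeometry]:
        rng = np.random.default_rng(seed)
        ha = _trunc_normal(rng, self.head_area_mean, self.head_area_sd, 0.2, n)
        nl = _trunc_normal(rng, self.neck_length_mean, self.neck_length_sd, 0.2, n)
        nd = _trunc_normal(rng, self.neck_diameter_mean, self.neck_diameter_sd,
                           0.05, n)
        return [SpineGeometry(head_area=float(a), neck_length=float(l),
                              neck_diameter=float(c))
                for a, l, c in zip(ha, nl, nd)]


def default_study_model(
    recipe: TreeRecipe = HUMAN_RECIPE,
    params: PassiveParams | None = None,
    seed: int = 0,
    d_lambda: float = 0.02,
    spine_correction: bool = True,
) -> CompartmentalModel:
    """A ready passive model: generated tree, discretized, spine-corrected."""
    from .cable import apply_spine_correction

    params = params or PassiveParams()
    morph = generate_morphology(recipe, seed=seed)
    model = build_compartmental_model(morph, params, d_lambda=d_lambda)
    return apply_spine_correction(model, params) if spine_correction else model


def generate_pair_epsp(
    model: CompartmentalModel,
    n_contacts: int = 5,
    g_per_contact: float = 0.88,
    noise_sd: float = 0.0,
    seed: int = 0,
    distance_mean: float = 140.0,
    distance_sd: float = 78.0,
    dt: float = 0.05,
    duration: float = 100.0,
    onset: float = 5.0,
) -> tuple[Trace, GroundTruth]:
    """Somatic EPSP of a synthetic 5-contact connection, plus ground truth.

    Contact path distances are drawn from the connection territory
    (140 ± 78 μm, truncated at 0 and at the tree's extent) and snapped to
    the nearest dendritic compartment; contacts are activated
    simultaneously and Gaussian noise of ``noise_sd`` mV is added.
    """
    rng = np.random.default_rng(seed)
    dend = np.flatnonzero(model.dendritic_mask())
    dmax = float(model.path_dist[dend].max())
    sites = []
    for _ in range(n_contacts):
        target = float(_trunc_normal(rng, distance_mean, distance_sd, 0.0))
        target = min(target, dmax)
        sites.append(int(dend[np.argmin(np.abs(model.path_dist[dend] - target))]))
    kin = SynapseKinetics(g_max=g_per_contact,
                          tau_rise=AMPA_DEFAULT.tau_rise,
                          tau_decay=AMPA_DEFAULT.tau_decay)
    events = [SynapticEvent(comp=s, kinetics=kin, onset=onset) for s in sites]
    soma = model.soma_index
    tr = simulate(model, events, dt=dt, duration=duration, record=[soma])[soma]
    v = tr.v + noise_sd * rng.standard_normal(tr.v.size)
    gt = GroundTruth(kind="pair_epsp", seed=seed, params={
        "sites": sites, "g_per_contact": g_per_contact,
        "noise_sd": noise_sd, "onset": onset,
        "tau_rise": kin.tau_rise, "tau_decay": kin.tau_decay,
    })
    return Trace(t=tr.t, v=v, site=soma), gt


@dataclass(frozen=True)
class NMDAKinetics:
    """Planted NMDA/AMPA parameters for target generation."""

    tau_rise: float = 8.02
    tau_decay: float = 34.99
    gamma: float = 0.0771
    g_nmda: float = 1.31
    g_ampa: float = 0.73
    g_ampa_blocked: float = 0.13


def generate_nmda_targets(
    model: CompartmentalModel,
    region: np.ndarray,
    true_kinetics: NMDAKinetics = NMDAKinetics(),
    n_syn: int | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    dt: float = 0.05,
    duration: float = 150.0,
    onset: float = 5.0,
) -> tuple[Trace, Trace, GroundTruth]:
    """Blocked / unblocked composite somatic EPSP pair with known kinetics.

    15–30 spinous synapses (each with NMDA plus AMPA conductances) are
    placed in ``region``; the blocked trace uses the residual AMPA
    conductance (≤ g_AMPA/5), the unblocked trace the full one.
    """
    region = np.asarray(region, dtype=int)
    if region.size == 0:
        raise ValueError("empty region")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(15, 31)) if n_syn is None else int(n_syn)
    sites = rng.choice(region, size=n, replace=region.size < n)
    spiny, heads = attach_spines(model, sites)
    soma = model.soma_index
    tk = true_kinetics
    nmda = SynapseKinetics(g_max=tk.g_nmda, tau_rise=tk.tau_rise,
                           tau_decay=tk.tau_decay, voltage_dependent=True,
                           gamma=tk.gamma)

    def compose(g_ampa: float) -> Trace:
        events = [SynapticEvent(comp=h, kinetics=nmda, onset=onset)
                  for h in heads]
        if g_ampa > 0:
            ampa = SynapseKinetics(g_max=g_ampa,
                                   tau_rise=AMPA_DEFAULT.tau_rise,
                                   tau_decay=AMPA_DEFAULT.tau_decay)
            events += [SynapticEvent(comp=h, kinetics=ampa, onset=onset)
                       for h in heads]
        tr = simulate(spiny, events, dt=dt, duration=duration,
                      record=[soma])[soma]
        v = tr.v + noise_sd * rng.standard_normal(tr.v.size)
        return Trace(t=tr.t, v=v, site=soma)

    blocked = compose(tk.g_ampa_blocked)
    unblocked = compose(tk.g_ampa)
    gt = GroundTruth(kind="nmda_targets", seed=seed, params={
        "sites": [int(s) for s in sites], "n_synapses": n,
        "noise_sd": noise_sd, "onset": onset, **asdict(tk),
    })
    return blocked, unblocked, gt


def titrate_current(
    active_model: CompartmentalModel,
    target_hz: float = 10.0,
    stim_on: float = 100.0,
    stim_dur: float = 1000.0,
    dt: float = 0.025,
    lo: float = 0.05,
    hi: float = 4.0,
    iters: int = 12,
) -> float:
    """Bisect the step amplitude (nA) to the target mean rate."""
    from .features import find_spikes

    def rate(amp: float) -> float:
        tr = simulate(active_model,
                      [CurrentStep(comp=0, amplitude=amp, start=stim_on,
                                   end=stim_on + stim_dur)],
                      dt=dt, duration=stim_on + stim_dur + 100.0,
                      record=[0])[0]
        pt, _ = find_spikes(tr)
        pt = pt[(pt >= stim_on) & (pt <= stim_on + stim_dur)]
        return pt.size / stim_dur * 1e3

    if rate(hi) < target_hz:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target_hz:
            lo = mid
        else:
            hi = mid
    return hi


def reference_if_curve(
    active_model: CompartmentalModel,
    i_10hz: float | None = None,
    fractions=(0.6, 0.8, 1.0, 1.3, 1.7, 2.2, 3.0),
    stim_on: float = 100.0,
    stim_dur: float = 1000.0,
    dt: float = 0.025,
) -> IFCurve:
    """Measure and normalize the model's own I-F curve."""
    from .features import find_spikes

    amp10 = i_10hz or titrate_current(active_model, 10.0, stim_on, stim_dur, dt)
    pts = []
    for f in fractions:
        amp = amp10 * f
        tr = simulate(active_model,
                      [CurrentStep(comp=0, amplitude=amp, start=stim_on,
                                   end=stim_on + stim_dur)],
                      dt=dt, duration=stim_on + stim_dur + 100.0,
                      record=[0])[0]
        pt, _ = find_spikes(tr)
        pt = pt[(pt >= stim_on) & (pt <= stim_on + stim_dur)]
        pts.append((amp, pt.size / stim_dur * 1e3))
    return normalize_if_curve(pts)


def generate_spike_train_targets(
    model: CompartmentalModel,
    params: ActiveParams = DEFAULT_ACTIVE,
    current: float | None = None,
    repeats: int = 10,
    param_jitter: float = 0.15,
    current_jitter: float = 0.05,
    if_population: int = 25,
    if_population_jitter: float = 0.18,
    seed: int = 0,
    stim_on: float = 100.0,
    stim_dur: float = 1000.0,
    dt: float = 0.025,
    sd_floor: float = 1e-3,
    if_reference: IFCurve | None = None,
):
    """Spike-train feature targets from a known ground-truth active model.

    The passive ``model`` (with axon stub) gets the ground-truth channel
    densities; the step current is titrated to ~10 Hz unless given.  Each
    repeat jitters the densities multiplicatively, the leak reversal
    additively and the stimulus amplitude by ``current_jitter``, emulating
    the trial-to-trial variability of repeated recordings.  The five
    normalized-I-F features take their mean from the reference curve and
    their SD from an emulated ``if_population`` of cells whose rates
    scatter by ``if_population_jitter`` around it (the experimental I-F
    spread comes from a separate cell population, not from repeats).
    Feature means ± SDs (with an SD floor) become the fit objectives.
    Returns (targets, stim, if_reference, traces, ground_truth).
    """
    rng = np.random.default_rng(seed)
    gt_model = attach_active(model, params)
    if current is None:
        current = titrate_current(gt_model, 10.0, stim_on, stim_dur, dt)
    if if_reference is None:
        if_reference = reference_if_curve(gt_model, current, stim_on=stim_on,
                                          stim_dur=stim_dur, dt=dt)
    stim = CurrentStep(comp=0, amplitude=current, start=stim_on,
                       end=stim_on + stim_dur)
    duration = stim_on + stim_dur + 100.0

    x0 = params.to_vector()
    rows, traces = [], []
    attempts = 0
    while len(rows) < repeats:
        attempts += 1
        if attempts > 6 * repeats:
            raise RuntimeError("could not generate enough spiking repeats")
        x = x0.copy()
        jit = rng.normal(0.0, param_jitter, size=x.size)
        x[:-1] = x[:-1] * (1.0 + jit[:-1])
        x[-1] = x[-1] + rng.normal(0.0, param_jitter * 15.0)
        amp = current * (1.0 + rng.normal(0.0, current_jitter))
        rep_stim = CurrentStep(comp=0, amplitude=amp, start=stim_on,
                               end=stim_on + stim_dur)
        m = attach_active(model, ActiveParams.from_vector(x))
        tr = simulate(m, [rep_stim], dt=dt, duration=duration, record=[0])[0]
        feats = extract_features(tr, stim.start, stim.end, if_reference)
        arr = feats.as_array()
        if not np.all(np.isfinite(arr)):
            logger.info("repeat without enough spikes; regenerating")
            continue
        rows.append(arr)
        traces.append(tr)
    rows = np.array(rows)
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1)

    # I-F features: the means stay the per-repeat averages (the same
    # reference-curve map the fit applies to its candidates); the SDs come
    # from an emulated cell population whose rates scatter multiplicatively
    # around the reference curve — the experimental spread across cells.
    if_idx = [FEATURE_NAMES.index(n) for n in
              ("if_rate_75", "if_rate_125", "if_rate_150",
               "if_rate_200", "if_rate_300")]
    base = mean[if_idx]
    pop = np.empty((if_population, len(if_idx)))
    for c in range(if_population):
        scale = 1.0 + rng.normal(0.0, if_population_jitter)
        wobble = 1.0 + rng.normal(0.0, if_population_jitter / 2,
                                  size=len(if_idx))
        pop[c] = np.maximum(base * scale * wobble, 0.0)
    sd[if_idx] = np.maximum(sd[if_idx], pop.std(axis=0, ddof=1))

    targets = FeatureTargets(mean=mean, sd=np.maximum(sd, sd_floor))
    gt = GroundTruth(kind="spike_train_targets", seed=seed, params={
        "active_params": x0.tolist(),
        "current_nA": current,
        "param_jitter": param_jitter,
        "current_jitter": current_jitter,
        "repeats": repeats,
        "stim_on": stim_on,
        "stim_dur": stim_dur,
    })
    return targets, stim, if_reference, traces, gt
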