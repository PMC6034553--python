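"""Number of simultaneously activated spinous synapses per somatic spike.

AMPA+NMDA synapses on individual spines are placed either *distributed*
(uniformly over dendritic length) or *clustered* (anchors uniform over
dendritic length, 20 synapses per cluster within a 20 μm stretch of one
branch).  All synapses fire at a common onset; a trial counts as a somatic
spike when the somatic voltage crosses 0 mV.  The 50% threshold N_50 is
read off the probability-vs-count curve by linear interpolation (linear
extrapolation, flagged, when 0.5 is not bracketed — the clustered curves
are shallow and may not reach 0.5 inside the swept range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cable import CompartmentalModel, simulate
from .nmda_spikes import cluster_positions
from .synapses import (
    AMPA_DEFAULT,
    NMDA_DEFAULT,
    PROTOTYPICAL_SPINE,
    SpineGeometry,
    SynapseKinetics,
    SynapticEvent,
    attach_spines,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlacementSpec:
    """How to place a given total number of spinous synapses."""

    mode: str                    # "distributed" | "clustered"
    n_synapses: int
    cluster_size: int = 20
    cluster_span: float = 20.0   # μm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("distributed", "clustered"):
            raise ValueError("mode must be 'distributed' or 'clustered'")
        if self.n_synapses < 0 or self.cluster_size < 1:
            raise ValueError("counts must be non-negative")


def place_synapses(model: CompartmentalModel, spec: PlacementSpec) -> np.ndarray:
    """Draw spine-anchor compartments for ``spec`` (one synapse per spine).

    Distributed mode samples compartments with probability proportional to
    their dendritic length.  Clustered mode samples cluster anchors the
    same way, then places ``cluster_size`` synapses within
    ``cluster_span`` μm of the anchor on the same branch; a trailing
    partial cluster is dropped.
    """
    rng = np.random.default_rng(spec.seed)
    dend = np.flatnonzero(model.dendritic_mask())
    if dend.size == 0:
        raise ValueError("model has no dendrites")
    w = model.seg_len[dend]
    w = w / w.sum()
    if spec.mode == "distributed":
        return rng.choice(dend, size=spec.n_synapses, replace=True, p=w)
    n_clusters = spec.n_synapses // spec.cluster_size
    if spec.n_synapses % spec.cluster_size:
        logger.info(
            "clustered placement: dropping partial cluster of %d synapses",
            spec.n_synapses % spec.cluster_size,
        )
    sites = []
    for _ in range(n_clusters):
        anchor = int(rng.choice(dend, p=w))
        sites.append(cluster_positions(
            model, anchor, spec.cluster_span, spec.cluster_size, rng))
    return np.concatenate(sites) if sites else np.array([], dtype=int)


@dataclass
class ProbabilityCurve:
    """Somatic-spike probability as a function of synapse count."""

    counts: np.ndarray
    probability: np.ndarray
    n_trials: int
    mode: str = "distributed"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.probability = np.asarray(self.probability, dtype=float)
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.counts, self.probability,
                             np.full(self.counts.size, self.n_trials)]),
            delimiter=",", header="n_synapses,probability,trials",
            comments="", fmt=("%d", "%.6f", "%d"),
        )


@dataclass(frozen=True)
class ThresholdEstimate:
    n_50: float
    extrapolated: bool
    defined: bool = True


def spike_probability_curve(
    active_model: CompartmentalModel,
    counts,
    mode: str = "distributed",
    trials: int = 1000,
    spike_threshold_mv: float = 0.0,
    seed: int = 0,
    cluster_size: int = 20,
    cluster_span: float = 20.0,
    ampa: SynapseKinetics = AMPA_DEFAULT,
    nmda: SynapseKinetics = NMDA_DEFAULT,
    geom: SpineGeometry = PROTOTYPICAL_SPINE,
    dt: float = 0.05,
    duration: float = 300.0,
    onset: float = 5.0,
) -> ProbabilityCurve:
    """Monte-Carlo spike probability per synapse count.

    Trial seeds derive deterministically from (master seed, count, trial),
    so the whole curve is reproducible from ``seed``.  The model must carry
    active soma/axon mechanisms.
    """
    if active_model.active is None:
        raise ValueError("spike_probability_curve needs an active model")
    counts = np.asarray(counts, dtype=int)
    soma = active_model.soma_index
    probs = np.empty(counts.size)
    for ci, n in enumerate(counts):
        hits = 0
        for trial in range(trials):
            trial_seed = int(
                np.random.SeedSequence([seed, int(n), trial]).generate_state(1)[0]
                % (2**31 - 1)
            )
            spec = PlacementSpec(mode=mode, n_synapses=int(n),
                                 cluster_size=cluster_size,
                                 cluster_span=cluster_span, seed=trial_seed)
            sites = place_synapses(active_model, spec)
            if sites.size == 0:
                continue
            spiny, heads = attach_spines(active_model, sites, geom)
            events = []
            for h in heads:
                events.append(SynapticEvent(comp=h, kinetics=ampa, onset=onset))
                events.append(SynapticEvent(comp=h, kinetics=nmda, onset=onset))
            tr = simulate(spiny, events, dt=dt, duration=duration,
                          record=[soma])[soma]
            if tr.v.max() >= spike_threshold_mv:
                hits += 1
        probs[ci] = hits / trials
    return ProbabilityCurve(counts=counts, probability=probs,
                            n_trials=trials, mode=mode)


def threshold_at_half(curve: ProbabilityCurve) -> ThresholdEstimate:
    """N_50: synapse count at 50% spike probability.

    Linear interpolation between the bracketing points of the first upward
    crossing; linear extrapolation from the nearest rising segment when 0.5
    is not bracketed (flagged).  A flat curve leaves the threshold
    undefined.
    """
    n, p = curve.counts.astype(float), curve.probability
    if n.size < 2:
        raise ValueError("curve needs at least 2 points")
    for i in range(n.size - 1):
        lo, hi = p[i], p[i + 1]
        if lo < 0.5 <= hi:
            f = (0.5 - lo) / (hi - lo)
            return ThresholdEstimate(n_50=float(n[i] + f * (n[i + 1] - n[i])),
                                     extrapolated=False)
    # not bracketed: extrapolate from the last segment with positive slope
    rising = [i for i in range(n.size - 1) if p[i + 1] > p[i]]
    if not rising:
        return ThresholdEstimate(n_50=float("nan"), extrapolated=True,
                                 defined=False)
    i = rising[-1]
    slope = (p[i + 1] - p[i]) / (n[i + 1] - n[i])
    return ThresholdEstimate(
        n_50=float(n[i] + (0.5 - p[i]) / slope), extrapolated=True)
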