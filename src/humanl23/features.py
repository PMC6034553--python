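"""Spike-train feature extraction and I-F curve handling.

Seventeen features characterize a somatic response to a depolarizing step:
twelve trace-derived features (baseline and steady-state voltage, rate and
ISI statistics, spike shape) and five read from a normalized I-F reference
curve at 75/125/150/200/300% of the normalized input matching the trace's
mean rate.  Spikes are bookkept by their peaks above 0 mV; the spike onset
("AP begin") is where dV/dt first crosses 20 mV/ms before the peak.

The ISI coefficient of variation is computed as ISI_mean/ISI_SD (the
convention used for the target data this package emulates); the reciprocal
convention is available via ``isi_cv_convention="sd_over_mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .cable import Trace

SPIKE_PEAK_THRESHOLD = 0.0     # mV
AP_BEGIN_DVDT = 20.0           # mV/ms
IF_FRACTIONS = (0.75, 1.25, 1.5, 2.0, 3.0)

FEATURE_NAMES = (
    "voltage_base",
    "steady_state_voltage",
    "mean_frequency",
    "time_to_first_spike",
    "burst_isi",
    "isi_cv",
    "adaptation_index",
    "ap_height",
    "ap_begin_voltage",
    "ahp_depth",
    "ahp_time_from_peak",
    "spike_half_width",
    "if_rate_75",
    "if_rate_125",
    "if_rate_150",
    "if_rate_200",
    "if_rate_300",
)


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeTrainFeatures:
    """The 17 spike-train features; undefined entries are NaN, never
    fabricated (ISI statistics require at least two spikes)."""

    voltage_base: float
    steady_state_voltage: float
    mean_frequency: float
    time_to_first_spike: float
    burst_isi: float
    isi_cv: float
    adaptation_index: float
    ap_height: float
    ap_begin_voltage: float
    ahp_depth: float
    ahp_time_from_peak: float
    spike_half_width: float
    if_rate_75: float
    if_rate_125: float
    if_rate_150: float
    if_rate_200: float
    if_rate_300: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


@dataclass
class IFCurve:
    """Firing rate vs injected current, piecewise-linear between points.

    ``normalize`` rescales the abscissa by the current producing 10 Hz
    (linear interpolation), so 1.0 on a normalized curve is the 10-Hz
    input.
    """

    currents: np.ndarray     # pA (or normalized units)
    rates: np.ndarray        # Hz
    normalized: bool = False
    i_10hz: float | None = None

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.currents.size != self.rates.size or self.currents.size < 2:
            raise ValueError("need >= 2 (current, rate) pairs")
        order = np.argsort(self.currents)
        self.currents = self.currents[order]
        self.rates = self.rates[order]
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    def rate_at(self, current) -> np.ndarray | float:
        """Rate at ``current``; linear extrapolation beyond the end points."""
        return _interp_extrap(current, self.currents, self.rates)

    def current_at(self, rate: float) -> float:
        """Inverse lookup (requires non-decreasing rates)."""
        if np.any(np.diff(self.rates) < 0):
            # use the first crossing on a non-monotone curve
            above = self.rates >= rate
            if above.any() and not above[0]:
                i = int(np.argmax(above))
                f = (rate - self.rates[i - 1]) / (self.rates[i] - self.rates[i - 1])
                return float(self.currents[i - 1]
                             + f * (self.currents[i] - self.currents[i - 1]))
        return float(_interp_extrap(rate, self.rates, self.currents))


def _interp_extrap(x, xp, fp):
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if np.any(lo):
        s = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(lo, fp[0] + s * (x - xp[0]), y)
    if np.any(hi):
        s = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, fp[-1] + s * (x - xp[-1]), y)
    return y if y.ndim else float(y)


def normalize_if_curve(points) -> IFCurve:
    """Normalize an I-F curve by the input current that leads to 10 Hz.

    ``points``: iterable of (current, rate).  Raises when 10 Hz is outside
    the measured rate range.
    """
    pts = np.asarray(points, dtype=float)
    curve = IFCurve(currents=pts[:, 0], rates=pts[:, 1])
    if not (curve.rates.min() <= 10.0 <= curve.rates.max()):
        raise ValueError("10 Hz outside the measured rate range")
    i10 = curve.current_at(10.0)
    if i10 <= 0:
        raise ValueError("non-positive 10-Hz current")
    return IFCurve(currents=curve.currents / i10, rates=curve.rates,
                   normalized=True, i_10hz=i10)


def find_spikes(trace: Trace, threshold: float = SPIKE_PEAK_THRESHOLD):
    """Spike peak times and indices: maxima between upward and downward
    crossings of ``threshold``."""
    v, t = trace.v, trace.t
    above = v >= threshold
    d = np.diff(above.astype(np.int8))
    ups = np.flatnonzero(d == 1) + 1
    downs = np.flatnonzero(d == -1) + 1
    peaks = []
    for u in ups:
        later = downs[downs > u]
        end = later[0] if later.size else len(v)
        peaks.append(u + int(np.argmax(v[u:end])))
    return t[peaks], np.asarray(peaks, dtype=int)


def _ap_begin(trace: Trace, peak_idx: int) -> tuple[float, float]:
    """(voltage, time) where dV/dt crosses ``AP_BEGIN_DVDT`` on the upstroke.

    Walks back from the peak: first over the near-peak region where dV/dt
    has already dropped below the criterion, then down the upstroke to the
    crossing.
    """
    v, t = trace.v, trace.t
    dt = trace.dt
    dvdt = np.gradient(v, dt)
    i = peak_idx
    while i > 0 and dvdt[i] <= AP_BEGIN_DVDT:
        i -= 1
    while i > 0 and dvdt[i] > AP_BEGIN_DVDT:
        i -= 1
    if i == 0 and dvdt[i] > AP_BEGIN_DVDT:
        return float(v[0]), float(t[0])
    # linear interpolation of the crossing between samples i and i+1
    f = (AP_BEGIN_DVDT - dvdt[i]) / (dvdt[i + 1] - dvdt[i]) if dvdt[i + 1] != dvdt[i] else 0.0
    f = min(max(f, 0.0), 1.0)
    return float(v[i] + f * (v[i + 1] - v[i])), float(t[i] + f * dt)


def _half_width(trace: Trace, peak_idx: int, begin_v: float) -> float:
    """Width (ms) at half height between AP-begin voltage and the peak."""
    v, t = trace.v, trace.t
    half = 0.5 * (begin_v + v[peak_idx])
    i = peak_idx
    while i > 0 and v[i] > half:
        i -= 1
    f = (half - v[i]) / (v[i + 1] - v[i]) if v[i + 1] != v[i] else 0.0
    t_up = t[i] + f * (t[i + 1] - t[i])
    j = peak_idx
    while j < len(v) - 1 and v[j] > half:
        j += 1
    f = (half - v[j - 1]) / (v[j] - v[j - 1]) if v[j] != v[j - 1] else 0.0
    t_dn = t[j - 1] + f * (t[j] - t[j - 1])
    return float(t_dn - t_up)


def extract_features(
    trace: Trace,
    stim_on: float,
    stim_off: float,
    if_reference: IFCurve | None = None,
    isi_cv_convention: str = "mean_over_sd",
) -> SpikeTrainFeatures:
    """Extract the 17 spike-train features from a step response.

    ``if_reference`` must be a normalized I-F curve; when omitted the five
    I-F features are NaN.  Features that need at least two spikes are NaN
    when undefined.
    """
    t, v = trace.t, trace.v
    if t[0] > stim_on or t[-1] < stim_off:
        raise FeatureError("trace does not cover the stimulus window")
    nan = float("nan")
    pre = t < stim_on
    voltage_base = float(v[pre].mean()) if pre.any() else nan
    ss_mask = (t >= stim_off - 0.1 * (stim_off - stim_on)) & (t <= stim_off)
    steady_state = float(v[ss_mask].mean())

    peak_t, peak_i = find_spikes(trace)
    in_stim = (peak_t >= stim_on) & (peak_t <= stim_off)
    peak_t, peak_i = peak_t[in_stim], peak_i[in_stim]
    nsp = peak_t.size
    mean_freq = nsp / (stim_off - stim_on) * 1e3

    tfs = float(peak_t[0] - stim_on) if nsp >= 1 else nan
    if nsp >= 2:
        isi = np.diff(peak_t)
        burst_isi = float(isi[0])
        sd = isi.std(ddof=1) if nsp >= 3 else nan
        if isi_cv_convention == "mean_over_sd":
            isi_cv = float(isi.mean() / sd) if sd and sd > 0 else nan
        elif isi_cv_convention == "sd_over_mean":
            isi_cv = float(sd / isi.mean()) if sd == sd else nan
        else:
            raise ValueError("unknown ISI CV convention")
        if nsp >= 3:
            adaptation = float(np.mean((isi[1:] - isi[:-1]) / (isi[1:] + isi[:-1])))
        else:
            adaptation = nan
    else:
        burst_isi = isi_cv = adaptation = nan

    if nsp >= 1:
        ap_height = float(v[peak_i].mean())
        begins = [_ap_begin(trace, int(i)) for i in peak_i]
        ap_begin = float(np.mean([b[0] for b in begins]))
        half_w = float(np.mean([
            _half_width(trace, int(i), b[0]) for i, b in zip(peak_i, begins)
        ]))
    else:
        ap_height = ap_begin = half_w = nan

    if nsp >= 2:
        depths, lags = [], []
        for a, b in zip(peak_i[:-1], peak_i[1:]):
            seg = v[a:b]
            k = int(np.argmin(seg))
            depths.append(float(seg[k]))
            lags.append(float(t[a + k] - t[a]))
        ahp_depth = float(np.mean(depths))
        ahp_lag = float(np.mean(lags))
    else:
        ahp_depth = ahp_lag = nan

    if if_reference is not None and nsp >= 1:
        if not if_reference.normalized:
            raise FeatureError("if_reference must be a normalized I-F curve")
        u = if_reference.current_at(mean_freq)
        if_feats = [float(if_reference.rate_at(u * f)) for f in IF_FRACTIONS]
    else:
        if_feats = [nan] * 5

    return SpikeTrainFeatures(
        voltage_base=voltage_base,
        steady_state_voltage=steady_state,
        mean_frequency=mean_freq,
        time_to_first_spike=tfs,
        burst_isi=burst_isi,
        isi_cv=isi_cv,
        adaptation_index=adaptation,
        ap_height=ap_height,
        ap_begin_voltage=ap_begin,
        ahp_depth=ahp_depth,
        ahp_time_from_peak=ahp_lag,
        spike_half_width=half_w,
        if_rate_75=if_feats[0],
        if_rate_125=if_feats[1],
        if_rate_150=if_feats[2],
        if_rate_200=if_feats[3],
        if_rate_300=if_feats[4],
    )
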