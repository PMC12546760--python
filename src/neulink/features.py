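"""Electrophysiological summary features of a current-step response.

23 features describe one voltage trace: first- and third-spike waveform
measures (threshold, amplitude, width at half height, afterhyperpolarization
depth), spike counts in five windows of the 600 ms stimulus, amplitude- and
interval-adaptation ratios, coefficients of variation, latency, and four
subthreshold voltage moments.  A feature whose prerequisite spikes are
missing is *undefined* (NaN); a trace is *valid* only if all 23 transformed
features are defined and finite — this validity notion is what makes a
simulation "fail" downstream.

Count-like and ratio-like features are log-transformed (natural log, no
offset, so zero counts stay undefined); the average amplitude-adaptation
ratio is squashed with a logistic sigmoid instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import StimulusProtocol, VoltageTrace

__all__ = [
    "FEATURE_NAMES",
    "LOG_FEATURES",
    "SIGMOID_FEATURES",
    "SpikeEvent",
    "detect_spikes",
    "extract_features",
    "extract_features_batch",
    "transform_features",
    "valid_mask",
    "FeatureStandardizer",
    "feature_distance",
]

FEATURE_NAMES = (
    "ap_threshold",
    "ap_amplitude",
    "ap_width",
    "ahp",
    "ap3_threshold",
    "ap3_amplitude",
    "ap3_width",
    "ahp3",
    "ap_count",
    "ap_count_1st_8th",
    "ap_count_1st_quarter",
    "ap_count_1st_half",
    "ap_count_2nd_half",
    "ap_amp_adapt",
    "ap_avg_amp_adapt",
    "ap_cv",
    "isi_adapt",
    "isi_cv",
    "latency",
    "rest_vm_mean",
    "vm_mean",
    "vm_sd",
    "vm_skewness",
)

#: features that get a natural-log transform (zero/negative -> undefined)
LOG_FEATURES = (
    "ap_count",
    "ap_count_1st_8th",
    "ap_count_1st_quarter",
    "ap_count_1st_half",
    "ap_count_2nd_half",
    "ap_amp_adapt",
    "ap_cv",
    "isi_adapt",
    "isi_cv",
    "latency",
)

#: features squashed with 1 / (1 + exp(-x))
SIGMOID_FEATURES = ("ap_avg_amp_adapt",)

_IDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


@dataclass
class SpikeEvent:
    """One detected action potential."""

    threshold_time: float
    threshold_vm: float
    peak_time: float
    peak_vm: float
    width_half_height: float  # NaN if the downstroke never recrosses half height
    ahp_depth: float          # threshold_vm - post-peak minimum; NaN if no window

    @property
    def amplitude(self) -> float:
        return self.peak_vm - self.threshold_vm


def detect_spikes(trace: VoltageTrace, dvdt_threshold: float = 20.0,
                  min_amplitude: float = 2.0) -> list[SpikeEvent]:
    """Detect action potentials by a dV/dt criterion.

    The threshold of a spike is the sample where dV/dt first crosses
    ``dvdt_threshold`` (mV/ms) from below; the peak is the voltage maximum
    before the next such crossing.  Candidates whose peak rises less than
    ``min_amplitude`` above threshold are discarded.  The AHP is measured as
    the drop from threshold to the minimum voltage between the peak and the
    next spike's threshold (or the end of the stimulus).
    """
    t, v = trace.t, trace.vm
    if not np.all(np.isfinite(v)):
        return []
    dt = trace.dt
    dvdt = np.diff(v) / dt
    above = dvdt >= dvdt_threshold
    onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(onsets) == 0:
        return []
    end_stim_idx = min(int(round(trace.protocol.t_off / dt)), len(v) - 1)

    events: list[SpikeEvent] = []
    bounds = list(onsets[1:]) + [len(v) - 1]
    kept: list[tuple[int, int]] = []
    for on, nxt in zip(onsets, bounds):
        seg = v[on:nxt + 1]
        pk = on + int(np.argmax(seg))
        if v[pk] - v[on] < min_amplitude:
            continue
        kept.append((on, pk))

    for j, (on, pk) in enumerate(kept):
        thr_vm, pk_vm = v[on], v[pk]
        half = thr_vm + 0.5 * (pk_vm - thr_vm)
        next_on = kept[j + 1][0] if j + 1 < len(kept) else max(end_stim_idx, pk)
        # rising half-height crossing (linear interpolation)
        rise = np.flatnonzero(v[on:pk + 1] >= half)
        t_rise = np.nan
        if len(rise):
            i = on + rise[0]
            if i == on:
                t_rise = t[i]
            else:
                f = (half - v[i - 1]) / (v[i] - v[i - 1])
                t_rise = t[i - 1] + f * dt
        # falling crossing after the peak, before the next spike
        fall = np.flatnonzero(v[pk:next_on + 1] <= half)
        t_fall = np.nan
        if len(fall):
            i = pk + fall[0]
            if i == pk:
                t_fall = t[i]
            else:
                f = (v[i - 1] - half) / (v[i - 1] - v[i])
                t_fall = t[i - 1] + f * dt
        width = t_fall - t_rise if np.isfinite(t_rise) and np.isfinite(t_fall) else np.nan

        ahp_lo = pk + 1
        ahp_hi = kept[j + 1][0] if j + 1 < len(kept) else end_stim_idx
        if ahp_hi > ahp_lo:
            ahp = thr_vm - float(np.min(v[ahp_lo:ahp_hi + 1]))
        else:
            ahp = np.nan
        events.append(SpikeEvent(threshold_time=t[on], threshold_vm=thr_vm,
                                 peak_time=t[pk], peak_vm=pk_vm,
                                 width_half_height=width, ahp_depth=ahp))
    return events


def _window_count(times, lo, hi):
    return float(np.sum((times >= lo) & (times < hi)))


def extract_features(trace: VoltageTrace, dvdt_threshold: float = 20.0) -> np.ndarray:
    """Raw 23-feature vector of a trace; undefined entries are NaN.

    Spike-derived features use spikes whose threshold time falls in the
    stimulus window [t_on, t_off); subthreshold moments use the raw samples.
    """
    prot = trace.protocol
    t, v = np.asarray(trace.t, float), np.asarray(trace.vm, float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("trace grid malformed: time and voltage must be equal-length 1-D")
    f = np.full(23, np.nan)

    rest = v[(t >= 0) & (t < prot.t_on)]
    stim = v[(t >= prot.t_on) & (t < prot.t_off)]
    if len(rest) and np.all(np.isfinite(rest)):
        f[_IDX["rest_vm_mean"]] = np.mean(rest)
    if len(stim) and np.all(np.isfinite(stim)):
        f[_IDX["vm_mean"]] = np.mean(stim)
        sd = np.std(stim)
        f[_IDX["vm_sd"]] = sd
        # skewness of a constant segment is 0/0: leave undefined
        f[_IDX["vm_skewness"]] = stats.skew(stim) if sd > 0 else np.nan

    spikes = [s for s in detect_spikes(trace, dvdt_threshold)
              if prot.t_on <= s.threshold_time < prot.t_off]
    thr_times = np.array([s.threshold_time for s in spikes])
    amps = np.array([s.amplitude for s in spikes])

    t_on, t_off = prot.t_on, prot.t_off
    span = t_off - t_on
    f[_IDX["ap_count"]] = _window_count(thr_times, t_on, t_off)
    f[_IDX["ap_count_1st_8th"]] = _window_count(thr_times, t_on, t_on + span / 8)
    f[_IDX["ap_count_1st_quarter"]] = _window_count(thr_times, t_on, t_on + span / 4)
    f[_IDX["ap_count_1st_half"]] = _window_count(thr_times, t_on, t_on + span / 2)
    f[_IDX["ap_count_2nd_half"]] = _window_count(thr_times, t_on + span / 2, t_off)

    if len(spikes) >= 1:
        s1 = spikes[0]
        f[_IDX["ap_threshold"]] = s1.threshold_vm
        f[_IDX["ap_amplitude"]] = s1.amplitude
        f[_IDX["ap_width"]] = s1.width_half_height
        f[_IDX["ahp"]] = s1.ahp_depth
        f[_IDX["latency"]] = s1.threshold_time - t_on
    if len(spikes) >= 2:
        f[_IDX["ap_amp_adapt"]] = amps[0] / amps[1]
        f[_IDX["ap_avg_amp_adapt"]] = np.mean(amps[:-1] / amps[1:])
        mean_amp = np.mean(amps)
        f[_IDX["ap_cv"]] = np.std(amps) / mean_amp if mean_amp != 0 else np.nan
    if len(spikes) >= 3:
        s3 = spikes[2]
        f[_IDX["ap3_threshold"]] = s3.threshold_vm
        f[_IDX["ap3_amplitude"]] = s3.amplitude
        f[_IDX["ap3_width"]] = s3.width_half_height
        f[_IDX["ahp3"]] = s3.ahp_depth
        isis = np.diff(thr_times)
        f[_IDX["isi_adapt"]] = isis[1] / isis[0]
        mean_isi = np.mean(isis)
        f[_IDX["isi_cv"]] = np.std(isis) / mean_isi if mean_isi != 0 else np.nan
    return f


def extract_features_batch(vm: np.ndarray, protocol: StimulusProtocol,
                           dvdt_threshold: float = 20.0) -> np.ndarray:
    """Raw feature matrix (n, 23) for a batch of traces on a shared grid."""
    t = protocol.time_grid()
    out = np.empty((vm.shape[0], 23))
    for i in range(vm.shape[0]):
        out[i] = extract_features(VoltageTrace(t=t, vm=vm[i], protocol=protocol),
                                  dvdt_threshold)
    return out


def transform_features(raw: np.ndarray) -> np.ndarray:
    """Apply the per-feature log/sigmoid transforms; works on vectors or matrices."""
    raw = np.asarray(raw, dtype=float)
    out = raw.copy()
    idx_log = [_IDX[n] for n in LOG_FEATURES]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = out[..., idx_log]
        out[..., idx_log] = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), np.nan)
        i = _IDX[SIGMOID_FEATURES[0]]
        out[..., i] = 1.0 / (1.0 + np.exp(-out[..., i]))
    return out


def valid_mask(transformed: np.ndarray) -> np.ndarray:
    """True where all 23 transformed features are defined and finite."""
    return np.all(np.isfinite(np.atleast_2d(transformed)), axis=1)


class FeatureStandardizer:
    """Z-scoring by per-feature mean and SD, fitted on valid rows only.

    sklearn-style transformer; `mean_` and `scale_` are set by :meth:`fit`.
    """

    def __init__(self):
        self.mean_ = None
        self.scale_ = None

    def fit(self, X: np.ndarray, mask: np.ndarray | None = None) -> "FeatureStandardizer":
        X = np.atleast_2d(np.asarray(X, float))
        if mask is None:
            mask = valid_mask(X)
        rows = X[np.asarray(mask, bool)]
        if rows.shape[0] < 2:
            raise ValueError("need at least 2 valid rows to fit a standardizer")
        self.mean_ = rows.mean(axis=0)
        self.scale_ = rows.std(axis=0)
        if np.any(self.scale_ == 0):
            bad = [FEATURE_NAMES[i] if len(self.scale_) == 23 else str(i)
                   for i in np.flatnonzero(self.scale_ == 0)]
            raise ValueError(f"constant feature column(s): {bad}")
        return self

    def _check(self):
        if self.mean_ is None:
            raise ValueError("standardizer is not fitted")

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(X, float) - self.mean_) / self.scale_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(Z, float) * self.scale_ + self.mean_

    def to_dict(self) -> dict:
        self._check()
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureStandardizer":
        obj = cls()
        obj.mean_ = np.asarray(d["mean"], float)
        obj.scale_ = np.asarray(d["scale"], float)
        return obj


def feature_distance(z1: np.ndarray, z2: np.ndarray) -> float:
    """Euclidean distance between two fully defined z-scored feature vectors."""
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    if not (np.all(np.isfinite(z1)) and np.all(np.isfinite(z2))):
        raise ValueError("feature_distance requires fully defined vectors")
    return float(np.linalg.norm(z1 - z2))
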