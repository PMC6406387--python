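"""Somatosensory evoked-potential (SERP) pipeline: from raw multichannel
EEG plus stimulus markers to averaged ERPs, P50 measurements and
paired-stimulus sensory-gating ratios.

Processing chain (fixed order)::

    rereference -> detrend -> bandpass -> epoch -> reject -> baseline -> average -> measure

* re-referencing: first to the mastoid mean, then to the cross-channel
  average (after which the per-sample channel mean is exactly zero);
* polynomial detrend (default linear) per channel on the continuous data;
* zero-phase Butterworth band-pass, default 10-300 Hz, 4th order
  (phase preservation matters because P50 latency is read off the peak);
* epochs of -100..+200 ms around each marker (half-open sample windows);
* peak-to-peak artifact rejection (default 100 uV, any channel);
* baseline correction over the 100 ms pre-stimulus interval;
* P50 = maximum positive amplitude at Cz in the closed 40-85 ms window,
  baseline-to-peak; a P50 must reach 0.5 uV to count as measurable;
* gating ratio = test P50 / conditioning P50 over the pair-averaged ERPs,
  valid only when the conditioning amplitude meets the 0.5 uV criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

MARKER_KINDS = ("single", "pair_first", "pair_second")


class SerpConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EventMarker:
    """Stimulus marker at a 0-based sample index."""

    sample: int
    kind: str
    pair_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise SerpConfigError(f"unknown marker kind {self.kind!r}")


@dataclass
class Recording:
    """Continuous multichannel recording, amplitudes in microvolts."""

    fs: float
    channels: Sequence[str]
    data: np.ndarray  # (n_channels, n_samples)
    markers: List[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise SerpConfigError(
                f"data shape {self.data.shape} does not match {len(self.channels)} channels"
            )
        samples = [m.sample for m in self.markers]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise SerpConfigError("marker sample indices must be strictly increasing")

    def channel_index(self, label: str) -> int:
        try:
            return list(self.channels).index(label)
        except ValueError:
            raise SerpConfigError(f"channel {label!r} not present") from None


@dataclass
class Epoch:
    """One stimulus-locked segment, -100..+200 ms around the marker."""

    data: np.ndarray  # (n_channels, n_times)
    fs: float
    channels: Sequence[str]
    marker: EventMarker
    pre_s: float = 0.1
    post_s: float = 0.2

    @property
    def times_ms(self) -> np.ndarray:
        n_pre = int(round(self.pre_s * self.fs))
        return (np.arange(self.data.shape[1]) - n_pre) / self.fs * 1000.0


@dataclass
class ERPWaveform:
    """Trial-averaged evoked waveform on the epoch time base."""

    data: np.ndarray  # (n_channels, n_times)
    fs: float
    channels: Sequence[str]
    times_ms: np.ndarray
    n_trials: int
    n_rejected: int = 0


@dataclass(frozen=True)
class P50Measurement:
    amplitude: float  # uV, baseline-to-peak
    latency_ms: float  # post-stimulus
    meets_criterion: bool


@dataclass(frozen=True)
class GatingResult:
    c_amplitude: float
    t_amplitude: float
    ratio: Optional[float]
    valid: bool


@dataclass(frozen=True)
class SerpParams:
    """Pipeline parameters; defaults are the analysis values of the design."""

    band: Tuple[float, float] = (10.0, 300.0)
    filter_order: int = 4
    detrend_order: int = 1
    reject_uv: float = 100.0
    p50_window_ms: Tuple[float, float] = (40.0, 85.0)
    criterion_uv: float = 0.5
    channel: str = "Cz"
    mastoids: Tuple[str, str] = ("M1", "M2")
    pre_s: float = 0.1
    post_s: float = 0.2


@dataclass
class SerpResult:
    """Per-participant pipeline output."""

    single: Optional[P50Measurement] = None
    conditioning: Optional[P50Measurement] = None
    test: Optional[P50Measurement] = None
    gating: Optional[GatingResult] = None
    counts: Dict[str, int] = field(default_factory=dict)
    erps: Dict[str, ERPWaveform] = field(default_factory=dict)


def rereference(rec: Recording, mastoids: Tuple[str, str] = ("M1", "M2")) -> Recording:
    """Reference to the mastoid mean, then to the average of all channels.

    After the second stage the cross-channel mean is zero at every sample.
    """
    idx = [rec.channel_index(m) for m in mastoids]
    data = rec.data - rec.data[idx].mean(axis=0, keepdims=True)
    data = data - data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def detrend(rec: Recording, order: int = 1) -> Recording:
    """Subtract a per-channel least-squares polynomial of the given order."""
    if order < 0:
        raise SerpConfigError(f"detrend order must be >= 0, got {order}")
    n = rec.data.shape[1]
    # centred/scaled abscissa keeps the Vandermonde system well conditioned
    x = np.linspace(-1.0, 1.0, n)
    V = np.polynomial.polynomial.polyvander(x, order)
    coef, *_ = np.linalg.lstsq(V, rec.data.T, rcond=None)
    return replace(rec, data=rec.data - (V @ coef).T)


def bandpass(rec: Recording, low: float = 10.0, high: float = 300.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise SerpConfigError(f"invalid band edges ({low}, {high}) for fs={rec.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return replace(rec, data=signal.sosfiltfilt(sos, rec.data, axis=1))


def extract_epochs(
    rec: Recording,
    kinds: Iterable[str],
    pre_s: float = 0.1,
    post_s: float = 0.2,
) -> List[Epoch]:
    """Cut one epoch per selected marker: samples [t0 - pre, t0 + post).

    Markers whose window would cross a recording edge are dropped (counted
    in the log).
    """
    kinds = set(kinds)
    n_pre = int(round(pre_s * rec.fs))
    n_post = int(round(post_s * rec.fs))
    n_samples = rec.data.shape[1]
    epochs: List[Epoch] = []
    dropped = 0
    for m in rec.markers:
        if m.kind not in kinds:
            continue
        start, stop = m.sample - n_pre, m.sample + n_post
        if start < 0 or stop > n_samples:
            dropped += 1
            continue
        epochs.append(
            Epoch(
                data=rec.data[:, start:stop].copy(),
                fs=rec.fs,
                channels=rec.channels,
                marker=m,
                pre_s=pre_s,
                post_s=post_s,
            )
        )
    if dropped:
        logger.info("extract_epochs: dropped %d marker(s) at recording edges", dropped)
    return epochs


def reject_artifacts(epochs: Sequence[Epoch], threshold_uv: float = 100.0) -> List[Epoch]:
    """Drop epochs whose peak-to-peak amplitude exceeds the threshold on any
    channel."""
    if not threshold_uv > 0:
        raise SerpConfigError(f"rejection threshold must be > 0, got {threshold_uv}")
    kept = [
        e for e in epochs if (e.data.max(axis=1) - e.data.min(axis=1)).max() <= threshold_uv
    ]
    n_rej = len(epochs) - len(kept)
    if n_rej:
        logger.info("reject_artifacts: removed %d of %d epochs", n_rej, len(epochs))
    return kept


def baseline_correct(epoch: Epoch) -> Epoch:
    """Subtract the per-channel mean over the pre-stimulus [-100, 0) ms."""
    n_pre = int(round(epoch.pre_s * epoch.fs))
    base = epoch.data[:, :n_pre].mean(axis=1, keepdims=True)
    return replace(epoch, data=epoch.data - base)


def average_epochs(epochs: Sequence[Epoch], n_rejected: int = 0) -> ERPWaveform:
    """Pointwise mean over epochs sharing one time base."""
    if not epochs:
        raise SerpConfigError("cannot average an empty epoch list")
    shapes = {e.data.shape for e in epochs}
    if len(shapes) != 1:
        raise SerpConfigError(f"epochs have differing shapes: {shapes}")
    data = np.mean([e.data for e in epochs], axis=0)
    first = epochs[0]
    return ERPWaveform(
        data=data,
        fs=first.fs,
        channels=first.channels,
        times_ms=first.times_ms,
        n_trials=len(epochs),
        n_rejected=n_rejected,
    )


def measure_p50(
    erp: ERPWaveform,
    channel: str = "Cz",
    window_ms: Tuple[float, float] = (40.0, 85.0),
    criterion_uv: float = 0.5,
) -> P50Measurement:
    """Peak amplitude (baseline-to-peak) in the closed 40-85 ms window at Cz.

    The peak is the maximum positive sample in the window; no local-maximum
    requirement.  ``meets_criterion`` records whether the 0.5 uV inclusion
    threshold is reached.
    """
    ci = list(erp.channels).index(channel)
    mask = (erp.times_ms >= window_ms[0]) & (erp.times_ms <= window_ms[1])
    if not mask.any():
        raise SerpConfigError(f"window {window_ms} ms not covered by the epoch time base")
    seg = erp.data[ci, mask]
    k = int(np.argmax(seg))
    amp = float(seg[k])
    lat = float(erp.times_ms[mask][k])
    return P50Measurement(amplitude=amp, latency_ms=lat, meets_criterion=amp >= criterion_uv)


def gating_ratio(c: P50Measurement, t: P50Measurement, criterion_uv: float = 0.5) -> GatingResult:
    """Test/conditioning (T/C) amplitude ratio; smaller means more gating.

    Valid only when the conditioning amplitude reaches the inclusion
    criterion (the criterion is not applied to the test response).
    """
    valid = c.amplitude >= criterion_uv
    ratio = t.amplitude / c.amplitude if valid else None
    return GatingResult(c_amplitude=c.amplitude, t_amplitude=t.amplitude, ratio=ratio, valid=valid)


def _preprocess(rec: Recording, params: SerpParams) -> Recording:
    out = rereference(rec, params.mastoids)
    out = detrend(out, params.detrend_order)
    out = bandpass(out, params.band[0], params.band[1], params.filter_order)
    return out


def _measure_kind(rec: Recording, kind: str, params: SerpParams):
    epochs = extract_epochs(rec, {kind}, params.pre_s, params.post_s)
    if not epochs:
        return None, None, {"extracted": 0, "rejected": 0, "averaged": 0}
    kept = reject_artifacts(epochs, params.reject_uv)
    counts = {"extracted": len(epochs), "rejected": len(epochs) - len(kept), "averaged": len(kept)}
    if not kept:
        return None, None, counts
    kept = [baseline_correct(e) for e in kept]
    erp = average_epochs(kept, n_rejected=counts["rejected"])
    meas = measure_p50(erp, params.channel, params.p50_window_ms, params.criterion_uv)
    return erp, meas, counts


def run_serp(rec: Recording, params: SerpParams = SerpParams()) -> SerpResult:
    """Run the full pipeline on one recording.

    Handles the single-train paradigm (``single`` markers) and the paired
    paradigm (``pair_first``/``pair_second``) in the same recording or
    separately; deterministic given inputs and parameters.
    """
    pre = _preprocess(rec, params)
    result = SerpResult()
    erp, meas, counts = _measure_kind(pre, "single", params)
    if erp is not None:
        result.single = meas
        result.erps["single"] = erp
    for key in ("extracted", "rejected", "averaged"):
        result.counts[f"single_{key}"] = counts[key]

    erp_c, meas_c, counts_c = _measure_kind(pre, "pair_first", params)
    erp_t, meas_t, counts_t = _measure_kind(pre, "pair_second", params)
    for key in ("extracted", "rejected", "averaged"):
        result.counts[f"conditioning_{key}"] = counts_c[key]
        result.counts[f"test_{key}"] = counts_t[key]
    if erp_c is not None:
        result.conditioning = meas_c
        result.erps["conditioning"] = erp_c
    if erp_t is not None:
        result.test = meas_t
        result.erps["test"] = erp_t
    if meas_c is not None and meas_t is not None:
        result.gating = gating_ratio(meas_c, meas_t, params.criterion_uv)
    return result
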