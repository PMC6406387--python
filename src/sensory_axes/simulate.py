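"""Synthetic cohorts with known ground truth.

Two generators make every pipeline stage testable without external data:

* questionnaire responses with *archetype* structure -- each simulated
  respondent belongs to one quadrant and rates that quadrant's items from
  a higher Likert distribution than the remaining items (discretized
  truncated normal);
* multichannel EEG (2000 Hz) consisting of background noise (white + 1/f
  mix) plus a positive evoked component -- a Gaussian-windowed oscillation
  whose main lobe peaks ~55 ms post-stimulus, with a fixed zero-mean scalp
  topography centred on Cz -- at every stimulus marker.  (The windowed
  oscillation, rather than an isolated bump, matches what a fast evoked
  deflection looks like inside a 10-300 Hz analysis band: it carries no
  DC content, so the band-pass leaves its peak nearly untouched.)  In the paired paradigm the
  second-in-pair response is attenuated by a known gating factor ``g``.

Stimulus timing follows the study paradigms: 200 single stimuli in a 5 Hz
train, and 200 pairs with 500 ms within-pair separation.  Distributional
parameters for responses and noise are not taken from any publication;
the defaults are documented choices that a practitioner would call
plausible, and every quantity is tunable.

All randomness flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .epq import EPQItemMap
from .profile import ACTIVE_QUADRANTS, QUADRANTS, ItemMap, ResponseSet
from .serp import EventMarker, Recording, SerpConfigError

#: default mixture, skewed toward active/high-threshold patterns as observed
#: in healthy-adult convenience samples
DEFAULT_WEIGHTS: Dict[str, float] = {
    "seeking": 0.70,
    "low_registration": 0.20,
    "sensitivity": 0.05,
    "avoiding": 0.05,
}

DEFAULT_CHANNELS: Tuple[str, ...] = ("Cz", "C1", "C3", "Pz", "Fp1", "Fp2", "M1", "M2")
#: zero-mean evoked topography (Cz weight 1), so the average-referenced Cz
#: amplitude equals the nominal component amplitude
DEFAULT_TOPOGRAPHY: Tuple[float, ...] = (1.0, 0.6, 0.6, 0.4, -0.65, -0.65, -0.65, -0.65)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Likert response distributions for one target quadrant."""

    target: str
    on_mean: float = 4.2
    on_sd: float = 0.8
    off_mean: float = 2.2
    off_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.target not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.target!r}")
        for m in (self.on_mean, self.off_mean):
            if not 1 <= m <= 5:
                raise ValueError(f"archetype mean {m} outside the 1-5 rating scale")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, archetype mixture and optional personality coupling."""

    n: int = 139
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    on_mean: float = 4.2
    on_sd: float = 0.8
    off_mean: float = 2.2
    off_sd: float = 0.8
    #: mean I/E axis score by behavioral-response group (optional coupling)
    ie_axis_mean: Mapping[str, float] = field(
        default_factory=lambda: {"passive": -3.0, "active": 2.0}
    )
    ie_item_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        w = np.array([self.weights.get(q, 0.0) for q in QUADRANTS], dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must be nonnegative and sum to 1")


@dataclass(frozen=True)
class EEGSimSpec:
    """Synthetic EEG paradigm and signal/noise parameters.

    ``amplitude_uv`` is the evoked P50 amplitude at Cz (after average
    reference, by construction of the zero-mean topography); ``gating``
    multiplies the response to the second stimulus of each pair only.
    """

    paradigm: str = "pairs"  # or "single_train"
    n_stimuli: int = 200
    fs: float = 2000.0
    amplitude_uv: float = 2.0
    latency_ms: float = 55.0
    width_ms: float = 6.0  # Gaussian envelope sigma
    carrier_hz: float = 55.0  # oscillation under the envelope
    gating: float = 0.6
    noise_sd_uv: float = 2.0
    pink_fraction: float = 0.5
    train_rate_hz: float = 5.0
    intra_pair_s: float = 0.5
    inter_pair_s: float = 8.0
    pad_s: float = 1.0
    channels: Tuple[str, ...] = DEFAULT_CHANNELS
    topography: Tuple[float, ...] = DEFAULT_TOPOGRAPHY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.paradigm not in ("single_train", "pairs"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if not 0 <= self.gating <= 1:
            raise ValueError("gating factor must lie in [0, 1]")
        if len(self.channels) != len(self.topography):
            raise ValueError("topography length must match the channel list")
        if self.paradigm == "pairs" and self.inter_pair_s < self.intra_pair_s + 0.3:
            raise SerpConfigError(
                "pairs overlap: inter-pair interval must exceed the within-pair "
                "interval plus the 300 ms epoch window"
            )


def _likert(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Discretized truncated normal on the 1-5 integer scale."""
    return np.clip(np.rint(rng.normal(mean, sd, size)), 1, 5).astype(int)


def simulate_responses(
    spec: CohortSpec, item_map: ItemMap, rng: Optional[np.random.Generator] = None
) -> Tuple[List[ResponseSet], List[str]]:
    """Draw a cohort of questionnaire responses with known archetypes.

    Returns the response sets and, parallel to them, each respondent's true
    quadrant label.  Deterministic given ``spec.seed`` (or the supplied rng).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    weights = np.array([spec.weights.get(q, 0.0) for q in QUADRANTS])
    labels = [QUADRANTS[i] for i in rng.choice(len(QUADRANTS), size=spec.n, p=weights)]
    responses = []
    items = list(item_map.entries)
    quads = np.array([item_map.entries[i] for i in items])
    for p, target in enumerate(labels):
        on = quads == target
        ratings = np.empty(len(items), dtype=int)
        ratings[on] = _likert(rng, spec.on_mean, spec.on_sd, int(on.sum()))
        ratings[~on] = _likert(rng, spec.off_mean, spec.off_sd, int((~on).sum()))
        responses.append(
            ResponseSet(
                participant_id=f"P{p + 1:03d}",
                ratings=dict(zip(items, (int(r) for r in ratings))),
            )
        )
    return responses, labels


def simulate_epq_responses(
    labels: Sequence[str],
    epq_map: EPQItemMap,
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
) -> List[Dict[str, int]]:
    """Draw personality ratings whose I/E axis mean depends on the BR group
    of each respondent's true quadrant (active vs passive coupling).

    Reverse-marked items are stored pre-reversal (6 - r), so that scoring
    recovers the intended construct value.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    out = []
    for target in labels:
        group = "active" if target in ACTIVE_QUADRANTS else "passive"
        # item mean that yields the requested axis mean: axis = 12*(mu-1) - 24
        mu_ie = spec.ie_axis_mean[group] / 12.0 + 3.0
        ratings: Dict[str, int] = {}
        for item, scale in epq_map.entries.items():
            mu = mu_ie if scale == "ie" else 3.0
            r = int(_likert(rng, mu, spec.ie_item_sd, 1)[0])
            if item in epq_map.reverse_items:
                r = 6 - r
            ratings[item] = r
        out.append(ratings)
    return out


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping."""
    from scipy import fft as sfft

    n_fft = sfft.next_fast_len(n)
    white = rng.standard_normal(n_fft)
    spec = sfft.rfft(white)
    f = sfft.rfftfreq(n_fft)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    shaped = sfft.irfft(spec * scale, n_fft)[:n]
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _marker_onsets(spec: EEGSimSpec) -> List[EventMarker]:
    fs = spec.fs
    pad = int(round(spec.pad_s * fs))
    markers: List[EventMarker] = []
    if spec.paradigm == "single_train":
        step = int(round(fs / spec.train_rate_hz))
        for i in range(spec.n_stimuli):
            markers.append(EventMarker(sample=pad + i * step, kind="single"))
    else:
        inter = int(round(spec.inter_pair_s * fs))
        intra = int(round(spec.intra_pair_s * fs))
        for i in range(spec.n_stimuli):
            first = pad + i * inter
            markers.append(EventMarker(sample=first, kind="pair_first", pair_id=i))
            markers.append(EventMarker(sample=first + intra, kind="pair_second", pair_id=i))
    return markers


def simulate_eeg(spec: EEGSimSpec) -> Recording:
    """Render one synthetic recording with markers.

    The evoked component is a positive-peaked, Gaussian-windowed cosine
    (envelope sigma ``width_ms``, carrier ``carrier_hz``) whose maximum
    falls ``latency_ms`` after each stimulus, projected onto the channels
    through the fixed topography; pair-second responses are scaled by the
    gating factor.  Additive noise is an independent white/pink mix per
    channel with total sd ``noise_sd_uv``.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    markers = _marker_onsets(spec)
    n_samples = markers[-1].sample + int(round((spec.pad_s + 0.3) * fs))

    n_ch = len(spec.channels)
    data = np.zeros((n_ch, n_samples))
    if spec.noise_sd_uv > 0:
        w_frac = np.sqrt(1.0 - spec.pink_fraction)
        p_frac = np.sqrt(spec.pink_fraction)
        for c in range(n_ch):
            noise = w_frac * rng.standard_normal(n_samples)
            if spec.pink_fraction > 0:
                noise = noise + p_frac * _pink_noise(rng, n_samples)
            data[c] = spec.noise_sd_uv * noise

    # evoked kernel sampled out to +-5 sigma around the peak
    sigma = spec.width_ms / 1000.0
    half = int(round(5 * sigma * fs))
    t = (np.arange(2 * half + 1) - half) / fs
    kernel = np.exp(-0.5 * (t / sigma) ** 2) * np.cos(2 * np.pi * spec.carrier_hz * t)
    lat = int(round(spec.latency_ms / 1000.0 * fs))
    topo = np.asarray(spec.topography)

    for m in markers:
        amp = spec.amplitude_uv * (spec.gating if m.kind == "pair_second" else 1.0)
        centre = m.sample + lat
        lo, hi = centre - half, centre + half + 1
        klo, khi = max(0, -lo), len(kernel) - max(0, hi - n_samples)
        lo, hi = max(lo, 0), min(hi, n_samples)
        data[:, lo:hi] += amp * topo[:, None] * kernel[klo:khi]

    return Recording(fs=fs, channels=list(spec.channels), data=data, markers=markers)
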