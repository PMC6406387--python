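"""Evoked-potential pipeline: referencing, filtering, epoching, averaging,
P50 measurement and gating ratios."""

import numpy as np
import pytest

from sensory_axes.serp import (
    Epoch,
    ERPWaveform,
    EventMarker,
    GatingResult,
    P50Measurement,
    Recording,
    SerpConfigError,
    SerpParams,
    average_epochs,
    bandpass,
    baseline_correct,
    detrend,
    extract_epochs,
    gating_ratio,
    measure_p50,
    rereference,
    reject_artifacts,
    run_serp,
)
from sensory_axes.simulate import EEGSimSpec, simulate_eeg

FS = 2000.0


def make_recording(data, channels=None, markers=()):
    data = np.asarray(data, dtype=float)
    channels = channels or [f"ch{i}" for i in range(data.shape[0])]
    return Recording(fs=FS, channels=channels, data=data, markers=list(markers))


def epoch_from(data):
    data = np.asarray(data, dtype=float)
    return Epoch(data=data, fs=FS, channels=[f"ch{i}" for i in range(data.shape[0])],
                 marker=EventMarker(400, "single"))


# -- rereference -----------------------------------------------------------

def test_rereference_removes_common_mode():
    rec = make_recording(np.full((4, 100), 7.0), channels=["Cz", "Pz", "M1", "M2"])
    out = rereference(rec)
    assert np.allclose(out.data, 0.0)


def test_rereference_zero_mastoids_then_demean():
    data = np.vstack([np.ones(50), -np.ones(50), np.zeros(50), np.zeros(50)])
    rec = make_recording(data, channels=["a", "b", "M1", "M2"])
    out = rereference(rec)
    # stage 1 is the identity (mastoids at zero); stage 2 removes the channel mean
    assert np.allclose(out.data, data - data.mean(axis=0, keepdims=True))


def test_rereference_output_has_zero_channel_mean():
    rng = np.random.default_rng(0)
    rec = make_recording(rng.normal(size=(4, 500)), channels=["Cz", "Pz", "M1", "M2"])
    out = rereference(rec)
    assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)


def test_rereference_requires_mastoids():
    rec = make_recording(np.zeros((2, 10)), channels=["Cz", "Pz"])
    with pytest.raises(SerpConfigError):
        rereference(rec)


# -- detrend ---------------------------------------------------------------

def test_detrend_removes_fitted_polynomials():
    n = 1000
    x = np.arange(n, dtype=float)
    ramp = make_recording(np.vstack([2.0 + 0.01 * x]))
    assert np.allclose(detrend(ramp, order=1).data, 0.0, atol=1e-8)
    const = make_recording(np.vstack([np.full(n, 3.0)]))
    assert np.allclose(detrend(const, order=0).data, 0.0, atol=1e-10)


def test_detrend_preserves_oscillation():
    t = np.arange(4000) / FS
    sine = np.sin(2 * np.pi * 20 * t)
    rec = make_recording(sine[None, :])
    out = detrend(rec, order=1)
    rms_in = np.sqrt(np.mean(sine**2))
    rms_out = np.sqrt(np.mean(out.data**2))
    assert abs(rms_out - rms_in) / rms_in < 0.01


def test_detrend_rejects_negative_order():
    with pytest.raises(SerpConfigError):
        detrend(make_recording(np.zeros((1, 10))), order=-1)


# -- bandpass --------------------------------------------------------------

def sine_gain(freq):
    t = np.arange(int(4 * FS)) / FS
    rec = make_recording(np.sin(2 * np.pi * freq * t)[None, :])
    out = bandpass(rec, 10.0, 300.0)
    mid = slice(2000, -2000)  # avoid edge transients
    return np.abs(out.data[0, mid]).max()


def test_bandpass_frequency_response():
    assert sine_gain(50.0) >= 0.9
    assert sine_gain(1.0) <= 0.1


def test_bandpass_zero_in_zero_out():
    rec = make_recording(np.zeros((2, 100)))
    assert np.allclose(bandpass(rec, 10, 300).data, 0.0)


@pytest.mark.parametrize("low,high", [(0, 300), (300, 10), (10, 1500)])
def test_bandpass_rejects_bad_edges(low, high):
    with pytest.raises(SerpConfigError):
        bandpass(make_recording(np.zeros((1, 100))), low, high)


# -- epoching --------------------------------------------------------------

def test_epoch_window_indices():
    data = np.arange(4000, dtype=float)[None, :]
    rec = make_recording(data, markers=[EventMarker(2000, "single")])
    (epoch,) = extract_epochs(rec, {"single"})
    assert epoch.data.shape == (1, 600)
    assert np.array_equal(epoch.data[0], data[0, 1800:2400])
    assert epoch.times_ms[0] == -100.0 and epoch.times_ms[-1] == pytest.approx(199.5)


def test_edge_marker_dropped():
    rec = make_recording(np.zeros((1, 4000)), markers=[EventMarker(100, "single")])
    assert extract_epochs(rec, {"single"}) == []


def test_full_train_yields_one_epoch_per_stimulus():
    rec = simulate_eeg(EEGSimSpec(paradigm="single_train", n_stimuli=200,
                                  noise_sd_uv=0.0, seed=0))
    assert len(extract_epochs(rec, {"single"})) == 200


def test_epoching_is_shift_equivariant():
    rng = np.random.default_rng(1)
    data = rng.normal(size=(2, 3000))
    shift = 250
    rec_a = make_recording(data[:, :2500], markers=[EventMarker(1000, "single")])
    # same data delayed by `shift` samples with markers delayed alike
    delayed = np.concatenate([np.zeros((2, shift)), data[:, :2500]], axis=1)
    rec_c = make_recording(delayed, markers=[EventMarker(1000 + shift, "single")])
    (ea,) = extract_epochs(rec_a, {"single"})
    (ec,) = extract_epochs(rec_c, {"single"})
    assert np.array_equal(ea.data, ec.data)


# -- artifact rejection / baseline / averaging -----------------------------

def test_artifact_rejection_removes_exactly_contaminated():
    rng = np.random.default_rng(2)
    clean = [epoch_from(rng.normal(0, 5, size=(2, 600))) for _ in range(10)]
    dirty = []
    for k in range(3):
        d = rng.normal(0, 5, size=(2, 600))
        d[0, 300] = 500.0
        dirty.append(epoch_from(d))
    kept = reject_artifacts(clean + dirty, threshold_uv=100.0)
    assert len(kept) == 10
    assert all(any(k is c for c in clean) for k in kept)
    assert [e is c for e, c in zip(reject_artifacts(clean, threshold_uv=100.0), clean)]
    assert len(reject_artifacts(clean, threshold_uv=100.0)) == len(clean)


def test_baseline_correction():
    const = epoch_from(np.full((1, 600), 4.0))
    assert np.allclose(baseline_correct(const).data, 0.0)
    data = np.full((1, 600), 3.0)
    data[0, 200:] = 8.0  # post-stimulus
    out = baseline_correct(epoch_from(data))
    assert np.allclose(out.data[0, 200:], 5.0)
    zero_mean = epoch_from(np.concatenate([np.tile([1.0, -1.0], 100), np.ones(400)])[None, :])
    assert np.allclose(baseline_correct(zero_mean).data, zero_mean.data)


def test_average_epochs():
    a = epoch_from(np.ones((1, 600)))
    b = epoch_from(-np.ones((1, 600)))
    assert np.allclose(average_epochs([a, a]).data, a.data)
    assert np.allclose(average_epochs([a, b]).data, 0.0)
    with pytest.raises(SerpConfigError):
        average_epochs([])


def test_averaging_suppresses_noise_as_sqrt_n():
    rng = np.random.default_rng(3)
    sigma, n = 5.0, 200
    template = np.sin(np.linspace(0, 4 * np.pi, 600))[None, :]
    epochs = [epoch_from(template + rng.normal(0, sigma, size=(1, 600))) for _ in range(n)]
    residual = average_epochs(epochs).data - template
    rms = np.sqrt(np.mean(residual**2))
    expected = sigma / np.sqrt(n)
    assert expected / 3 < rms < 2 * expected


# -- P50 measurement and gating --------------------------------------------

def erp_with_bump(amp, centre_ms, channel="Cz"):
    times = (np.arange(600) - 200) / FS * 1000.0
    data = amp * np.exp(-0.5 * ((times - centre_ms) / 8.0) ** 2)[None, :]
    return ERPWaveform(data=data, fs=FS, channels=[channel], times_ms=times, n_trials=10)


def test_p50_peak_and_latency():
    m = measure_p50(erp_with_bump(2.0, 55.0))
    assert m.amplitude == pytest.approx(2.0, abs=0.01)
    assert m.latency_ms == pytest.approx(55.0, abs=1.0)
    assert m.meets_criterion


def test_p50_flat_erp_fails_criterion():
    m = measure_p50(erp_with_bump(0.0, 55.0))
    assert m.amplitude == 0.0 and not m.meets_criterion


def test_p50_window_excludes_late_bump():
    m = measure_p50(erp_with_bump(3.0, 120.0))
    assert m.amplitude < 0.5 and not m.meets_criterion


def test_gating_ratio_rules():
    c = P50Measurement(1.0, 55.0, True)
    t = P50Measurement(0.5, 55.0, True)
    g = gating_ratio(c, t)
    assert g.valid and g.ratio == pytest.approx(0.5)
    weak = P50Measurement(0.4, 55.0, False)
    g2 = gating_ratio(weak, t)
    assert not g2.valid and g2.ratio is None


# -- end-to-end ------------------------------------------------------------

def test_noiseless_pipeline_recovers_amplitude_and_gating():
    spec = EEGSimSpec(paradigm="pairs", n_stimuli=15, amplitude_uv=2.0, gating=0.77,
                      noise_sd_uv=0.0, inter_pair_s=1.2, seed=0)
    res = run_serp(simulate_eeg(spec))
    assert res.conditioning.amplitude == pytest.approx(2.0, rel=0.05)
    assert res.gating.ratio == pytest.approx(0.77, abs=0.01)
    assert res.conditioning.latency_ms == pytest.approx(55.0, abs=3.0)


def test_pipeline_linear_scaling_leaves_ratio_unchanged():
    spec = EEGSimSpec(paradigm="pairs", n_stimuli=15, amplitude_uv=1.5, gating=0.6,
                      noise_sd_uv=0.3, inter_pair_s=1.2, seed=4)
    rec = simulate_eeg(spec)
    res1 = run_serp(rec)
    scaled = Recording(fs=rec.fs, channels=rec.channels, data=3.0 * rec.data,
                       markers=rec.markers)
    res3 = run_serp(scaled)
    assert res3.conditioning.amplitude == pytest.approx(3 * res1.conditioning.amplitude, rel=1e-6)
    assert res3.gating.ratio == pytest.approx(res1.gating.ratio, rel=1e-6)


def test_pure_noise_recording_fails_criterion():
    spec = EEGSimSpec(paradigm="single_train", n_stimuli=150, amplitude_uv=0.0, seed=5)
    res = run_serp(simulate_eeg(spec))
    assert not res.single.meets_criterion


def test_run_serp_deterministic():
    spec = EEGSimSpec(paradigm="pairs", n_stimuli=10, amplitude_uv=1.0, gating=0.5,
                      inter_pair_s=1.2, seed=6)
    r1 = run_serp(simulate_eeg(spec))
    r2 = run_serp(simulate_eeg(spec))
    assert r1.conditioning.amplitude == r2.conditioning.amplitude
    assert r1.gating.ratio == r2.gating.ratio
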