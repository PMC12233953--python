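"""Photometry preprocessing: baselines, artifact removal, alignment, filters."""

import numpy as np
import pandas as pd
import pytest

from beliefbandit.photometry import (airpls_baseline, isosbestic_correct,
                                     zscore_session, preprocess,
                                     align_to_event, da_peak_trough,
                                     compute_durations, filter_trials,
                                     PhotometrySession, transient_kernel,
                                     make_synthetic_recording,
                                     synthesize_dlight)


def random_recording(n_sec=600, rate=20.0, n_events=80, snr=4.0, seed=0):
    """Synthetic recording with randomly timed positive transients."""
    rng = np.random.default_rng(seed)
    events = np.sort(rng.choice(np.arange(5.0, n_sec - 5.0, 1.0 / rate),
                                n_events, replace=False))
    amps = rng.uniform(0.5, 1.5, n_events)
    rec = make_synthetic_recording(events, amps, duration=n_sec, rate=rate,
                                   snr=snr, rng=rng)
    rec["events"] = events
    return rec


def test_airpls_tracks_pure_drift():
    t = np.linspace(0, 100, 2000)
    drift = 0.05 * t + 2.0
    base = airpls_baseline(drift, lam=1e6)
    assert np.abs(base - drift).max() < 0.01 * (drift.max() - drift.min())


def test_airpls_constant_series_is_its_own_baseline():
    y = np.full(500, 3.7)
    np.testing.assert_allclose(airpls_baseline(y), y, atol=1e-8)


def test_airpls_preserves_positive_transients():
    rng = np.random.default_rng(2)
    t = np.linspace(0, 300, 6000)
    drift = 2 * np.exp(-t / 200)
    transients = np.zeros_like(t)
    idx = rng.choice(len(t) - 100, 30, replace=False)
    kern = transient_kernel()
    for i in idx:
        transients[i:i + len(kern)] += kern[:len(t) - i]
    y = drift + transients
    base = airpls_baseline(y, lam=1e8)
    corrected = y - base
    peak_in = transients[idx + 10]
    peak_out = corrected[idx + 10]
    assert np.abs(peak_out - peak_in).max() < 0.05 * transients.max()


def test_airpls_rejects_bad_input():
    with pytest.raises(ValueError):
        airpls_baseline(np.array([1.0, np.nan, 2.0] * 10))
    with pytest.raises(ValueError):
        airpls_baseline(np.arange(5.0))


def test_isosbestic_perfect_artifact_cancels():
    rng = np.random.default_rng(3)
    ref = rng.normal(0, 1, 2000)
    corrected = isosbestic_correct(2.0 * ref, ref)
    assert np.abs(corrected).max() < 1e-8


def test_isosbestic_zero_variance_reference_warns():
    sig = np.random.default_rng(0).normal(0, 1, 100)
    with pytest.warns(UserWarning, match="zero variance"):
        out = isosbestic_correct(sig, np.zeros(100))
    np.testing.assert_array_equal(out, sig)


def test_isosbestic_independent_noise_keeps_signal_variance():
    rng = np.random.default_rng(4)
    sig = rng.normal(0, 1, 5000)
    ref = rng.normal(0, 1, 5000)
    out = isosbestic_correct(sig, ref)
    assert abs(out.var() / sig.var() - 1) < 0.1


def test_zscore_definitional_and_affine_invariant():
    rng = np.random.default_rng(5)
    x = rng.normal(3, 7, 1000)
    z = zscore_session(x)
    assert abs(z.mean()) < 1e-10
    assert abs(z.std() - 1) < 1e-10
    np.testing.assert_allclose(zscore_session(2.5 * x - 4), z, atol=1e-10)
    with pytest.raises(ValueError):
        zscore_session(np.full(10, 1.0))


def test_full_chain_recovers_transients():
    """At the default synthetic SNR the chain removes bleach and shared
    motion artifact well enough to track the true transient time course.

    (The attainable correlation is ceiling-limited by the white noise left
    in the corrected trace, so the bar tests artifact removal, not
    denoising.)
    """
    rec = random_recording(seed=7)
    z = preprocess(rec["signal_470"], rec["reference_415"])
    r = np.corrcoef(z, rec["transients"])[0, 1]
    assert r >= 0.9


def test_align_constant_series_and_debase():
    t = np.arange(0, 100, 0.05)
    series = np.full(len(t), 2.0)
    mat, offs = align_to_event(series, t, np.array([10.0, 50.0]), (1.0, 2.0))
    assert mat.shape == (2, len(offs))
    np.testing.assert_allclose(mat, 2.0)
    mat, _ = align_to_event(series, t, np.array([10.0]), (1.0, 2.0),
                            de_base=True)
    np.testing.assert_allclose(mat, 0.0)


def test_align_places_transient_at_expected_offset():
    rate = 20.0
    t = np.arange(0, 200, 1 / rate)
    events = np.array([20.0, 60.0, 100.0, 140.0])
    series = np.zeros(len(t))
    for ev in events:
        series[int((ev + 0.3) * rate)] = 1.0
    mat, offs = align_to_event(series, t, events, (1.0, 1.0))
    avg = mat.mean(axis=0)
    assert offs[np.argmax(avg)] == pytest.approx(0.3)


def test_align_event_outside_span_warns_with_nan_row():
    t = np.arange(0, 10, 0.05)
    with pytest.warns(UserWarning, match="outside"):
        mat, _ = align_to_event(np.ones(len(t)), t, np.array([50.0]), (1, 1))
    assert np.isnan(mat).all()


def test_align_boundary_overhang_yields_leading_nans():
    t = np.arange(0, 10, 0.05)
    mat, offs = align_to_event(np.ones(len(t)), t, np.array([0.2]), (1.0, 1.0))
    assert np.isnan(mat[0, 0])
    assert mat[0, -1] == 1.0


def test_da_peak_trough_max_min_and_flat():
    offs = np.arange(-0.5, 1.55, 0.05)
    row = np.zeros(len(offs))
    row[(offs >= 0) & (offs <= 1)] = np.nan
    assert np.isnan(da_peak_trough(row, offs, rewarded=True))
    row = np.linspace(-1, 2, len(offs))
    assert da_peak_trough(row, offs, rewarded=True) == row[offs <= 1][-1]
    vals = np.full(len(offs), 0.0)
    assert da_peak_trough(vals, offs, rewarded=True) == 0.0
    row = np.where((offs >= 0) & (offs <= 1), -1.5, 0.0)
    assert da_peak_trough(row, offs, rewarded=False) == -1.5


def test_compute_durations_identities(small_bifp_data, rng):
    from beliefbandit import generate_event_times, TimingConfig
    df = generate_event_times(small_bifp_data, TimingConfig(), rng)
    d = compute_durations(df.drop(columns=["MVMT", "ITI", "center_dur",
                                           "port_dur", "SO_lat"]))
    np.testing.assert_allclose(d["center_dur"], df["CO"] - df["CI"])
    np.testing.assert_allclose(d["port_dur"], df["SO1"] - df["O"])
    np.testing.assert_allclose(d["SO_lat"], df["SO1"] - df["SO0"])
    assert np.isnan(d["MVMT"].iloc[0])


def test_filter_trials_inclusive_thresholds_and_empty():
    at_threshold = pd.DataFrame({"center_dur": [0.8], "port_dur": [6.0],
                                 "MVMT": [3.0], "SO_lat": [1.0]})
    kept, rep = filter_trials(at_threshold)
    assert rep["n_kept"] == 1  # thresholds are inclusive
    kept, rep = filter_trials(at_threshold.iloc[:0])
    assert rep["n_total"] == 0 and len(kept) == 0


def test_filter_report_union_identity(small_bifp_data):
    from beliefbandit import generate_event_times, TimingConfig
    df = generate_event_times(small_bifp_data, TimingConfig(outlier_frac=0.2),
                              np.random.default_rng(17))
    kept, rep = filter_trials(df)
    assert rep["n_kept"] == rep["n_total"] - rep["n_rejected"]
    assert rep["n_rejected"] <= sum(rep[c] for c in
                                    ["center_dur", "port_dur", "MVMT", "SO_lat"])


def test_dlight_end_to_end_da_pt_tracks_rpe():
    """Full loop: agent simulation -> event times -> RPE-driven dLight
    trace -> preprocessing -> outcome alignment -> DA-PT summary.  The
    extracted per-trial peaks/troughs must track the generating RPEs."""
    from beliefbandit import (TaskConfig, TimingConfig, simulate_sessions,
                              generate_event_times)
    df = simulate_sessions("BIfp", dict(beta=4.0, phi=0.5, q=0.08),
                           TaskConfig(n_trials=300), 1, seed=21)
    df = generate_event_times(df, TimingConfig(), np.random.default_rng(21))
    rec = synthesize_dlight(df, np.random.default_rng(22), gain=1.0, snr=4.0)
    z = preprocess(rec["signal_470"], rec["reference_415"])
    mat, offs = align_to_event(z, rec["timestamps"], df["O"].to_numpy(),
                               (1.0, 2.0), de_base=True)
    da_pt = np.array([
        da_peak_trough(mat[i], offs, rewarded=bool(df["reward"].iloc[i]))
        for i in range(len(df))])
    ok = ~np.isnan(da_pt)
    r = np.corrcoef(da_pt[ok], df["rpe"].to_numpy()[ok])[0, 1]
    assert r > 0.7


def test_session_quality_auc_separates_transients_from_artifact():
    """Sessions with real transients score near 1; artifact-only near 0.5."""
    from beliefbandit.photometry import session_quality_auc
    rec = random_recording(seed=13)
    sig = rec["signal_470"] - airpls_baseline(rec["signal_470"])
    ref = rec["reference_415"] - airpls_baseline(rec["reference_415"])
    good = session_quality_auc(sig, ref)
    rng = np.random.default_rng(14)
    noise_only = session_quality_auc(rng.normal(0, 1, 5000),
                                     rng.normal(0, 1, 5000))
    assert good > 0.51  # transients are sparse, so the shift is modest
    assert abs(noise_only - 0.5) < 0.02
    assert good > noise_only


def test_photometry_session_validates_geometry():
    t = np.arange(0, 10, 0.05)
    with pytest.raises(ValueError, match="length"):
        PhotometrySession(np.ones(10), np.ones(11), t[:10])
    with pytest.raises(ValueError, match="rate"):
        PhotometrySession(np.ones(100), np.ones(100), np.arange(100) * 1.0)
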