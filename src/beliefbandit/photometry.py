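"""Two-channel fiber-photometry preprocessing and trial-level summaries.

The dopamine-sensitive channel (470 nm) and the dopamine-insensitive
isosbestic reference (415 nm), both sampled at 20 Hz, are preprocessed in
three steps: (1) slow per-channel trends (photobleaching) are removed with
the airPLS adaptive baseline, (2) shared motion/bleaching artifacts are
removed by robustly regressing the signal channel on the reference and
subtracting the fit, (3) the corrected trace is z-scored per session.
Trial-level summaries align the processed trace to the outcome event and
take the peak (rewarded) or trough (unrewarded) in the following second
(the "DA-PT" statistic).
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
import statsmodels.api as sm

__all__ = [
    "transient_kernel",
    "make_synthetic_recording",
    "synthesize_dlight",
    "airpls_baseline",
    "isosbestic_correct",
    "zscore_session",
    "preprocess",
    "align_to_event",
    "da_peak_trough",
    "compute_durations",
    "filter_trials",
    "DEFAULT_FILTERS",
    "PhotometrySession",
]

SAMPLING_RATE = 20.0


def transient_kernel(rate: float = SAMPLING_RATE, rise: float = 0.1,
                     decay: float = 0.5, length: float = 3.0) -> np.ndarray:
    """Unit-peak dLight-like transient: fast saturating rise, exponential
    decay, sampled at ``rate``."""
    t = np.arange(0.0, length, 1.0 / rate)
    k = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    return k / k.max()


def make_synthetic_recording(event_times: np.ndarray,
                             amplitudes: np.ndarray,
                             duration: float,
                             rate: float = SAMPLING_RATE,
                             decays: Optional[np.ndarray] = None,
                             snr: float = 4.0,
                             rng: Optional[np.random.Generator] = None) -> dict:
    """Synthetic two-channel recording: bleach + shared motion artifact +
    event-locked transients + white noise.

    ``snr`` is the ratio of the transient trace's SD to the white-noise SD;
    both channels share a slow motion artifact (scaled 0.9 in the
    reference), and each carries its own exponential photobleaching trend.
    Returns a dict with signal/reference/timestamps and the ground-truth
    transient trace.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    bleach_sig = 3.0 * np.exp(-t / 500.0) + 1.0
    bleach_ref = 2.0 * np.exp(-t / 600.0) + 0.8
    artifact = np.cumsum(rng.normal(0.0, 0.01, n))
    kern_w = 41
    artifact = np.convolve(artifact, np.ones(kern_w) / kern_w, mode="same")
    transients = np.zeros(n)
    decays = decays if decays is not None else np.full(len(event_times), 0.5)
    for ev, amp, dec in zip(event_times, amplitudes, decays):
        if np.isnan(ev) or np.isnan(amp):
            continue
        i0 = int(round(ev * rate))
        if i0 < 0 or i0 >= n:
            continue
        k = transient_kernel(rate, decay=float(dec))
        transients[i0:i0 + len(k)] += amp * k[:n - i0]
    sd = transients.std()
    noise_sd = (sd / snr) if sd > 0 else 0.05
    signal = bleach_sig + artifact + transients + rng.normal(0, noise_sd, n)
    reference = bleach_ref + 0.9 * artifact + rng.normal(0, noise_sd, n)
    return {"signal_470": signal, "reference_415": reference, "timestamps": t,
            "transients": transients, "rate": rate}


def synthesize_dlight(records: pd.DataFrame,
                      rng: Optional[np.random.Generator] = None,
                      gain: float = 1.0, snr: float = 4.0,
                      rate: float = SAMPLING_RATE) -> dict:
    """dLight-like recording driven by a session's model RPEs.

    Transients are locked to the outcome event (O), with amplitude
    ``gain * rpe`` and a decay timescale that grows with the time spent at
    the port, mirroring the observation that dopamine transients extend
    while the animal lingers.  Requires O, rpe and (optionally) port_dur
    columns on a single-session trial table.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if records["O"].isna().all() or "rpe" not in records.columns:
        raise ValueError("records need O event times and an rpe column")
    o = records["O"].to_numpy(dtype=float)
    amp = gain * records["rpe"].to_numpy(dtype=float)
    port = records.get("port_dur", pd.Series(np.ones(len(records))))
    port = np.clip(np.nan_to_num(np.asarray(port, dtype=float), nan=1.0), 0, 6)
    decays = 0.3 + 0.1 * port
    duration = float(np.nanmax(records["SOf"])) + 5.0
    return make_synthetic_recording(o, amp, duration, rate=rate,
                                    decays=decays, snr=snr, rng=rng)


def airpls_baseline(y: np.ndarray, lam: float = 1e8, max_iter: int = 50) -> np.ndarray:
    """Adaptive iteratively reweighted penalized least-squares baseline.

    Iterates a weighted Whittaker smoother (second-difference penalty
    ``lam``) whose weights progressively ignore points above the running
    baseline, so positive transients do not drag the baseline up.  Stops
    when the mass of negative residuals falls below 0.1% of the total
    signal mass or after ``max_iter`` iterations.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 10:
        raise ValueError("series must be 1-d with length >= 10")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    n = len(y)
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    H = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for it in range(1, max_iter + 1):
        W = sparse.diags(w, 0, format="csc")
        z = spsolve(W + H, w * y)
        d = y - z
        neg = d < 0
        dssn = float(np.abs(d[neg]).sum())
        if dssn < 0.001 * float(np.abs(y).sum()) or not neg.any():
            break
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(d[neg]) / dssn)
        w[0] = np.exp(it * np.abs(d[neg]).max() / dssn)
        w[-1] = w[0]
    return z


def isosbestic_correct(signal_470: np.ndarray,
                       reference_415: np.ndarray) -> np.ndarray:
    """Subtract the robust linear projection of the reference channel.

    Both channels should already be detrended.  Uses a Huber-loss robust
    regression so transients in the signal channel do not bias the artifact
    fit.  A zero-variance reference skips the regression with a warning.
    """
    s = np.asarray(signal_470, dtype=float)
    ref = np.asarray(reference_415, dtype=float)
    if s.shape != ref.shape:
        raise ValueError("channels must have equal length")
    if ref.std() < 1e-12:
        warnings.warn("reference channel has zero variance; skipping "
                      "isosbestic regression")
        return s.copy()
    X = sm.add_constant(ref)
    fit = sm.RLM(s, X, M=sm.robust.norms.HuberT()).fit()
    return s - fit.fittedvalues


def zscore_session(series: np.ndarray) -> np.ndarray:
    """Z-score a whole-session trace (mean 0, SD 1; per-session semantics)."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (x - x.mean()) / sd


def preprocess(signal_470: np.ndarray, reference_415: np.ndarray,
               lam: float = 1e8, max_iter: int = 50) -> np.ndarray:
    """Full chain: airPLS detrend both channels -> robust isosbestic
    correction -> per-session z-score.  Returns Z(DA)."""
    s = np.asarray(signal_470, dtype=float)
    ref = np.asarray(reference_415, dtype=float)
    s_d = s - airpls_baseline(s, lam=lam, max_iter=max_iter)
    ref_d = ref - airpls_baseline(ref, lam=lam, max_iter=max_iter)
    corrected = isosbestic_correct(s_d, ref_d)
    return zscore_session(corrected)


class PhotometrySession:
    """Paired 470/415 nm traces at a fixed rate plus per-trial event times."""

    def __init__(self, signal_470: np.ndarray, reference_415: np.ndarray,
                 timestamps: np.ndarray, events: Optional[pd.DataFrame] = None,
                 sampling_rate: float = SAMPLING_RATE):
        signal_470 = np.asarray(signal_470, float)
        reference_415 = np.asarray(reference_415, float)
        timestamps = np.asarray(timestamps, float)
        if not (len(signal_470) == len(reference_415) == len(timestamps)):
            raise ValueError("channels and timestamps must share a length")
        if np.any(np.diff(timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        dt = np.diff(timestamps)
        if np.abs(dt.mean() - 1.0 / sampling_rate) > 0.2 / sampling_rate:
            raise ValueError("timestamps inconsistent with declared rate")
        self.signal_470 = signal_470
        self.reference_415 = reference_415
        self.timestamps = timestamps
        self.events = events
        self.sampling_rate = sampling_rate

    def zda(self, lam: float = 1e8) -> np.ndarray:
        return preprocess(self.signal_470, self.reference_415, lam=lam)


def align_to_event(series: np.ndarray, timestamps: np.ndarray,
                   event_times: np.ndarray, window: Tuple[float, float],
                   rate: float = SAMPLING_RATE, de_base: bool = False):
    """Interpolate a trace onto a fixed grid around each event.

    Returns ``(matrix, offsets)`` with one row per event and grid spacing
    ``1/rate``.  Samples falling outside the recording are NaN (an event
    entirely outside the span warns and yields an all-NaN row).  With
    ``de_base`` the value at the event time is subtracted from its row.
    """
    series = np.asarray(series, float)
    timestamps = np.asarray(timestamps, float)
    event_times = np.asarray(event_times, float)
    pre, post = window
    offsets = np.arange(-round(pre * rate), round(post * rate) + 1) / rate
    out = np.full((len(event_times), len(offsets)), np.nan)
    t0, t1 = timestamps[0], timestamps[-1]
    for i, ev in enumerate(event_times):
        if np.isnan(ev):
            continue
        if ev < t0 or ev > t1:
            warnings.warn(f"event at {ev:.3f}s outside recording span "
                          f"[{t0:.3f}, {t1:.3f}]")
            continue
        grid = ev + offsets
        inside = (grid >= t0) & (grid <= t1)
        out[i, inside] = np.interp(grid[inside], timestamps, series)
        if de_base:
            base = np.interp(ev, timestamps, series)
            out[i] -= base
    return out, offsets


def da_peak_trough(aligned_row: np.ndarray, offsets: np.ndarray,
                   rewarded: bool, window: float = 1.0) -> float:
    """Peak (rewarded) or trough (unrewarded) in the post-event window."""
    sel = (offsets >= 0) & (offsets <= window)
    vals = np.asarray(aligned_row, float)[sel]
    if np.all(np.isnan(vals)):
        return np.nan
    return float(np.nanmax(vals) if rewarded else np.nanmin(vals))


def session_quality_auc(signal_470: np.ndarray,
                        reference_415: np.ndarray) -> float:
    """AUC-ROC separating signal-channel from rescaled reference samples.

    A session-quality screen, reported for inspection: both (detrended)
    channels are rescaled robustly (median/MAD, so the bulk distributions
    match) and the statistic is P(signal sample > reference sample) — the
    Mann-Whitney U normalised by the number of pairs.  Real fluorescence
    transients give the signal channel a longer right tail than the
    dopamine-blind reference, pushing the value above 0.5;
    artifact-dominated sessions sit at 0.5.
    """
    from scipy.stats import mannwhitneyu

    def _rescale(x):
        x = np.asarray(x, dtype=float)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        return (x - med) / (mad if mad > 0 else 1.0)

    s = _rescale(signal_470)
    ref = _rescale(reference_415)
    u = mannwhitneyu(s, ref, alternative="greater").statistic
    return float(u / (len(s) * len(ref)))


def compute_durations(records: pd.DataFrame) -> pd.DataFrame:
    """Derive MVMT/ITI/center_dur/port_dur/SO_lat from the event columns."""
    df = records.sort_values(["subject_id", "session_id", "trial"],
                             kind="stable").reset_index(drop=True)
    df["center_dur"] = df["CO"] - df["CI"]
    df["port_dur"] = df["SO1"] - df["O"]
    df["SO_lat"] = df["SO1"] - df["SO0"]
    grp = df.groupby(["subject_id", "session_id"], sort=False)
    df["MVMT"] = df["CI"] - grp["SOf"].shift(1)
    df["ITI"] = df["CI"] - grp["SO1"].shift(1)
    return df


#: Inclusive upper bounds on trial durations (seconds) for the quality
#: filter: brief center poke, bounded port lingering, bounded travel, and a
#: single clean side-poke bout.
DEFAULT_FILTERS: Dict[str, float] = {
    "center_dur": 0.8,
    "port_dur": 6.0,
    "MVMT": 3.0,
    "SO_lat": 1.0,
}


def filter_trials(records: pd.DataFrame,
                  thresholds: Optional[Dict[str, float]] = None):
    """Keep trials whose durations pass every (inclusive <=) threshold.

    Missing durations do not fail a rule.  Returns ``(kept, report)`` where
    the report counts rejections per rule and in total (a trial may fail
    several rules; the kept count is total minus the union of failures).
    """
    thresholds = thresholds if thresholds is not None else DEFAULT_FILTERS
    df = records.reset_index(drop=True)
    fail_any = np.zeros(len(df), dtype=bool)
    report = {}
    for col, thresh in thresholds.items():
        if col not in df.columns:
            report[col] = 0
            continue
        failed = (df[col] > thresh).fillna(False).to_numpy()
        report[col] = int(failed.sum())
        fail_any |= failed
    kept = df[~fail_any].reset_index(drop=True)
    report["n_total"] = int(len(df))
    report["n_rejected"] = int(fail_any.sum())
    report["n_kept"] = int(len(kept))
    return kept, report
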