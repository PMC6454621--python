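"""Raw-session preprocessing: filtering, artifact blanking, spike detection
and sorting, boxcar firing-rate estimation, SNR and trial selection.

The microneurogram is band-passed with a zero-phase third-order Butterworth
filter (700-2000 Hz), artifacts are blanked with a 4 ms window, spikes are
detected by a robust amplitude threshold and clustered into putative
motoneurons, and firing rates are estimated with a centered 100 ms boxcar
kernel (spike count per window divided by the window length).

SNR follows the interval-maxima definition: the trace is fragmented into
100 ms intervals and SNR is the mean of per-interval absolute maxima during
activity divided by the same mean during rest. A repetition enters the
behavioral analysis only if its SNR exceeds 1 and the task was executed
correctly (pressure within +/-10% of the request for grasps, sEMG-envelope
peak within +/-10% of the repetition duration from the cue transition for
flexions); tolerance boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .protocols import ISOTONIC, ISOKINETIC
from .session import RecordingSession, MNG_FS

__all__ = [
    "bandpass_filter", "blank_artifacts", "detect_and_sort",
    "estimate_firing_rate", "compute_snr", "select_trials",
    "most_correlated_muscle", "envelope", "SortedUnit", "SnrReport",
    "TrialSelection", "sort_session",
]

BAND = (700.0, 2000.0)
BLANK_WINDOW_S = 0.004
BOXCAR_S = 0.1
SNR_INTERVAL_S = 0.1
SNIPPET_S = 0.0016          # 1.6 ms waveform window
DETECTION_K = 4.0
MIN_CLUSTER_SPIKES = 10
FR_GRID_DT = 0.001


def bandpass_filter(x, fs: float = MNG_FS, low: float = BAND[0],
                    high: float = BAND[1], order: int = 3) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} too low for high cutoff {high}")
    sos = sp_signal.butter(order, (low, high), btype="bandpass", fs=fs,
                           output="sos")
    return sp_signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def blank_artifacts(x, threshold: float, fs: float = MNG_FS,
                    window_s: float = BLANK_WINDOW_S):
    """Zero out a centered window around supra-threshold events.

    Events are samples where |x| exceeds ``threshold``; overlapping windows
    are merged. Returns ``(blanked, artifact_times)``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(x, dtype=float)
    idx = np.flatnonzero(np.abs(x) > threshold)
    y = x.copy()
    if idx.size == 0:
        return y, np.empty(0)
    half = int(round(window_s / 2 * fs))
    # merge overlapping [i-half, i+half] intervals
    starts = idx - half
    stops = idx + half + 1
    merged = []
    cur_a, cur_b = starts[0], stops[0]
    for a, b in zip(starts[1:], stops[1:]):
        if a <= cur_b:
            cur_b = max(cur_b, b)
        else:
            merged.append((cur_a, cur_b))
            cur_a, cur_b = a, b
    merged.append((cur_a, cur_b))
    for a, b in merged:
        y[max(a, 0):min(b, len(y))] = 0.0
    return y, idx / fs


def robust_noise_sd(x) -> float:
    """Median-absolute-deviation estimate of the noise standard deviation."""
    return float(np.median(np.abs(x)) / 0.6745)


@dataclass
class SortedUnit:
    unit_id: int
    spike_times: np.ndarray            # s, strictly increasing
    template: np.ndarray               # mean waveform snippet
    fs: float = MNG_FS

    def firing_rate(self, t_grid: np.ndarray,
                    kernel_width: float = BOXCAR_S) -> np.ndarray:
        return estimate_firing_rate(self.spike_times, t_grid, kernel_width)


def _detect_events(x, fs: float, detection_k: float):
    """Threshold crossings of |x|, aligned to the local trough, with a 1 ms
    dead time."""
    sd = robust_noise_sd(x)
    thr = detection_k * sd
    above = np.abs(x) > thr
    if not above.any():
        return np.empty(0, dtype=int), thr
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    if above[0]:
        edges = np.insert(edges, 0, 0)
    half = int(round(SNIPPET_S / 2 * fs))
    dead = int(round(0.001 * fs))
    peaks, last = [], -dead - 1
    for e in edges:
        a, b = e, min(e + half, len(x))
        if b <= a:
            continue
        p = a + int(np.argmin(x[a:b]))      # align to trough
        if p - last > dead:
            peaks.append(p)
            last = p
    return np.asarray(peaks, dtype=int), thr


def _snippets(x, peaks, fs: float):
    half = int(round(SNIPPET_S / 2 * fs))
    keep = (peaks >= half) & (peaks < len(x) - half)
    peaks = peaks[keep]
    snips = np.stack([x[p - half:p + half] for p in peaks]) if peaks.size \
        else np.empty((0, 2 * half))
    return snips, peaks


def _drop_shadowed_events(snips, peaks, fs, window_s=0.003, ratio=2.0):
    """Drop detections dwarfed by a much larger event a few ms away.

    The band-pass filter rings, so the secondary lobes of large spikes can
    re-cross the detection threshold outside the dead time; those echoes
    are identifiable as events with a >``ratio``-fold larger neighbour.
    """
    if len(peaks) == 0:
        return snips, peaks
    amp = np.abs(snips.min(axis=1))
    win = int(round(window_s * fs))
    keep = np.ones(len(peaks), dtype=bool)
    for i in range(len(peaks)):
        lo = np.searchsorted(peaks, peaks[i] - win)
        hi = np.searchsorted(peaks, peaks[i] + win)
        for j in range(lo, hi):
            if j != i and amp[j] >= ratio * amp[i]:
                keep[i] = False
                break
    return snips[keep], peaks[keep]


def _merge_similar_clusters(snips, labels, shape_thresh: float = 0.8,
                            amp_ratio: float = 1.25):
    """Merge clusters whose members are the same waveform.

    Alignment jitter can split one unit across k-means clusters (and dilute
    the mean template's amplitude unevenly); two clusters are merged when
    their templates' peak shift-invariant normalized cross-correlation
    exceeds ``shape_thresh`` and their median trough depths differ by less
    than ``amp_ratio``.
    """
    labels = labels.copy()
    trough = np.abs(snips.min(axis=1))
    changed = True
    while changed:
        changed = False
        uniq = np.unique(labels)
        templates = {u: snips[labels == u].mean(axis=0) for u in uniq}
        depths = {u: float(np.median(trough[labels == u])) for u in uniq}
        for i, a in enumerate(uniq):
            for b in uniq[i + 1:]:
                ta, tb = templates[a], templates[b]
                na, nb = np.linalg.norm(ta), np.linalg.norm(tb)
                if na == 0 or nb == 0:
                    continue
                cc = np.max(np.abs(np.correlate(ta / na, tb / nb, "full")))
                da, db = depths[a], depths[b]
                if cc >= shape_thresh and \
                        max(da, db) / max(min(da, db), 1e-12) <= amp_ratio:
                    labels[labels == b] = a
                    changed = True
                    break
            if changed:
                break
    return labels


def detect_and_sort(x, fs: float = MNG_FS, detection_k: float = DETECTION_K,
                    max_units: int = 5,
                    min_spikes: int = MIN_CLUSTER_SPIKES) -> list[SortedUnit]:
    """Amplitude-threshold detection and PCA + k-means waveform sorting.

    Spikes are detected at ``detection_k`` times the robust noise SD, aligned
    snippets of 1.6 ms are projected on their top principal directions and
    clustered with k-means for k = 1..max_units; k is selected by silhouette
    score. Clusters with fewer than ``min_spikes`` spikes are discarded.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    peaks, _thr = _detect_events(x, fs, detection_k)
    snips, peaks = _snippets(x, peaks, fs)
    snips, peaks = _drop_shadowed_events(snips, peaks, fs)
    if len(peaks) < min_spikes:
        return []
    n_pc = min(3, snips.shape[1], len(peaks) - 1)
    feats = PCA(n_components=n_pc, random_state=0).fit_transform(snips)
    best_k, best_labels, best_score = 1, np.zeros(len(peaks), dtype=int), -1.0
    for k in range(2, max_units + 1):
        if len(peaks) <= k:
            break
        km = KMeans(n_clusters=k, n_init=5, random_state=0).fit(feats)
        score = silhouette_score(feats, km.labels_,
                                 sample_size=min(len(peaks), 1500),
                                 random_state=0)
        if score > best_score:
            best_k, best_labels, best_score = k, km.labels_, score
    if best_score < 0.5:        # clusters not meaningfully separated
        best_k, best_labels = 1, np.zeros(len(peaks), dtype=int)
    best_labels = _merge_similar_clusters(snips, best_labels)
    # clusters below 2% of detections are overlap/collision residue
    min_keep = max(min_spikes, int(np.ceil(0.02 * len(peaks))))
    units = []
    uid = 0
    for lbl in np.unique(best_labels):
        sel = best_labels == lbl
        if sel.sum() < min_keep:
            continue
        template = snips[sel].mean(axis=0)
        # discard heterogeneous clusters (overlap/collision events)
        norm_t = template / (np.linalg.norm(template) + 1e-12)
        proj = snips[sel] @ norm_t
        consistency = np.median(
            proj / (np.linalg.norm(snips[sel], axis=1) + 1e-12))
        if consistency < 0.5:
            continue
        units.append(SortedUnit(unit_id=uid,
                                spike_times=peaks[sel] / fs,
                                template=template, fs=fs))
        uid += 1
    # stable ordering: largest template amplitude first
    units.sort(key=lambda u: -np.abs(u.template).max())
    for i, u in enumerate(units):
        u.unit_id = i
    return units


def estimate_firing_rate(spike_times, t_grid,
                         kernel_width: float = BOXCAR_S) -> np.ndarray:
    """Centered boxcar firing rate: FR(t) = spikes in [t - w/2, t + w/2)
    divided by the kernel width w."""
    if kernel_width <= 0:
        raise ValueError("kernel_width must be positive")
    st = np.asarray(spike_times, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if st.size == 0:
        return np.zeros_like(t)
    half = kernel_width / 2
    counts = np.searchsorted(st, t + half, side="left") - \
        np.searchsorted(st, t - half, side="left")
    return counts / kernel_width


@dataclass
class SnrReport:
    snr: float
    interval_ms: float = 100.0
    n_act: int = 0
    n_rest: int = 0

    def to_dict(self):
        return {"snr": self.snr, "interval_ms": self.interval_ms,
                "n_act": self.n_act, "n_rest": self.n_rest}


def _interval_maxima(x, fs, intervals, width_s):
    out = []
    for a, b in intervals:
        i0, i1 = int(round(a * fs)), min(int(round(b * fs)), len(x))
        seg = np.abs(x[i0:i1])
        w = int(round(width_s * fs))
        for s in range(0, len(seg) - w + 1, w):
            out.append(seg[s:s + w].max())
    return np.asarray(out)


def compute_snr(x, activity_intervals, rest_intervals, fs: float = MNG_FS,
                interval_ms: float = 100.0) -> SnrReport:
    """Interval-maxima SNR: mean of 100 ms |x| maxima during activity over
    the same mean during rest. Intervals come from the protocol timeline."""
    width = interval_ms / 1e3
    act = _interval_maxima(x, fs, activity_intervals, width)
    rest = _interval_maxima(x, fs, rest_intervals, width)
    if act.size == 0 or rest.size == 0:
        raise ValueError("need at least one activity and one rest interval")
    rest_mean = rest.mean()
    if rest_mean == 0.0:
        raise ZeroDivisionError("all rest maxima are zero; SNR undefined")
    return SnrReport(snr=float(act.mean() / rest_mean), interval_ms=interval_ms,
                     n_act=act.size, n_rest=rest.size)


def envelope(x, fs: float = MNG_FS, cutoff: float = 2.0) -> np.ndarray:
    """Signal envelope: rectification followed by a zero-phase 2 Hz
    second-order Butterworth low-pass."""
    sos = sp_signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, np.abs(np.asarray(x, dtype=float)))


def most_correlated_muscle(mng_env, semg_envs):
    """Index and Pearson r of the sEMG envelope most correlated with the
    MNG envelope."""
    mng_env = np.asarray(mng_env, dtype=float)
    if len(semg_envs) == 0:
        raise ValueError("need at least one sEMG channel")
    if mng_env.std() == 0.0:
        raise ValueError("zero-variance MNG envelope")
    rs = []
    for e in semg_envs:
        e = np.asarray(e, dtype=float)
        if e.shape != mng_env.shape:
            raise ValueError("envelope length mismatch")
        if e.std() == 0.0:
            raise ValueError("zero-variance sEMG envelope")
        rs.append(float(np.corrcoef(mng_env, e)[0, 1]))
    best = int(np.argmax(rs))
    return best, rs[best]


@dataclass
class TrialSelection:
    included: list[int]
    snr: list[float]
    pressure_ok: list[bool]
    timing_ok: list[bool]

    def to_dict(self):
        return {"included": self.included, "snr": self.snr,
                "pressure_ok": self.pressure_ok, "timing_ok": self.timing_ok}


def select_trials(session: RecordingSession, filtered_mng=None,
                  tolerance: float = 0.10) -> TrialSelection:
    """Apply the inclusion rule per repetition: SNR > 1 and correct task
    execution (both tolerance boundaries inclusive)."""
    proto = session.protocol
    fs = session.fs
    x = filtered_mng if filtered_mng is not None \
        else bandpass_filter(session.mng, fs=fs)
    rests = proto.rest_intervals()
    if proto.task == ISOTONIC and session.pressure.size == 0:
        raise ValueError("isotonic selection requires a pressure channel")
    semg_env = None
    if proto.task == ISOKINETIC:
        if not session.semg:
            raise ValueError("isokinetic selection requires an sEMG channel")
        mng_env = envelope(x, fs=fs)
        envs = [envelope(ch, fs=fs) for ch in session.semg]
        best, _ = most_correlated_muscle(mng_env, envs)
        semg_env = envs[best]
    snrs, p_ok, t_ok, included = [], [], [], []
    t_p = np.arange(len(session.pressure)) / session.pressure_fs
    for i, ((start, stop), level) in enumerate(zip(proto.cue_times,
                                                   proto.rep_levels)):
        rep = compute_snr(x, [(start, stop)], rests, fs=fs)
        snrs.append(rep.snr)
        if proto.task == ISOTONIC:
            # mean held pressure over the plateau (after the 1 s rise)
            m = (t_p >= start + 1.5) & (t_p < stop)
            held = float(session.pressure[m].mean()) if m.any() else 0.0
            ok = abs(held - level) <= tolerance * level + 1e-12
            p_ok.append(bool(ok))
            t_ok.append(True)
        else:
            i0, i1 = int(start * fs), int(stop * fs)
            seg = semg_env[i0:i1]
            t_max = start + float(np.argmax(seg)) / fs
            dur = stop - start
            ok = abs(t_max - stop) <= tolerance * dur + 1e-12
            t_ok.append(bool(ok))
            p_ok.append(True)
        if rep.snr > 1.0 and p_ok[-1] and t_ok[-1]:
            included.append(i)
    return TrialSelection(included=included, snr=snrs,
                          pressure_ok=p_ok, timing_ok=t_ok)


def sort_session(session: RecordingSession, detection_k: float = DETECTION_K,
                 blank_threshold: float | None = None,
                 max_units: int = 5):
    """Full preprocessing of one session: band-pass, optional blanking,
    detection and sorting. Returns ``(units, filtered_signal)``."""
    x = bandpass_filter(session.mng, fs=session.fs)
    if blank_threshold is not None:
        x, _ = blank_artifacts(x, blank_threshold, fs=session.fs)
    units = detect_and_sort(x, fs=session.fs, detection_k=detection_k,
                            max_units=max_units)
    return units, x
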