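"""Fully ground-truthed synthetic microneurography sessions.

The generator emulates the study conditions the analysis assumes: isotonic
grasps at 1/2/4/6 kPa (11 s repetitions, 2 s rests) and isokinetic flexions
at 17/26/47 deg/s, motoneuron trains whose rates follow the saturating
rate-force law during grasps and a constant-peak / velocity-proportional-
slope ramp during flexions, extracellular templates summed with band-limited
noise into a 10 kHz microneurogram, an sEMG channel whose envelope correlates
with the MNG envelope at a configurable Pearson target (default 0.6), and a
10 Hz pressure readout with 10% multiplicative hold noise.

Everything is reproducible: one session seed deterministically spawns
per-fiber and per-channel substreams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .characterize import fr_force_curve
from .protocols import ProtocolTimeline, ISOTONIC, ISOKINETIC
from .session import RecordingSession, MNG_FS, PRESSURE_FS

__all__ = [
    "WaveformTemplate", "default_templates", "generate_ground_truth_trains",
    "render_spike_trains", "synthesize_population_recording",
    "synthesize_session", "CorrelationTargetError", "RATE_LAWS",
]

RATE_GRID_DT = 0.001           # s, rate-profile resolution
#: generating rate-force parameters (A, B, C, D) of the saturation law
DEFAULT_GEN_PARAMS = (0.5, 1.0, 1.0, 0.2)
DEFAULT_PEAK_RATE = 25.0       # Hz, per-unit peak during the strongest grasp
DEFAULT_PLATEAU_FRAC = 0.6     # holding-phase rate as a fraction of the peak
DEFAULT_REST_RATE = 1.0        # Hz, spontaneous background
RISE_S = 0.8                   # reaching-phase rise time, isotonic
DECAY_TAU_S = 0.8              # peak-to-plateau decay constant


@dataclass
class WaveformTemplate:
    """Extracellular single-fiber spike template at 10 kHz.

    Zero-mean, biphasic difference-of-Gaussians shape of ~1.2 ms; stands in
    for volume-conducted single-fiber waveforms.
    """

    samples: np.ndarray
    fs: float = MNG_FS
    peak_amplitude: float = 1.0

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.fs * 1e3


def _gauss_template(width_ms: float, lobes: int, skew: float,
                    amplitude: float, fs: float = MNG_FS) -> WaveformTemplate:
    n = max(int(round(width_ms * 1e-3 * fs)), 7)
    t = np.linspace(-1.0, 1.0, n)
    if lobes == 2:
        w = (-np.exp(-((t + skew) ** 2) / (2 * 0.18 ** 2))
             + 0.7 * np.exp(-((t - skew) ** 2) / (2 * 0.30 ** 2)))
    else:  # triphasic
        w = (0.5 * np.exp(-((t + 0.5) ** 2) / (2 * 0.15 ** 2))
             - np.exp(-(t ** 2) / (2 * 0.15 ** 2))
             + 0.5 * np.exp(-((t - 0.5) ** 2) / (2 * 0.15 ** 2)))
        w = w * (1.0 + skew * t)
    w -= w.mean()
    w /= np.abs(w).max()
    return WaveformTemplate(samples=w * amplitude, fs=fs,
                            peak_amplitude=amplitude)


def default_templates(n: int, fs: float = MNG_FS,
                      cycle: bool = False) -> list[WaveformTemplate]:
    """Family of mutually distinguishable bi-/triphasic templates (pairwise
    normalized cross-correlation < 0.9).

    With ``cycle`` the five base shapes are reused for n > 5 fibers (large
    pools of similar fibers; distinctness then no longer holds pairwise).
    """
    # widths, lobe counts and asymmetries chosen so shapes, not only
    # amplitudes, differ
    params = [
        (1.2, 2, 0.35, 1.0),
        (1.6, 3, 0.20, 0.65),
        (1.0, 2, 0.15, 1.4),
        (2.4, 3, -0.50, 0.85),
        (1.4, 2, 0.55, 1.15),
    ]
    if n > len(params) and not cycle:
        raise ValueError(f"at most {len(params)} distinct default templates "
                         "available (pass cycle=True for larger pools)")
    return [_gauss_template(*params[i % len(params)], fs=fs)
            for i in range(n)]


def template_cross_correlation(a: WaveformTemplate,
                               b: WaveformTemplate) -> float:
    """Peak normalized cross-correlation over all lags."""
    x = a.samples / np.linalg.norm(a.samples)
    y = b.samples / np.linalg.norm(b.samples)
    return float(np.max(np.abs(np.correlate(x, y, mode="full"))))


# ---------------------------------------------------------------------------
# rate laws and point-process ground truth

def _isotonic_rep_rate(t_rel: np.ndarray, level: float, max_level: float,
                       gen_params, peak_rate, plateau_frac) -> np.ndarray:
    """Peak-then-plateau profile; peak scales with force by the saturation law."""
    f_norm = level / max_level
    scale = (fr_force_curve(f_norm, *gen_params)
             / fr_force_curve(1.0, *gen_params))
    peak = peak_rate * scale
    plateau = plateau_frac * peak
    r = np.where(
        t_rel < RISE_S,
        peak * t_rel / RISE_S,
        plateau + (peak - plateau) * np.exp(-(t_rel - RISE_S) / DECAY_TAU_S),
    )
    return np.clip(r, 0.0, None)


def rate_profile(protocol: ProtocolTimeline, rate_law: str,
                 gen_params=DEFAULT_GEN_PARAMS,
                 peak_rate: float = DEFAULT_PEAK_RATE,
                 plateau_frac: float = DEFAULT_PLATEAU_FRAC,
                 rest_rate: float = DEFAULT_REST_RATE,
                 constant_rate: float = 10.0,
                 sim_rate: np.ndarray | None = None) -> np.ndarray:
    """Underlying firing rate (Hz) on a 1 ms grid over the whole protocol.

    rate_law: "saturating_isotonic" | "ramp_isokinetic" | "constant" |
    "from_simulation".
    """
    n = int(round(protocol.total_duration / RATE_GRID_DT))
    t = np.arange(n) * RATE_GRID_DT
    if rate_law == "constant":
        return np.full(n, float(constant_rate))
    if rate_law == "from_simulation":
        if sim_rate is None:
            raise ValueError("from_simulation requires sim_rate")
        return np.interp(t, np.arange(len(sim_rate)) * RATE_GRID_DT, sim_rate)
    if rate_law not in ("saturating_isotonic", "ramp_isokinetic"):
        raise ValueError(f"unknown rate_law {rate_law!r}")
    rate = np.full(n, float(rest_rate))
    max_level = max(protocol.levels)
    for (start, stop), level in zip(protocol.cue_times, protocol.rep_levels):
        sl = slice(int(round(start / RATE_GRID_DT)),
                   int(round(stop / RATE_GRID_DT)))
        t_rel = t[sl] - start
        if rate_law == "saturating_isotonic":
            rate[sl] = np.maximum(
                _isotonic_rep_rate(t_rel, level, max_level, gen_params,
                                   peak_rate, plateau_frac), rest_rate)
        else:
            # constant peak, slope proportional to velocity: linear rise to
            # a level-independent peak over the flexion duration
            dur = stop - start
            rate[sl] = np.maximum(peak_rate * t_rel / dur, rest_rate)
    return rate


def _poisson_times(rate: np.ndarray, dt: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson realization by thinning."""
    lam_max = float(rate.max())
    if lam_max <= 0:
        return np.empty(0)
    duration = len(rate) * dt
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    lam_at = rate[np.minimum((cand / dt).astype(int), len(rate) - 1)]
    keep = rng.uniform(0.0, lam_max, size=n_cand) < lam_at
    return cand[keep]


def generate_ground_truth_trains(protocol: ProtocolTimeline, n_units: int,
                                 rate_law: str, seed: int,
                                 rate_jitter: float = 0.15,
                                 **rate_kwargs) -> list[np.ndarray]:
    """Per-unit spike-time lists from independent inhomogeneous Poisson
    processes sharing the protocol's rate law.

    Units get a multiplicative rate scale drawn from U(1-j, 1+j) with
    j = ``rate_jitter`` to emulate across-unit heterogeneity.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    base = rate_profile(protocol, rate_law, **rate_kwargs)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(n_units)]
    trains = []
    for rng in streams:
        scale = 1.0 + rate_jitter * (2 * rng.uniform() - 1.0)
        trains.append(_poisson_times(base * scale, RATE_GRID_DT, rng))
    return trains


# ---------------------------------------------------------------------------
# voltage-trace construction

def render_spike_trains(trains, templates, duration: float,
                        fs: float = MNG_FS) -> np.ndarray:
    """Sum every independent spike train convolved with its fiber template."""
    if len(trains) != len(templates):
        raise ValueError("one template per fiber required")
    n = int(round(duration * fs))
    trace = np.zeros(n)
    for times, tpl in zip(trains, templates):
        w = tpl.samples
        half = len(w) // 2
        for t in np.asarray(times, dtype=float):
            i0 = int(round(t * fs)) - half
            a, b = max(i0, 0), min(i0 + len(w), n)
            if a < b:
                trace[a:b] += w[a - i0:b - i0]
    return trace


def band_limited_noise(n: int, sd: float, rng: np.random.Generator,
                       band=(300.0, 3000.0), fs: float = MNG_FS) -> np.ndarray:
    """White Gaussian noise band-limited to the hardware filter band."""
    if sd == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = sp_signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, white)
    return x * (sd / x.std())


def synthesize_population_recording(n_fibers: int, mean_rates, templates,
                                    noise_sd: float, duration: float,
                                    seed: int, fs: float = MNG_FS):
    """Population voltage trace from homogeneous-Poisson fibers.

    Returns ``(trace, trains)``; ``trains`` is the embedded ground truth.
    """
    mean_rates = list(mean_rates)
    if len(mean_rates) != n_fibers or len(templates) != n_fibers:
        raise ValueError("template/rate/fiber count mismatch")
    if any(not (0.0 < r <= 100.0) for r in mean_rates):
        raise ValueError("mean rates must lie in (0, 100] Hz")
    ss = np.random.SeedSequence(seed).spawn(n_fibers + 1)
    trains = []
    for rate, s in zip(mean_rates, ss[:-1]):
        rng = np.random.default_rng(s)
        n_sp = rng.poisson(rate * duration)
        trains.append(np.sort(rng.uniform(0.0, duration, size=n_sp)))
    trace = render_spike_trains(trains, templates, duration, fs=fs)
    trace += band_limited_noise(len(trace), noise_sd,
                                np.random.default_rng(ss[-1]), fs=fs)
    return trace, trains


class CorrelationTargetError(ValueError):
    """Requested MNG-sEMG envelope correlation could not be realized."""


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0.0:
        raise CorrelationTargetError("zero-variance envelope")
    return (x - x.mean()) / sd


def _make_semg(mng_env: np.ndarray, corr_target: float,
               rng: np.random.Generator, fs: float) -> np.ndarray:
    """sEMG channel = target envelope times a 100-1000 Hz noise carrier.

    The target envelope mixes the standardized MNG envelope with an
    independent envelope so the envelope-envelope Pearson correlation hits
    ``corr_target``. Because the envelope operator (rectify + 2 Hz
    low-pass) and positivity clipping re-correlate the channels, the mixing
    weight is corrected by a few secant iterations on the measured
    correlation of the fully synthesized channel.
    """
    from .preprocess import envelope

    if corr_target >= 1.0 - 1e-12:
        # degenerate limit: an sEMG whose envelope IS the MNG envelope
        return np.clip(mng_env, 0.0, None).copy()
    carrier = band_limited_noise(len(mng_env), 1.0, rng,
                                 band=(100.0, 1000.0), fs=fs)
    noise_env = envelope(band_limited_noise(len(mng_env), 1.0, rng,
                                            band=(100.0, 1000.0), fs=fs),
                         fs=fs)
    z_m, z_n = _standardize(mng_env), _standardize(noise_env)

    def realize(w):
        mix = _standardize(w * z_m + (1.0 - w) * z_n)
        env = np.clip(mng_env.mean() + mng_env.std() * mix, 0.0, None)
        semg = env * carrier
        got = float(np.corrcoef(envelope(semg, fs=fs), mng_env)[0, 1])
        return semg, got

    rp = corr_target / np.sqrt(1.0 - corr_target ** 2)
    w = rp / (1.0 + rp)
    semg, got = realize(w)
    w_prev, got_prev = 1.0, 1.0          # w=1 reproduces the MNG envelope
    for _ in range(4):
        if abs(got - corr_target) < 0.02 or got == got_prev:
            break
        w_new = np.clip(w + (corr_target - got) * (w_prev - w)
                        / (got_prev - got), 0.0, 1.0)
        w_prev, got_prev = w, got
        w = float(w_new)
        semg, got = realize(w)
    return semg


def synthesize_session(protocol: ProtocolTimeline, trains, templates,
                       noise_sd: float = 0.1, semg_corr_target: float = 0.6,
                       n_semg: int = 2, seed: int = 0,
                       corr_tolerance: float = 0.1,
                       check_corr: bool = True) -> RecordingSession:
    """Assemble a complete synthetic recording session.

    MNG = summed templated trains + band-limited noise; first sEMG channel
    targets the requested envelope correlation with the MNG, further channels
    get progressively weaker targets; the pressure channel follows the
    commanded isotonic profile with 10% multiplicative hold noise. Raises
    :class:`CorrelationTargetError` when the measured envelope correlation of
    the first channel misses the target by more than ``corr_tolerance``.
    """
    from .preprocess import envelope

    if not (0.0 < semg_corr_target <= 1.0):
        raise ValueError("semg_corr_target must lie in (0, 1]")
    protocol.validate()
    duration = protocol.total_duration
    fs = MNG_FS
    ss = np.random.SeedSequence([seed, 1234]).spawn(n_semg + 2)
    mng = render_spike_trains(trains, templates, duration, fs=fs)
    mng = mng + band_limited_noise(len(mng), noise_sd,
                                   np.random.default_rng(ss[0]), fs=fs)
    mng_env = envelope(mng, fs=fs)
    semg = []
    for k in range(n_semg):
        target = semg_corr_target * (0.5 ** k)
        semg.append(_make_semg(mng_env, target,
                               np.random.default_rng(ss[1 + k]), fs))
    if check_corr and n_semg >= 1:
        got = float(np.corrcoef(envelope(semg[0], fs=fs), mng_env)[0, 1])
        if abs(got - semg_corr_target) > corr_tolerance:
            raise CorrelationTargetError(
                f"measured envelope correlation {got:.3f} misses target "
                f"{semg_corr_target:.3f} by more than {corr_tolerance}")

    p_rng = np.random.default_rng(ss[-1])
    n_p = int(round(duration * PRESSURE_FS))
    t_p = np.arange(n_p) / PRESSURE_FS
    pressure = np.zeros(n_p)
    if protocol.task == ISOTONIC:
        for (start, stop), level in zip(protocol.cue_times,
                                        protocol.rep_levels):
            in_rep = (t_p >= start) & (t_p < stop)
            t_rel = t_p[in_rep] - start
            ramp = np.clip(t_rel / 1.0, 0.0, 1.0)   # 1 s rise to target
            hold = level * (1.0 + 0.1 * p_rng.standard_normal(in_rep.sum()))
            pressure[in_rep] = ramp * hold

    gt = {f"unit{i}": np.asarray(tr, dtype=float)
          for i, tr in enumerate(trains)}
    sess = RecordingSession(mng=mng, semg=semg, pressure=pressure,
                            protocol=protocol, ground_truth=gt, seed=seed)
    sess.validate()
    return sess


RATE_LAWS = ("saturating_isotonic", "ramp_isokinetic", "constant", "from_simulation")
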