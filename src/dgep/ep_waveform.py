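"""Per-sweep evoked-potential feature extraction.

A dentate-gyrus evoked potential consists of a slow positive field EPSP
(fEPSP) with one or more sharp negative population spikes (PS) riding on
it. This module locates the waveform landmarks, fits the rising-phase
fEPSP slope by ordinary least squares, and integrates each population
spike as the area enclosed between the trace and the tangent joining the
flanking positive peaks.

Conventions
-----------
* Traces are oriented so the fEPSP is positive-going
  (``AnalysisConfig.invert`` flips inverted recordings).
* Landmark times in :class:`EPFeatures` are reported in milliseconds
  after stimulus onset.
* The fEPSP peak is the first positive local maximum after onset: when
  population spikes are present this is the positive inflection just
  before the first spike, which bounds the uncontaminated rising phase.
* PS area is ``∫ max(tangent(t) − V(t), 0) dt`` over the inter-peak
  interval (trapezoidal rule, mV·ms), summed over spikes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .errors import (InsufficientRise, MalformedLandmarks,
                     NoResponseDetected)

__all__ = ["Sweep", "Landmarks", "EPFeatures", "detect_landmarks",
           "fit_fepsp_slope", "population_spike_area", "extract_features",
           "features_table"]


@dataclass
class Sweep:
    """One evoked-potential voltage trace with stimulus metadata."""

    samples: np.ndarray          #: voltage trace, mV
    sample_rate: float           #: Hz
    stim_time: float             #: stimulus onset within the trace, s
    intensity: float             #: stimulation intensity, µA
    pulse: str                   #: "a" (conditioning) or "b" (test)
    session: str
    repetition: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not 0 <= self.stim_time < self.samples.size / self.sample_rate:
            raise ValueError("stim_time outside trace")
        if self.pulse not in ("a", "b"):
            raise ValueError(f"pulse must be 'a' or 'b', got {self.pulse!r}")

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms from trace start."""
        return np.arange(self.samples.size) / self.sample_rate * 1e3


@dataclass
class Landmarks:
    """Sample-index landmarks of one sweep (indices into ``samples``)."""

    artifact_end: int
    onset: int
    peak: int
    #: per population spike: (left positive peak, trough, right positive peak)
    ps: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass
class EPFeatures:
    """Extracted features of one sweep (latencies in ms post-stimulus)."""

    fepsp_onset: float
    fepsp_peak: float
    fepsp_slope: float           #: mV/ms
    ps_events: list[dict]        #: left_peak_t, trough_t, right_peak_t, area
    ps_area_total: float         #: mV·ms
    n_population_spikes: int


def _oriented(sweep: Sweep, cfg: AnalysisConfig) -> np.ndarray:
    return -sweep.samples if cfg.invert else sweep.samples


def _smoothed(x: np.ndarray, sample_rate: float, smooth_ms: float
              ) -> np.ndarray:
    """Boxcar-smoothed copy used only for landmark search.

    Landmark positions of symmetric deflections move by well under one
    sample; slope and area are always computed on the raw trace.
    """
    m = int(round(smooth_ms * sample_rate / 1e3))
    if m <= 1:
        return x
    if m % 2 == 0:
        m += 1  # symmetric kernel: no phase shift
    kernel = np.full(m, 1.0 / m)
    return np.convolve(np.pad(x, m // 2, mode="edge"), kernel, mode="valid")


def detect_landmarks(sweep: Sweep, cfg: AnalysisConfig | None = None
                     ) -> Landmarks:
    """Locate artifact end, fEPSP onset/peak and PS peaks/troughs.

    Troughs are negative local extrema with prominence at least
    ``cfg.min_prominence`` inside the post-stimulus search window; each
    is flanked by the nearest positive local maxima (falling back to the
    maximal sample on that side when the trace is monotone there).

    Raises
    ------
    NoResponseDetected
        If the post-blanking response amplitude relative to the
        pre-stimulus baseline is below ``cfg.min_response_mV``.
    """
    cfg = cfg or AnalysisConfig()
    x = _oriented(sweep, cfg)
    fs = sweep.sample_rate
    stim_i = int(round(sweep.stim_time * fs))
    blank_end = stim_i + int(round(cfg.blank_ms * fs / 1e3))
    search_lo = stim_i + int(round(cfg.search_lo_ms * fs / 1e3))
    win_end = min(x.size, stim_i + int(round(cfg.analysis_window_ms * fs / 1e3)))
    if blank_end >= win_end:
        raise NoResponseDetected("analysis window empty after blanking")

    xs = _smoothed(x, fs, cfg.smooth_ms)
    baseline = float(np.median(x[:stim_i])) if stim_i > 0 else float(x[0])
    seg = x[blank_end:win_end]
    if seg.size == 0 or float(seg.max()) - baseline < cfg.min_response_mV:
        raise NoResponseDetected(
            f"response amplitude below {cfg.min_response_mV} mV")

    # pre-stimulus noise scale of the smoothed trace (0 for noiseless
    # input), used to raise detection thresholds above the noise floor
    m_pad = int(round(cfg.smooth_ms * fs / 1e3)) + 1
    pre = xs[:max(0, stim_i - m_pad)]
    noise_sd = float(pre.std()) if pre.size > 3 else 0.0
    prominence = max(cfg.min_prominence, cfg.noise_prominence_k * noise_sd)

    # peak/trough search on the smoothed copy, restricted to
    # [search_lo, win_end)
    lo = max(search_lo, blank_end)
    sub = xs[lo:win_end]
    pos_peaks, _ = find_peaks(sub, prominence=prominence)
    troughs, _ = find_peaks(-sub, prominence=prominence)
    pos_peaks = pos_peaks + lo
    troughs = troughs + lo

    # fEPSP peak: first positive local maximum; monotone rise -> argmax
    if pos_peaks.size:
        peak = int(pos_peaks[0])
    else:
        peak = int(lo + np.argmax(sub))

    # onset: first post-blanking sample exceeding onset_frac of peak
    # amplitude (or the noise floor, whichever is higher)
    amp = xs[peak] - baseline
    thresh = baseline + max(cfg.onset_frac * amp,
                            cfg.onset_noise_k * noise_sd)
    rise = np.nonzero(xs[blank_end:peak + 1] >= thresh)[0]
    onset = int(blank_end + (rise[0] if rise.size else 0))
    if onset >= peak:
        onset = max(blank_end, peak - 1)

    ps: list[tuple[int, int, int]] = []
    for tr in troughs:
        left_c = pos_peaks[pos_peaks < tr]
        right_c = pos_peaks[pos_peaks > tr]
        if left_c.size:
            left = int(left_c[-1])
        elif tr > lo:
            left = int(lo + np.argmax(xs[lo:tr]))
        else:
            left = -1
        if right_c.size:
            right = int(right_c[0])
        elif tr + 1 < win_end:
            right = int(tr + 1 + np.argmax(xs[tr + 1:win_end]))
        else:
            right = -1
        if left < 0 or right < 0 or not (left < tr < right):
            continue  # trough at window edge without flanks: drop
        ps.append((left, int(tr), right))

    return Landmarks(artifact_end=blank_end, onset=onset, peak=peak, ps=ps)


def fit_fepsp_slope(sweep: Sweep, landmarks: Landmarks,
                    cfg: AnalysisConfig | None = None) -> float:
    """Ordinary-least-squares slope of the fEPSP rising phase, mV/ms.

    The fitted span runs from the first crossing of ``rise_lo`` to the
    first crossing of ``rise_hi`` of the peak amplitude (defaults
    20–80%), which avoids onset curvature and population-spike
    contamination. The window is delimited on the smoothed detection
    copy — a raw noisy trace crosses any level many times — while the
    least-squares fit itself runs on the raw samples. Invariant to DC
    offset and exact for noiseless linear ramps.
    """
    cfg = cfg or AnalysisConfig()
    x = _oriented(sweep, cfg)
    fs = sweep.sample_rate
    xs = _smoothed(x, fs, cfg.smooth_ms)
    stim_i = int(round(sweep.stim_time * fs))
    win_end = min(x.size, stim_i + int(round(cfg.analysis_window_ms
                                             * fs / 1e3)))
    lo = landmarks.artifact_end
    if lo >= win_end:
        raise MalformedLandmarks("artifact end beyond analysis window")
    baseline = float(np.median(x[:stim_i])) if stim_i > 0 else float(x[0])
    g = int(lo + np.argmax(xs[lo:win_end]))
    rise = xs[g] - baseline
    if rise <= 0:
        raise InsufficientRise("non-positive rise amplitude")
    seg = xs[lo:g + 1]
    above_lo = np.nonzero(seg >= baseline + cfg.rise_lo * rise)[0]
    j_lo = int(above_lo[0]) if above_lo.size else 0
    above_hi = np.nonzero(seg[j_lo:] >= baseline + cfg.rise_hi * rise)[0]
    j_hi = int(j_lo + above_hi[0]) if above_hi.size else seg.size - 1
    sel = np.arange(j_lo, j_hi + 1)
    if sel.size < cfg.min_fit_points:
        raise InsufficientRise(
            f"only {sel.size} samples in the rising-phase window")
    t_ms = (lo + sel) / fs * 1e3
    slope, _ = np.polyfit(t_ms, x[lo + sel], 1)
    return float(slope)


def population_spike_area(sweep: Sweep, landmarks: Landmarks,
                          cfg: AnalysisConfig | None = None
                          ) -> tuple[list[dict], float]:
    """Per-spike areas (mV·ms) and their total.

    For each trough the tangent is the straight line joining the two
    flanking positive-peak samples; the event area is the trapezoidal
    integral of ``max(tangent − V, 0)`` between the peaks. Returns
    ``([], 0.0)`` when no troughs were found.
    """
    cfg = cfg or AnalysisConfig()
    x = _oriented(sweep, cfg)
    fs = sweep.sample_rate
    stim_ms = sweep.stim_time * 1e3
    events: list[dict] = []
    total = 0.0
    for left, tr, right in landmarks.ps:
        if right <= left:
            raise MalformedLandmarks("right peak does not follow left peak")
        if not left <= tr <= right:
            raise MalformedLandmarks("trough outside flanking peaks")
        idx = np.arange(left, right + 1)
        t_ms = idx / fs * 1e3
        tangent = np.interp(t_ms, [t_ms[0], t_ms[-1]], [x[left], x[right]])
        area = float(np.trapezoid(np.clip(tangent - x[idx], 0.0, None), t_ms))
        events.append({
            "left_peak_t": left / fs * 1e3 - stim_ms,
            "trough_t": tr / fs * 1e3 - stim_ms,
            "right_peak_t": right / fs * 1e3 - stim_ms,
            "area": area,
        })
        total += area
    return events, total


def extract_features(sweep: Sweep, cfg: AnalysisConfig | None = None
                     ) -> EPFeatures:
    """Full per-sweep feature extraction (landmarks → slope → PS areas)."""
    cfg = cfg or AnalysisConfig()
    lm = detect_landmarks(sweep, cfg)
    slope = fit_fepsp_slope(sweep, lm, cfg)
    events, total = population_spike_area(sweep, lm, cfg)
    fs = sweep.sample_rate
    stim_ms = sweep.stim_time * 1e3
    return EPFeatures(
        fepsp_onset=lm.onset / fs * 1e3 - stim_ms,
        fepsp_peak=lm.peak / fs * 1e3 - stim_ms,
        fepsp_slope=slope,
        ps_events=events,
        ps_area_total=total,
        n_population_spikes=len(events),
    )


def features_table(sweeps, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Extract features for a collection of sweeps into one tidy table.

    Sweeps whose response is below the detection floor (a real outcome
    for strongly suppressed sessions at low stimulation intensities)
    yield NaN feature rows flagged ``no_response``.
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    for sw in sweeps:
        row = {"session": sw.session, "intensity": sw.intensity,
               "pulse": sw.pulse, "repetition": sw.repetition}
        try:
            f = extract_features(sw, cfg)
            row.update(fepsp_onset=f.fepsp_onset, fepsp_peak=f.fepsp_peak,
                       fepsp_slope=f.fepsp_slope,
                       ps_area_total=f.ps_area_total,
                       n_population_spikes=f.n_population_spikes,
                       no_response=False)
        except (NoResponseDetected, InsufficientRise):
            row.update(fepsp_onset=np.nan, fepsp_peak=np.nan,
                       fepsp_slope=np.nan, ps_area_total=np.nan,
                       n_population_spikes=np.nan, no_response=True)
        rows.append(row)
    return pd.DataFrame(rows)
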