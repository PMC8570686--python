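"""Synthetic study generator with analytic ground truth.

Emulates the three raw-data modalities of a chemogenetic
(DREADD/clozapine) dentate-gyrus experiment so that every downstream
stage is testable without real recordings:

* paired-pulse evoked-potential sweeps — a positive alpha-function fEPSP
  with superimposed negative Gaussian population spikes, a logistic
  input/output relation over a 25–1000 µA intensity grid, 5 repetitions
  per intensity, and a paired-pulse factor scaling the test-pulse (b)
  population spikes;
* broadband multichannel extracellular recordings — Poisson spike trains
  with per-channel rate changes after a clozapine injection event,
  template spikes added to Gaussian noise at 30 kHz;
* morphometry tables — per-slice delineated areas with damage on the
  injected side.

Every generator is a pure function of its parameter record including the
seed, and emits a ground-truth manifest alongside the data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (IncompleteDesign, InvalidDamage, InvalidDuration,
                     UnknownIntensity)
from .ep_waveform import Sweep

__all__ = ["EPSimParams", "EffectModel", "UnitSimParams",
           "SyntheticSessionSet", "SESSIONS", "IDENTITY", "SUPPRESSION",
           "DISINHIBITION", "logistic_drive", "ep_waveform_model",
           "generate_ep_sweep", "generate_session_set",
           "generate_broadband", "generate_morphometry_fixture",
           "default_spike_template"]

#: canonical session order of the paired-pulse protocol
SESSIONS = ("baseline", "vehicle", "clozapine1", "clozapine2")

DEFAULT_INTENSITIES = (25.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0,
                       700.0, 1000.0)

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class EPSimParams:
    """Generative parameters of one animal's evoked-potential recordings.

    The fEPSP is an alpha function ``A·(t/τ)·exp(1−t/τ)`` starting one
    synaptic delay after the stimulus; population spikes are negative
    Gaussian notches; both are scaled by a logistic function of the
    stimulation intensity (the input/output relation).
    """

    fepsp_amplitude: float = 3.0        #: mV, at full logistic drive
    fepsp_rise_tau: float = 2.0         #: ms
    ps_amplitudes: tuple[float, ...] = (4.0,)   #: mV per spike
    ps_latencies: tuple[float, ...] = (4.5,)    #: ms post-stimulus
    ps_width: float = 0.8               #: FWHM, ms
    io_midpoint: float = 300.0          #: µA
    io_slope: float = 0.01              #: 1/µA
    intensities: tuple[float, ...] = DEFAULT_INTENSITIES
    n_repetitions: int = 5
    inter_pulse_interval: float = 10.0  #: ms (protocol metadata)
    paired_pulse_factor: float = 0.6    #: pulse-b PS scaling (<1: inhibition)
    noise_sd: float = 0.1               #: mV
    sample_rate: float = 20000.0        #: Hz
    seed: int = 0
    pre_stim_ms: float = 5.0
    sweep_ms: float = 35.0
    synaptic_delay_ms: float = 1.5
    artifact_amplitude: float = 8.0     #: mV, saturating stimulus artifact
    artifact_width_ms: float = 0.4

    def __post_init__(self):
        lats = self.ps_latencies
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("ps_latencies must be strictly increasing")
        if len(self.ps_amplitudes) != len(lats):
            raise ValueError("ps_amplitudes and ps_latencies length mismatch")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass(frozen=True)
class EffectModel:
    """Session-level treatment effect applied to the generative model."""

    slope_factor: float = 1.0    #: multiplier on fEPSP amplitude
    ps_factor: float = 1.0       #: multiplier on PS amplitudes
    extra_spikes: int = 0        #: additional population spikes
    pp_factor_change: float = 0.0  #: added to paired_pulse_factor

    def __post_init__(self):
        if self.slope_factor < 0 or self.ps_factor < 0:
            raise ValueError("factors must be >= 0")
        if self.extra_spikes < 0:
            raise ValueError("extra_spikes must be >= 0")


IDENTITY = EffectModel()
#: high-expression regime: uniform ~80% suppression of the evoked response
SUPPRESSION = EffectModel(slope_factor=0.2, ps_factor=0.2)
#: low-titer regime: unchanged fEPSP, larger/multiple population spikes
#: and reduced paired-pulse inhibition
DISINHIBITION = EffectModel(slope_factor=1.0, ps_factor=1.3,
                            extra_spikes=1, pp_factor_change=0.25)

#: spacing of additional spikes in the disinhibition regime (ms)
EXTRA_SPIKE_SPACING_MS = 2.5
#: amplitude decrement per additional spike
EXTRA_SPIKE_DECAY = 0.6


def logistic_drive(intensity: float, params: EPSimParams) -> float:
    """Logistic input/output scaling in [0, 1]."""
    return 1.0 / (1.0 + math.exp(-params.io_slope
                                 * (intensity - params.io_midpoint)))


def _effective_spikes(params: EPSimParams, effect: EffectModel,
                      drive: float, pulse: str
                      ) -> tuple[list[float], list[float]]:
    """(amplitudes mV, latencies ms) of all PS notches for one sweep."""
    amps = [a * drive * effect.ps_factor for a in params.ps_amplitudes]
    lats = list(params.ps_latencies)
    for k in range(effect.extra_spikes):
        lats.append((lats[-1] if lats else params.synaptic_delay_ms + 3.0)
                    + EXTRA_SPIKE_SPACING_MS)
        amps.append((amps[-1] if amps else
                     params.fepsp_amplitude * drive * 0.5)
                    * EXTRA_SPIKE_DECAY)
    if pulse == "b":
        ppf = params.paired_pulse_factor + effect.pp_factor_change
        amps = [a * ppf for a in amps]
    return amps, lats


def ep_waveform_model(params: EPSimParams, intensity: float, pulse: str,
                      effect: EffectModel = IDENTITY) -> np.ndarray:
    """Noiseless generative waveform (mV) — the analytic ground truth."""
    fs = params.sample_rate
    n = int(round(params.sweep_ms * fs / 1e3))
    t = np.arange(n) / fs * 1e3  # ms from trace start
    stim = params.pre_stim_ms
    x = np.zeros(n)

    # biphasic saturating stimulus artifact
    half = params.artifact_width_ms / 2.0
    x[(t >= stim) & (t < stim + half)] += params.artifact_amplitude
    x[(t >= stim + half) & (t < stim + params.artifact_width_ms)] -= \
        params.artifact_amplitude

    drive = logistic_drive(intensity, params)
    amp = params.fepsp_amplitude * drive * effect.slope_factor
    ts = t - stim - params.synaptic_delay_ms
    tau = params.fepsp_rise_tau
    with np.errstate(over="ignore"):
        x += amp * np.where(ts > 0, (ts / tau) * np.exp(1.0 - ts / tau), 0.0)

    sigma = params.ps_width / _FWHM_TO_SIGMA
    amps, lats = _effective_spikes(params, effect, drive, pulse)
    for a, lat in zip(amps, lats):
        x -= a * np.exp(-0.5 * ((t - stim - lat) / sigma) ** 2)
    return x


def _sweep_rng(params: EPSimParams, session: str, intensity: float,
               pulse: str, rep: int) -> np.random.Generator:
    key = [int(params.seed),
           SESSIONS.index(session) if session in SESSIONS else 7,
           int(round(intensity * 1000)), 0 if pulse == "a" else 1, int(rep)]
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_ep_sweep(params: EPSimParams, intensity: float,
                      pulse: str = "a", rep: int = 0,
                      effect: EffectModel = IDENTITY,
                      session: str = "baseline") -> Sweep:
    """One synthetic evoked-potential sweep.

    Deterministic: identical ``(params, session, intensity, pulse, rep)``
    yield bit-identical traces.

    Raises
    ------
    UnknownIntensity
        If ``intensity`` is not on ``params.intensities``.
    """
    if not any(np.isclose(intensity, i) for i in params.intensities):
        raise UnknownIntensity(f"{intensity} µA not on the stimulation grid")
    x = ep_waveform_model(params, intensity, pulse, effect)
    if params.noise_sd > 0:
        rng = _sweep_rng(params, session, intensity, pulse, rep)
        x = x + rng.normal(0.0, params.noise_sd, x.size)
    return Sweep(samples=x, sample_rate=params.sample_rate,
                 stim_time=params.pre_stim_ms / 1e3, intensity=intensity,
                 pulse=pulse, session=session, repetition=rep)


@dataclass
class SyntheticSessionSet:
    """Complete four-session sweep grid plus its ground-truth manifest."""

    params: EPSimParams
    effects: dict[str, EffectModel]
    sweeps: list[Sweep] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def generate_session_set(params: EPSimParams,
                         effects: dict[str, EffectModel]
                         ) -> SyntheticSessionSet:
    """Full intensity × repetition × pulse grids for the four sessions.

    ``effects`` must cover baseline, vehicle, clozapine1 and clozapine2;
    extra sessions are generated too. The manifest records the true
    per-session factors and noiseless amplitudes per intensity.
    """
    missing = [s for s in SESSIONS if s not in effects]
    if missing:
        raise IncompleteDesign(f"missing session(s): {missing}")

    out = SyntheticSessionSet(params=params, effects=dict(effects))
    for session, eff in effects.items():
        truth = {"slope_factor": eff.slope_factor,
                 "ps_factor": eff.ps_factor,
                 "extra_spikes": eff.extra_spikes,
                 "paired_pulse_factor": params.paired_pulse_factor
                 + eff.pp_factor_change,
                 "fepsp_amplitude_mV": {},
                 "ps_amplitudes_mV": {},
                 "n_population_spikes": len(params.ps_amplitudes)
                 + eff.extra_spikes}
        for inten in params.intensities:
            drive = logistic_drive(inten, params)
            truth["fepsp_amplitude_mV"][inten] = (
                params.fepsp_amplitude * drive * eff.slope_factor)
            amps, _ = _effective_spikes(params, eff, drive, "a")
            truth["ps_amplitudes_mV"][inten] = amps
            for rep in range(params.n_repetitions):
                for pulse in ("a", "b"):
                    out.sweeps.append(generate_ep_sweep(
                        params, inten, pulse, rep, eff, session))
        out.manifest[session] = truth
    return out


# ---------------------------------------------------------------------------
# broadband extracellular recordings
# ---------------------------------------------------------------------------

def default_spike_template(sample_rate: float = 30000.0,
                           amplitude_uv: float = 100.0) -> np.ndarray:
    """Biphasic extracellular spike template (µV), trough-negative."""
    n = int(round(1.2e-3 * sample_rate))
    t = np.arange(n) / sample_rate * 1e3  # ms
    return (-amplitude_uv * np.exp(-0.5 * ((t - 0.3) / 0.1) ** 2)
            + 0.3 * amplitude_uv * np.exp(-0.5 * ((t - 0.7) / 0.2) ** 2))


@dataclass(frozen=True)
class UnitSimParams:
    """Generative parameters of one broadband probe recording."""

    n_channels: int = 8
    sample_rate: float = 30000.0
    #: Hz per channel-cluster, ordered dorsal → ventral
    baseline_rates: tuple[float, ...] = (50.0, 40.0, 30.0, 20.0,
                                         10.0, 8.0, 8.0, 8.0)
    #: rate multipliers after the clozapine event, per cluster
    post_event_rate_factors: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2,
                                                  1.0, 1.0, 1.5, 1.5)
    spike_waveform: tuple[float, ...] | None = None  #: µV; None → default
    noise_sd: float = 10.0      #: µV
    duration: float = 300.0     #: s
    event_time: float = 150.0   #: clozapine injection, s
    vehicle_time: float | None = None  #: defaults to event_time / 2
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidDuration("duration must be > 0")
        if not 0 < self.event_time < self.duration:
            raise ValueError("event_time must lie within the recording")
        if len(self.baseline_rates) != self.n_channels \
                or len(self.post_event_rate_factors) != self.n_channels:
            raise ValueError("per-channel parameter length mismatch")
        if any(r < 0 for r in self.baseline_rates) \
                or any(f < 0 for f in self.post_event_rate_factors):
            raise ValueError("rates and factors must be >= 0")

    @property
    def event_times(self) -> dict[str, float]:
        veh = (self.vehicle_time if self.vehicle_time is not None
               else self.event_time / 2.0)
        return {"vehicle": veh, "clozapine": self.event_time}


def generate_broadband(params: UnitSimParams):
    """Synthetic probe recording plus its ground-truth spike times.

    Each channel hosts one Poisson cluster firing at its baseline rate
    before the clozapine event and at ``rate × factor`` after it;
    template spikes are inserted additively into white Gaussian noise.

    Returns
    -------
    (BroadbandRecording, pandas.DataFrame)
        The recording and a manifest with columns
        ``cluster, time_s, channel``.
    """
    from .unit_activity import BroadbandRecording  # avoid module cycle

    fs = params.sample_rate
    n_samp = int(round(params.duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 91]))
    template = (np.asarray(params.spike_waveform, dtype=float)
                if params.spike_waveform is not None
                else default_spike_template(fs))
    data = (rng.normal(0.0, params.noise_sd, (params.n_channels, n_samp))
            if params.noise_sd > 0
            else np.zeros((params.n_channels, n_samp)))

    rows = []
    for ch in range(params.n_channels):
        times = []
        for rate, t0, t1 in [
                (params.baseline_rates[ch], 0.0, params.event_time),
                (params.baseline_rates[ch]
                 * params.post_event_rate_factors[ch],
                 params.event_time, params.duration)]:
            count = rng.poisson(rate * (t1 - t0))
            times.append(np.sort(rng.uniform(t0, t1, count)))
        times = np.concatenate(times)
        for t in times:
            i = int(round(t * fs))
            j = min(i + template.size, n_samp)
            if j > i:
                data[ch, i:j] += template[:j - i]
        rows.append(pd.DataFrame({"cluster": ch, "time_s": times,
                                  "channel": ch}))

    truth = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["cluster", "time_s", "channel"]))
    rec = BroadbandRecording(
        data=data, sample_rate=fs, event_times=params.event_times,
        channel_depth_order=tuple(range(params.n_channels)))
    return rec, truth


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

def generate_morphometry_fixture(n_slices: int = 8, spacing: float = 0.6,
                                 areas=8.5, damaged=0.0,
                                 seed: int | None = None,
                                 jitter_sd: float = 0.0,
                                 ap_start: float = -2.2) -> pd.DataFrame:
    """Per-slice area table for the injected and non-injected side.

    ``areas``/``damaged`` may be scalars or per-slice sequences (mm²);
    damage applies to the injected side only. With ``jitter_sd`` > 0 and
    a seed, total areas receive reproducible Gaussian jitter (damage is
    then clipped to the jittered total).
    """
    areas = np.broadcast_to(np.asarray(areas, dtype=float), n_slices).copy()
    damaged = np.broadcast_to(np.asarray(damaged, dtype=float),
                              n_slices).copy()
    if np.any(damaged > areas):
        raise InvalidDamage("damaged area exceeds total slice area")
    if np.any(damaged < 0) or np.any(areas < 0):
        raise ValueError("areas must be non-negative")

    rng = np.random.default_rng(np.random.SeedSequence([seed or 0, 37]))
    ap = ap_start - spacing * np.arange(n_slices)
    frames = []
    for side, dmg in [("injected", damaged), ("non_injected",
                                              np.zeros(n_slices))]:
        total = areas.copy()
        if jitter_sd > 0 and seed is not None:
            total = np.clip(total + rng.normal(0, jitter_sd, n_slices),
                            0.0, None)
        frames.append(pd.DataFrame({
            "slice": np.arange(n_slices), "ap_mm": ap, "side": side,
            "total_area_mm2": total,
            "damaged_area_mm2": np.minimum(dmg, total),
            "spacing_mm": spacing}))
    return pd.concat(frames, ignore_index=True)


def with_seed(params, seed: int):
    """Copy of a frozen parameter record with a different seed."""
    return replace(params, seed=int(seed))
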