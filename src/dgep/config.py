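"""Analysis configuration.

One flat record holds every tunable of the downstream stages, with the
defaults used throughout the package. Reading/writing the resolved config
next to each run's outputs is handled by :mod:`dgep.pipeline`.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # --- evoked-potential waveform stage ---
    #: artifact blanking window after stimulus onset (ms)
    blank_ms: float = 1.0
    #: start of the peak/trough search window after stimulus (ms)
    search_lo_ms: float = 2.0
    #: end of the post-stimulus analysis window (ms)
    analysis_window_ms: float = 15.0
    #: rising-phase fit window, as fractions of the onset-to-peak amplitude
    rise_lo: float = 0.2
    rise_hi: float = 0.8
    #: fEPSP onset threshold as a fraction of peak amplitude
    onset_frac: float = 0.05
    #: minimum prominence for peak/trough detection (mV)
    min_prominence: float = 0.1
    #: boxcar width for the detection copy of the trace (ms); landmark
    #: search runs on a lightly smoothed copy, slope/area on raw samples
    smooth_ms: float = 0.5
    #: noise-adaptive floors: prominence and onset thresholds are raised
    #: to k × the pre-stimulus noise SD of the smoothed trace, so small
    #: responses are not carved up by noise extrema
    noise_prominence_k: float = 6.0
    onset_noise_k: float = 4.0
    #: minimum post-stimulus response amplitude (mV)
    min_response_mV: float = 0.05
    #: minimum number of samples for the slope fit
    min_fit_points: int = 3
    #: flip the trace if acquired with inverted polarity
    invert: bool = False

    # --- session normalization stage ---
    #: fraction of the maximal population-spike area defining the
    #: reference intensity
    reference_frac: float = 0.75
    #: sessions averaged into the single clozapine estimate
    clozapine_sessions: tuple[str, ...] = ("clozapine1", "clozapine2")

    # --- unit-activity stage ---
    band_lo_hz: float = 500.0
    band_hi_hz: float = 5000.0
    filter_order: int = 3
    #: spike threshold in multiples of the median absolute deviation
    threshold_mad: float = 6.5
    #: trough-alignment search window after a crossing (ms)
    align_window_ms: float = 1.0
    #: refractory lockout between detections (ms)
    dead_time_ms: float = 1.0
    #: firing-rate bin width (s)
    bin_s: float = 60.0

    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clozapine_sessions"] = list(self.clozapine_sessions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "clozapine_sessions" in d:
            d["clozapine_sessions"] = tuple(d["clozapine_sessions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
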