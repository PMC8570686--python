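"""Session-level aggregation of evoked-potential features.

Builds per-session input/output (I/O) curves from per-sweep features,
selects the reference intensity (the grid intensity whose baseline
conditioning-pulse population-spike area is closest to 75% of the
maximal mean area), normalizes vehicle and clozapine sessions to
baseline at that intensity, and computes paired-pulse (EPb/EPa) ratios.

The two post-clozapine sessions are averaged into a single clozapine
estimate; the PS-area / fEPSP-slope ratio is formed from session means
(robust when individual sweeps have near-zero slope).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import (EmptySession, NoSpikingResponse, UndefinedRatio)

__all__ = ["IOCurve", "SessionSet", "NormalizedEffect", "build_io_curve",
           "select_reference_intensity", "normalize_sessions",
           "paired_pulse_ratio"]

METRICS = ("fepsp_slope", "ps_area_total", "n_population_spikes")


@dataclass
class IOCurve:
    """Mean/SD over repetitions of each feature per (intensity, pulse)."""

    session: str
    #: tidy table: intensity, pulse, <metric>_mean, <metric>_sd, n_reps
    table: pd.DataFrame

    @property
    def intensities(self) -> np.ndarray:
        return np.sort(self.table["intensity"].unique())

    def mean(self, metric: str, pulse: str) -> pd.Series:
        """Repetition-mean of ``metric`` vs intensity for one pulse."""
        sub = self.table[self.table["pulse"] == pulse]
        return (sub.set_index("intensity")[f"{metric}_mean"]
                .sort_index())

    def value_at(self, metric: str, pulse: str, intensity: float) -> float:
        s = self.mean(metric, pulse)
        if intensity not in s.index:
            raise KeyError(f"{intensity} µA not on the session grid")
        return float(s.loc[intensity])


@dataclass
class SessionSet:
    """session label → I/O curve for the four-session protocol."""

    curves: dict[str, IOCurve]

    def __getitem__(self, session: str) -> IOCurve:
        return self.curves[session]

    def __contains__(self, session: str) -> bool:
        return session in self.curves


@dataclass
class NormalizedEffect:
    """Treatment effects at the reference intensity (dimensionless)."""

    reference_intensity: float
    #: metric → {"vehicle_over_baseline": v, "clozapine_over_baseline": c}
    #: for fepsp_slope_a/b and ps_over_slope_a/b
    ratios: dict[str, dict[str, float]]
    #: session → {metric → EPb/EPa ratio}
    epb_over_epa: dict[str, dict[str, float]]
    #: metrics whose baseline was zero (ratio undefined → NaN)
    flags: list[str] = field(default_factory=list)

    def to_flat_dict(self) -> dict[str, float]:
        out = {"reference_intensity": self.reference_intensity}
        for metric, d in self.ratios.items():
            for contrast, v in d.items():
                out[f"{metric}_{contrast}"] = v
        for session, d in self.epb_over_epa.items():
            for metric, v in d.items():
                out[f"epb_over_epa_{metric}_{session}"] = v
        return out


def build_io_curve(features: pd.DataFrame, session: str) -> IOCurve:
    """Aggregate a per-sweep feature table into one session's I/O curve.

    Sweeps flagged ``no_response`` contribute NaN and are excluded from
    the means; ``n_reps`` records how many repetitions actually entered
    each cell, so missing repetitions are tolerated.
    """
    sub = features[features["session"] == session]
    sub = sub.dropna(subset=["fepsp_slope", "ps_area_total"], how="all")
    if sub.empty:
        raise EmptySession(f"no analyzable sweeps for session {session!r}")
    rows = []
    for (inten, pulse), grp in sub.groupby(["intensity", "pulse"],
                                           sort=True):
        row = {"intensity": inten, "pulse": pulse, "n_reps": len(grp)}
        for m in METRICS:
            vals = grp[m].astype(float)
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    table = (pd.DataFrame(rows)
             .sort_values(["intensity", "pulse"])
             .reset_index(drop=True))
    return IOCurve(session=session, table=table)


def select_reference_intensity(baseline: IOCurve, pulse: str = "a",
                               frac: float = 0.75) -> float:
    """Grid intensity whose mean EPa PS area is closest to 75% of max.

    Tie-break: the lower intensity. Raises :class:`NoSpikingResponse`
    when every mean area is zero.
    """
    areas = baseline.mean("ps_area_total", pulse).dropna()
    if areas.empty or (areas == 0).all():
        raise NoSpikingResponse("all population-spike areas are zero")
    target = frac * areas.max()
    dist = (areas - target).abs().sort_index()
    # stable sort keeps the lower intensity first among ties
    return float(dist.sort_values(kind="stable").index[0])


def _session_values(curve: IOCurve, ref: float) -> dict[str, float]:
    vals = {}
    for pulse in ("a", "b"):
        slope = curve.value_at("fepsp_slope", pulse, ref)
        area = curve.value_at("ps_area_total", pulse, ref)
        vals[f"fepsp_slope_{pulse}"] = slope
        vals[f"ps_area_{pulse}"] = area
        vals[f"ps_over_slope_{pulse}"] = (area / slope if slope != 0
                                          else np.nan)
    return vals


def normalize_sessions(sessions: SessionSet, ref: float,
                       cfg: AnalysisConfig | None = None
                       ) -> NormalizedEffect:
    """Vehicle/baseline and clozapine/baseline ratios at ``ref``.

    The clozapine estimate is the mean of the two post-clozapine
    sessions' values; PS/slope ratios are formed per session before any
    division. Zero baselines flag the affected metric (NaN) without
    failing the whole normalization.
    """
    cfg = cfg or AnalysisConfig()
    needed = ("baseline", "vehicle") + tuple(cfg.clozapine_sessions)
    for s in needed:
        if s not in sessions:
            raise EmptySession(f"session {s!r} missing")
    per_session = {s: _session_values(sessions[s], ref) for s in needed}
    cloz = {k: float(np.mean([per_session[s][k]
                              for s in cfg.clozapine_sessions]))
            for k in per_session["baseline"]}

    ratios: dict[str, dict[str, float]] = {}
    flags: list[str] = []
    for metric in ("fepsp_slope_a", "fepsp_slope_b",
                   "ps_over_slope_a", "ps_over_slope_b"):
        base = per_session["baseline"][metric]
        d = {}
        for contrast, val in [("vehicle_over_baseline",
                               per_session["vehicle"][metric]),
                              ("clozapine_over_baseline", cloz[metric])]:
            if base == 0 or not np.isfinite(base):
                d[contrast] = np.nan
                if metric not in flags:
                    flags.append(metric)
            else:
                d[contrast] = val / base
        ratios[metric] = d

    epb = {}
    for s in needed:
        v = per_session[s]
        epb[s] = {}
        for metric, a_key, b_key in [
                ("fepsp_slope", "fepsp_slope_a", "fepsp_slope_b"),
                ("ps_area_total", "ps_area_a", "ps_area_b")]:
            a, b = v[a_key], v[b_key]
            epb[s][metric] = b / a if a != 0 and np.isfinite(a) else np.nan
    return NormalizedEffect(reference_intensity=ref, ratios=ratios,
                            epb_over_epa=epb, flags=flags)


def paired_pulse_ratio(curve: IOCurve, ref: float,
                       metric: str = "ps_area_total") -> float:
    """Mean EPb metric / mean EPa metric at the reference intensity."""
    a = curve.value_at(metric, "a", ref)
    b = curve.value_at(metric, "b", ref)
    if a == 0 or not np.isfinite(a):
        raise UndefinedRatio(f"EPa {metric} is zero at {ref} µA")
    return b / a
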