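"""Study-level orchestration: simulate → analyze → report.

A synthetic study mirrors the design of a titer-dependent chemogenetic
experiment: a high-expression group in which clozapine uniformly
suppresses the evoked response, a low-expression group showing extra
population spikes and reduced paired-pulse inhibition, and a reporter-
only control. Each stage writes deterministic artifacts plus the fully
resolved configuration next to its outputs, so a run is reproducible
from its directory alone.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .config import AnalysisConfig
from .errors import (DgepError, IOFailure, MissingInput,
                     NoSpikingResponse)
from .ep_session import (SessionSet, build_io_curve, normalize_sessions,
                         select_reference_intensity)
from .ep_waveform import features_table
from .morphometry import (ExpressionScore, apply_exclusion,
                          hippocampal_volume, roi_intensity,
                          volume_difference)
from .report import build_report
from .synth import (DISINHIBITION, IDENTITY, SESSIONS, SUPPRESSION,
                    EffectModel, EPSimParams, UnitSimParams,
                    generate_broadband, generate_morphometry_fixture,
                    generate_session_set, with_seed)
from .unit_activity import multiunit_rates

__all__ = ["GroupSpec", "StudyConfig", "default_study_config",
           "simulate", "analyze", "report"]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of the synthetic study."""

    name: str
    n_animals: int
    clozapine_effect: EffectModel = IDENTITY
    vehicle_effect: EffectModel = IDENTITY
    #: per-slice damaged area on the injected side, mm²
    damage_mm2: float = 0.3
    #: typical transduction scores (granule, hilus)
    expression: tuple[int, int] = (3, 2)
    #: animals (from the end of the group) with zero expression, to be
    #: excluded from the EP analysis
    n_zero_expression: int = 0
    #: animals (from the start of the group) with a broadband recording
    n_unit_animals: int = 0


@dataclass
class StudyConfig:
    groups: list[GroupSpec]
    ep_params: EPSimParams = field(default_factory=EPSimParams)
    unit_params: UnitSimParams = field(default_factory=UnitSimParams)
    n_slices: int = 8
    slice_spacing_mm: float = 0.6
    slice_area_mm2: float = 8.5
    area_jitter_sd: float = 0.4
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_study_config(seed: int = 0) -> StudyConfig:
    """The default synthetic study: suppression, disinhibition, control."""
    groups = [
        GroupSpec("high_expression", n_animals=6,
                  clozapine_effect=SUPPRESSION, damage_mm2=3.2,
                  expression=(5, 4)),
        GroupSpec("low_expression", n_animals=6,
                  clozapine_effect=DISINHIBITION, damage_mm2=0.3,
                  expression=(3, 2), n_zero_expression=1,
                  n_unit_animals=2),
        GroupSpec("control", n_animals=3, clozapine_effect=IDENTITY,
                  damage_mm2=0.3, expression=(4, 3)),
    ]
    return StudyConfig(groups=groups, seed=seed)


def _derive_seed(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0]
               % (2 ** 31))


def _session_effects(group: GroupSpec) -> dict[str, EffectModel]:
    return {"baseline": IDENTITY, "vehicle": group.vehicle_effect,
            "clozapine1": group.clozapine_effect,
            "clozapine2": group.clozapine_effect}


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate(study: StudyConfig, outdir: str | Path) -> Path:
    """Generate the complete synthetic dataset under ``outdir``.

    Writes per-animal sweep CSVs, morphometry tables, ROI-intensity
    tables, expression scores, broadband recordings for the designated
    animals, the ground-truth manifests, and the resolved study config.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "animals").mkdir(exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create output directory: {exc}") from exc

    manifest: dict = {"seed": study.seed, "animals": []}
    truth: dict = {}
    score_rows, roi_rows = [], []
    for gi, group in enumerate(sorted(study.groups, key=lambda g: g.name)):
        for ai in range(group.n_animals):
            animal = f"{group.name}_{ai:02d}"
            zero = ai >= group.n_animals - group.n_zero_expression
            granule, hilus = (0, 0) if zero else group.expression
            score_rows.append({"animal": animal, "group": group.name,
                               "granule": granule, "hilus": hilus})

            ep = with_seed(study.ep_params,
                           _derive_seed(study.seed, gi, ai, 11))
            sset = generate_session_set(ep, _session_effects(group))
            sweeps_csv = outdir / "animals" / f"{animal}_sweeps.csv"
            dio.write_sweeps_csv(sset.sweeps, sweeps_csv)
            truth[animal] = sset.manifest

            morpho = generate_morphometry_fixture(
                n_slices=study.n_slices, spacing=study.slice_spacing_mm,
                areas=study.slice_area_mm2, damaged=group.damage_mm2,
                seed=_derive_seed(study.seed, gi, ai, 23),
                jitter_sd=study.area_jitter_sd)
            morpho_csv = outdir / "animals" / f"{animal}_morphometry.csv"
            morpho.to_csv(morpho_csv, index=False)

            rng = np.random.default_rng(
                _derive_seed(study.seed, gi, ai, 29))
            for level in ("dorsal", "ventral"):
                for side, base in [("injected",
                                    150.0 * (granule + hilus) / 2.0),
                                   ("non_injected", 20.0)]:
                    for _ in range(4):
                        roi_rows.append({
                            "animal": animal, "group": group.name,
                            "slice_level": level, "side": side,
                            "intensity": max(0.0, base
                                             + rng.normal(0.0, 10.0))})

            broadband_prefix = None
            if ai < group.n_unit_animals:
                up = with_seed(study.unit_params,
                               _derive_seed(study.seed, gi, ai, 31))
                rec, spikes = generate_broadband(up)
                prefix = outdir / "animals" / f"{animal}_broadband"
                dio.write_broadband(rec, prefix)
                spikes.to_csv(prefix.parent / f"{animal}_truth_spikes.csv",
                              index=False)
                broadband_prefix = str(prefix.relative_to(outdir))

            manifest["animals"].append({
                "id": animal, "group": group.name,
                "sweeps_csv": str(sweeps_csv.relative_to(outdir)),
                "morphometry_csv": str(morpho_csv.relative_to(outdir)),
                "broadband_prefix": broadband_prefix,
                "expression": {"granule": granule, "hilus": hilus}})

    pd.DataFrame(score_rows).to_csv(outdir / "scores.csv", index=False)
    pd.DataFrame(roi_rows).to_csv(outdir / "rois.csv", index=False)
    dio.write_json(truth, outdir / "ground_truth.json")
    dio.write_json(study.to_dict(), outdir / "config_resolved.json")
    dio.write_json(manifest, outdir / "manifest.json")
    return outdir


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def analyze(indir: str | Path, outdir: str | Path,
            cfg: AnalysisConfig | None = None) -> Path:
    """Run every analysis stage over a simulated (or conforming) dataset.

    Order: exclusion by expression score, per-sweep EP features,
    session normalization, multiunit rates, volumetry, ROI summary.
    Animals excluded by the transduction score never enter the EP
    statistics; a dataset without broadband recordings skips the unit
    stage with a log entry.
    """
    indir, outdir = Path(indir), Path(outdir)
    cfg = cfg or AnalysisConfig()
    manifest_path = indir / "manifest.json"
    if not manifest_path.exists():
        raise MissingInput(f"no manifest.json in {indir}")
    manifest = dio.read_json(manifest_path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create output directory: {exc}") from exc

    log: list[str] = []
    scores_df = pd.read_csv(indir / "scores.csv")
    scores = {r["animal"]: ExpressionScore(int(r["granule"]),
                                           int(r["hilus"]))
              for _, r in scores_df.iterrows()}
    included, excl_log = apply_exclusion(scores)
    log.extend(excl_log)
    (outdir / "exclusion_log.txt").write_text("\n".join(excl_log) + "\n")

    feature_frames, effect_rows = [], []
    volume_rows, rate_rows, depth_frames = [], [], []
    for animal in manifest["animals"]:
        aid, group = animal["id"], animal["group"]

        # morphometry runs on every animal, before any exclusion
        morpho = pd.read_csv(indir / animal["morphometry_csv"])
        inj = hippocampal_volume(morpho, "injected")
        non = hippocampal_volume(morpho, "non_injected")
        diff, pct = volume_difference(inj, non)
        volume_rows.append({"animal": aid, "group": group,
                            "injected_mm3": inj, "non_injected_mm3": non,
                            "diff_mm3": diff, "diff_pct": pct})

        if aid in included:
            sweeps = dio.read_sweeps_csv(indir / animal["sweeps_csv"])
            feats = features_table(sweeps, cfg)
            feats.insert(0, "animal", aid)
            feats.insert(1, "group", group)
            feature_frames.append(feats)
            try:
                curves = SessionSet({s: build_io_curve(feats, s)
                                     for s in SESSIONS})
                ref = select_reference_intensity(
                    curves["baseline"], frac=cfg.reference_frac)
                eff = normalize_sessions(curves, ref, cfg)
            except (NoSpikingResponse, DgepError) as exc:
                log.append(f"{aid}: EP normalization failed "
                           f"({type(exc).__name__}: {exc})")
                eff = None
            if eff is not None:
                row = {"animal": aid, "group": group}
                flat = eff.to_flat_dict()
                row.update({k: v for k, v in flat.items()
                            if not k.startswith("epb_over_epa")})
                row["epb_over_epa_ps_baseline"] = \
                    eff.epb_over_epa["baseline"]["ps_area_total"]
                row["epb_over_epa_ps_vehicle"] = \
                    eff.epb_over_epa["vehicle"]["ps_area_total"]
                row["epb_over_epa_ps_clozapine"] = float(np.mean(
                    [eff.epb_over_epa[s]["ps_area_total"]
                     for s in cfg.clozapine_sessions]))
                effect_rows.append(row)
        else:
            log.append(f"{aid}: skipped EP analysis (excluded)")

        if animal.get("broadband_prefix"):
            rec = dio.read_broadband(indir / animal["broadband_prefix"])
            spikes, series = multiunit_rates(rec, cfg)
            for rs in series:
                rate_rows.append({
                    "animal": aid, "group": group, "channel": rs.label,
                    "baseline_rate_hz": rs.baseline_rate,
                    "post_rate_hz": rs.post_rate,
                    "relative_change": rs.relative_change,
                    "undefined_change": rs.undefined_change})
            from .unit_activity import depth_profile
            prof = depth_profile(series, rec.channel_depth_order)
            prof.insert(0, "animal", aid)
            depth_frames.append(prof)

    if not any(a.get("broadband_prefix") for a in manifest["animals"]):
        log.append("units: no broadband recordings in dataset; "
                   "stage skipped")

    if feature_frames:
        pd.concat(feature_frames, ignore_index=True).to_csv(
            outdir / "features.csv", index=False, float_format="%.8g")
    pd.DataFrame(effect_rows).to_csv(outdir / "ep_effects.csv", index=False)
    pd.DataFrame(volume_rows).to_csv(outdir / "volumes.csv", index=False)
    if rate_rows:
        pd.DataFrame(rate_rows).to_csv(outdir / "unit_rates.csv",
                                       index=False)
        pd.concat(depth_frames, ignore_index=True).to_csv(
            outdir / "depth_profile.csv", index=False)
    rois_path = indir / "rois.csv"
    if rois_path.exists():
        rois = pd.read_csv(rois_path)
        per_animal = []
        for aid, sub in rois.groupby("animal", sort=True):
            summary = roi_intensity(sub)
            summary.insert(0, "animal", aid)
            per_animal.append(summary)
        pd.concat(per_animal, ignore_index=True).to_csv(
            outdir / "roi_summary.csv", index=False)

    (outdir / "analysis_log.txt").write_text("\n".join(log) + "\n")
    dio.write_json(cfg.to_dict(), outdir / "config_resolved.json")
    return outdir


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(indir: str | Path, outdir: str | Path,
           holm_family: str = "per_metric") -> Path:
    """Deterministic summary tables from an analysis directory."""
    indir, outdir = Path(indir), Path(outdir)

    def _maybe(name):
        p = indir / name
        if not p.exists():
            return None
        df = pd.read_csv(p)
        return df if not df.empty else None

    ep = _maybe("ep_effects.csv")
    vol = _maybe("volumes.csv")
    units = _maybe("unit_rates.csv")
    if ep is None and vol is None and units is None:
        raise MissingInput(f"no analysis outputs found in {indir}")
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create output directory: {exc}") from exc

    rep = build_report(ep_effects=ep, volumes=vol, unit_rates=units,
                       holm_family=holm_family)
    rep["comparisons"].to_csv(outdir / "comparisons.csv", index=False,
                              float_format="%.8g")
    rep["group_means"].to_csv(outdir / "group_means.csv", index=False,
                              float_format="%.8g")
    dio.write_json(rep["summary"], outdir / "report.json")
    return outdir
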