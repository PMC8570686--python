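"""I/O curves, reference-intensity selection, normalization, PP ratios."""
import numpy as np
import pandas as pd
import pytest

from dgep.config import AnalysisConfig
from dgep.ep_session import (SessionSet, build_io_curve,
                             normalize_sessions, paired_pulse_ratio,
                             select_reference_intensity)
from dgep.ep_waveform import features_table
from dgep.errors import (EmptySession, NoSpikingResponse, UndefinedRatio)
from dgep.synth import (IDENTITY, SESSIONS, EffectModel, EPSimParams,
                        generate_session_set)


def features_from_areas(areas: dict, slope=1.0, reps=5, session="baseline"):
    """Feature table with given per-intensity EPa PS areas (both pulses)."""
    rows = []
    for inten, area in areas.items():
        for pulse in ("a", "b"):
            for rep in range(reps):
                rows.append({"session": session, "intensity": float(inten),
                             "pulse": pulse, "repetition": rep,
                             "fepsp_slope": slope, "ps_area_total": area,
                             "n_population_spikes": 1 if area else 0,
                             "no_response": False})
    return pd.DataFrame(rows)


class TestIOCurve:
    def test_identical_sweeps_have_zero_sd(self):
        feats = features_from_areas({100: 2.0, 400: 3.0})
        curve = build_io_curve(feats, "baseline")
        assert (curve.table["ps_area_total_sd"] == 0).all()
        assert (curve.table["n_reps"] == 5).all()
        assert curve.value_at("ps_area_total", "a", 400.0) == 3.0

    def test_empty_session_raises(self):
        feats = features_from_areas({100: 2.0})
        with pytest.raises(EmptySession):
            build_io_curve(feats, "vehicle")

    def test_missing_repetitions_tolerated_and_recorded(self):
        feats = features_from_areas({100: 2.0, 400: 3.0})
        feats = feats.drop(feats[(feats.intensity == 400.0)
                                 & (feats.repetition > 1)].index)
        curve = build_io_curve(feats, "baseline")
        n = curve.table.set_index(["intensity", "pulse"])["n_reps"]
        assert n.loc[(100.0, "a")] == 5
        assert n.loc[(400.0, "a")] == 2

    def test_noisy_generator_means_near_ground_truth(self, cfg):
        """CLT bound: session means within 4·SD/√5 of noiseless truth."""
        p = EPSimParams(seed=6, intensities=(1000.0,), n_repetitions=5)
        ss = generate_session_set(p, {s: IDENTITY for s in SESSIONS})
        feats = features_table(ss.sweeps, cfg)
        curve = build_io_curve(feats, "baseline")
        p0 = EPSimParams(noise_sd=0.0, intensities=(1000.0,),
                         n_repetitions=1)
        ss0 = generate_session_set(p0, {s: IDENTITY for s in SESSIONS})
        truth = features_table(ss0.sweeps, cfg)
        truth_slope = truth[(truth.session == "baseline")
                            & (truth.pulse == "a")].fepsp_slope.iloc[0]
        row = curve.table.set_index(["intensity", "pulse"]).loc[
            (1000.0, "a")]
        bound = 4 * max(row["fepsp_slope_sd"], 1e-3) / np.sqrt(5)
        assert abs(row["fepsp_slope_mean"] - truth_slope) <= bound


class TestReferenceIntensity:
    def test_exact_match_on_grid(self):
        curve = build_io_curve(
            features_from_areas({100: 1.0, 200: 2.0, 400: 3.0,
                                 800: 4.0}), "baseline")
        assert select_reference_intensity(curve) == 400.0

    def test_closest_match_rule(self):
        curve = build_io_curve(
            features_from_areas({25: 0.0, 100: 1.0, 300: 2.6,
                                 1000: 4.0}), "baseline")
        # target 3.0: |2.6-3.0| < |4.0-3.0|
        assert select_reference_intensity(curve) == 300.0

    def test_tie_break_prefers_lower_intensity(self):
        curve = build_io_curve(
            features_from_areas({100: 2.0, 400: 2.0, 800: 2.0}),
            "baseline")
        assert select_reference_intensity(curve) == 100.0

    def test_all_zero_areas_raise(self):
        curve = build_io_curve(
            features_from_areas({100: 0.0, 400: 0.0}), "baseline")
        with pytest.raises(NoSpikingResponse):
            select_reference_intensity(curve)


def session_set_from(area_by_session, slope_by_session=None):
    curves = {}
    for s in SESSIONS:
        slope = (slope_by_session or {}).get(s, 1.0)
        curves[s] = build_io_curve(
            features_from_areas(area_by_session[s], slope=slope,
                                session=s), s)
    return SessionSet(curves)


class TestNormalization:
    def test_identical_sessions_give_unit_ratios(self):
        areas = {s: {100: 2.0, 400: 3.0} for s in SESSIONS}
        ne = normalize_sessions(session_set_from(areas), 400.0)
        for metric in ne.ratios:
            for v in ne.ratios[metric].values():
                assert v == pytest.approx(1.0)
        assert ne.flags == []

    def test_noiseless_suppression_recovers_factor_exactly(self, cfg):
        p = EPSimParams(noise_sd=0.0)
        supp = EffectModel(slope_factor=0.2, ps_factor=0.2)
        ss = generate_session_set(
            p, {"baseline": IDENTITY, "vehicle": IDENTITY,
                "clozapine1": supp, "clozapine2": supp})
        feats = features_table(ss.sweeps, cfg)
        curves = SessionSet({s: build_io_curve(feats, s) for s in SESSIONS})
        ref = select_reference_intensity(curves["baseline"])
        ne = normalize_sessions(curves, ref, cfg)
        assert ne.ratios["fepsp_slope_a"]["clozapine_over_baseline"] == \
            pytest.approx(0.2, abs=1e-9)
        assert ne.ratios["fepsp_slope_a"]["vehicle_over_baseline"] == \
            pytest.approx(1.0, abs=1e-9)

    def test_zero_baseline_ps_flags_only_ps_metrics(self):
        areas = {s: {400: 0.0} for s in SESSIONS}
        areas["clozapine1"] = {400: 1.0}
        areas["clozapine2"] = {400: 1.0}
        ne = normalize_sessions(session_set_from(areas), 400.0)
        assert np.isfinite(
            ne.ratios["fepsp_slope_a"]["clozapine_over_baseline"])
        assert np.isnan(
            ne.ratios["ps_over_slope_a"]["clozapine_over_baseline"])
        assert "ps_over_slope_a" in ne.flags
        assert "fepsp_slope_a" not in ne.flags

    def test_scale_invariance_of_normalized_effects(self, cfg):
        """Multiplying every sweep by c > 0 changes no ratio."""
        p = EPSimParams(seed=4, intensities=(300.0, 1000.0),
                        n_repetitions=2)
        ss = generate_session_set(p, {s: IDENTITY for s in SESSIONS})
        feats = features_table(ss.sweeps, cfg)
        scaled = feats.copy()
        scaled[["fepsp_slope", "ps_area_total"]] *= 3.7
        for f in (feats, scaled):
            curves = SessionSet({s: build_io_curve(f, s) for s in SESSIONS})
            ref = select_reference_intensity(curves["baseline"])
            ne = normalize_sessions(curves, ref)
            if f is feats:
                first = ne
        for metric in first.ratios:
            for contrast in first.ratios[metric]:
                assert ne.ratios[metric][contrast] == pytest.approx(
                    first.ratios[metric][contrast], rel=1e-12)

    def test_repetition_permutation_invariance(self):
        feats = features_from_areas({100: 2.0, 400: 3.0})
        rng = np.random.default_rng(0)
        shuffled = feats.sample(frac=1.0, random_state=1).reset_index(
            drop=True)
        c1 = build_io_curve(feats, "baseline")
        c2 = build_io_curve(shuffled, "baseline")
        pd.testing.assert_frame_equal(c1.table, c2.table)


class TestPairedPulse:
    def test_identical_pulses_give_unity(self):
        curve = build_io_curve(features_from_areas({400: 2.0}), "baseline")
        assert paired_pulse_ratio(curve, 400.0) == pytest.approx(1.0)

    def test_zero_epa_raises(self):
        curve = build_io_curve(features_from_areas({400: 0.0}), "baseline")
        with pytest.raises(UndefinedRatio):
            paired_pulse_ratio(curve, 400.0)

    def test_generator_pp_factor_tracks_waveform_analysis(self, cfg):
        """Noiseless EPb/EPa PS-area ratio equals the end-to-end value."""
        p = EPSimParams(noise_sd=0.0, paired_pulse_factor=0.5,
                        intensities=(1000.0,), n_repetitions=1)
        ss = generate_session_set(p, {s: IDENTITY for s in SESSIONS})
        feats = features_table(ss.sweeps, cfg)
        curve = build_io_curve(feats, "baseline")
        ratio = paired_pulse_ratio(curve, 1000.0)
        a = feats[(feats.session == "baseline")
                  & (feats.pulse == "a")].ps_area_total.mean()
        b = feats[(feats.session == "baseline")
                  & (feats.pulse == "b")].ps_area_total.mean()
        assert ratio == pytest.approx(b / a, rel=1e-12)
        # PS area is near-linear in notch amplitude, so the measured
        # ratio tracks the generative paired-pulse factor
        assert 0.35 <= ratio <= 0.65
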