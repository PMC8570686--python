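"""Assembly of the per-figure group summary report.

Pulls the stage outputs together into deterministic tables: group ×
metric means, paired vehicle-vs-clozapine contrasts on the normalized
evoked-potential effects, paired injected-vs-non-injected volume
contrasts, and the signed-rank pre/post contrast on unit firing rates.
Every comparison carries its raw and Holm-adjusted p; the adjustment
family is a configuration choice (default: across groups within each
metric).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateDifferences, MissingInput
from .stats import (ComparisonResult, holm_adjust, paired_t,
                    wilcoxon_signed_rank)

__all__ = ["build_report"]

EP_METRICS = ("fepsp_slope_a", "fepsp_slope_b",
              "ps_over_slope_a", "ps_over_slope_b")


def _safe(fn, *args, label: str, **kw) -> ComparisonResult | None:
    try:
        return fn(*args, label=label, **kw)
    except (DegenerateDifferences, ValueError):
        return None


def build_report(ep_effects: pd.DataFrame | None = None,
                 volumes: pd.DataFrame | None = None,
                 unit_rates: pd.DataFrame | None = None,
                 holm_family: str = "per_metric") -> dict:
    """Summary tables from the analysis-stage outputs.

    Parameters
    ----------
    ep_effects
        One row per animal: ``animal, group`` plus, per normalized EP
        metric, ``<metric>_vehicle_over_baseline`` and
        ``<metric>_clozapine_over_baseline`` columns, and the
        paired-pulse columns ``epb_over_epa_ps_vehicle`` /
        ``epb_over_epa_ps_clozapine``.
    volumes
        One row per animal: ``animal, group, injected_mm3,
        non_injected_mm3``.
    unit_rates
        One row per unit or channel: ``animal, channel, baseline_rate_hz,
        post_rate_hz``.
    holm_family
        ``"per_metric"`` adjusts across groups within each metric;
        ``"global"`` adjusts over every comparison at once.

    Returns
    -------
    dict with ``comparisons`` (DataFrame), ``group_means`` (DataFrame)
    and ``summary`` (JSON-ready dict).
    """
    if ep_effects is None and volumes is None and unit_rates is None:
        raise MissingInput("no stage outputs supplied")
    comparisons: list[tuple[str, ComparisonResult]] = []
    means_rows: list[dict] = []

    if ep_effects is not None and not ep_effects.empty:
        pp_cols = ("epb_over_epa_ps_vehicle", "epb_over_epa_ps_clozapine")
        for group, sub in ep_effects.groupby("group", sort=True):
            for metric in EP_METRICS:
                veh = sub[f"{metric}_vehicle_over_baseline"].dropna()
                clo = sub[f"{metric}_clozapine_over_baseline"].dropna()
                paired = veh.index.intersection(clo.index)
                means_rows.append({
                    "table": "ep", "group": group, "metric": metric,
                    "vehicle_mean": veh.mean(), "vehicle_sd": veh.std(),
                    "clozapine_mean": clo.mean(),
                    "clozapine_sd": clo.std(), "n": len(paired)})
                if len(paired) >= 2:
                    res = _safe(paired_t, clo.loc[paired].to_numpy(),
                                veh.loc[paired].to_numpy(),
                                label=f"ep:{metric}:{group}")
                    if res:
                        comparisons.append((metric, res))
            if all(c in sub.columns for c in pp_cols):
                veh = sub[pp_cols[0]].dropna()
                clo = sub[pp_cols[1]].dropna()
                paired = veh.index.intersection(clo.index)
                means_rows.append({
                    "table": "ep", "group": group,
                    "metric": "epb_over_epa_ps",
                    "vehicle_mean": veh.mean(), "vehicle_sd": veh.std(),
                    "clozapine_mean": clo.mean(),
                    "clozapine_sd": clo.std(), "n": len(paired)})
                if len(paired) >= 2:
                    res = _safe(paired_t, clo.loc[paired].to_numpy(),
                                veh.loc[paired].to_numpy(),
                                label=f"ep:epb_over_epa_ps:{group}")
                    if res:
                        comparisons.append(("epb_over_epa_ps", res))

    if volumes is not None and not volumes.empty:
        for group, sub in volumes.groupby("group", sort=True):
            inj = sub["injected_mm3"].to_numpy(dtype=float)
            non = sub["non_injected_mm3"].to_numpy(dtype=float)
            means_rows.append({
                "table": "volume", "group": group, "metric": "volume_mm3",
                "vehicle_mean": non.mean(), "vehicle_sd": non.std(ddof=1)
                if non.size > 1 else 0.0,
                "clozapine_mean": inj.mean(), "clozapine_sd":
                inj.std(ddof=1) if inj.size > 1 else 0.0, "n": inj.size})
            if inj.size >= 2:
                res = _safe(paired_t, inj, non,
                            label=f"volume:injected_vs_noninjected:{group}")
                if res:
                    comparisons.append(("volume", res))

    if unit_rates is not None and not unit_rates.empty:
        unit_rates = unit_rates.dropna(subset=["baseline_rate_hz",
                                               "post_rate_hz"])
    if unit_rates is not None and not unit_rates.empty:
        base = unit_rates["baseline_rate_hz"].to_numpy(dtype=float)
        post = unit_rates["post_rate_hz"].to_numpy(dtype=float)
        means_rows.append({
            "table": "units", "group": "units", "metric": "rate_hz",
            "vehicle_mean": float(np.median(base)),
            "vehicle_sd": float(np.subtract(
                *np.percentile(base, [75, 25]))),
            "clozapine_mean": float(np.median(post)),
            "clozapine_sd": float(np.subtract(
                *np.percentile(post, [75, 25]))), "n": base.size})
        res = _safe(wilcoxon_signed_rank, post, base,
                    label="units:post_vs_baseline")
        if res:
            comparisons.append(("units", res))

    # Holm adjustment per family
    rows = [r.as_dict() | {"family": fam} for fam, r in comparisons]
    df = pd.DataFrame(rows)
    if not df.empty:
        if holm_family == "global":
            df["p_adjusted"] = holm_adjust(df["p"].to_numpy())
        else:
            for fam, idx in df.groupby("family").groups.items():
                df.loc[idx, "p_adjusted"] = holm_adjust(
                    df.loc[idx, "p"].to_numpy())
        df = df.sort_values(["family", "label"]).reset_index(drop=True)

    group_means = (pd.DataFrame(means_rows)
                   .sort_values(["table", "group", "metric"])
                   .reset_index(drop=True)
                   if means_rows else pd.DataFrame())
    summary = {
        "n_comparisons": int(len(df)),
        "holm_family": holm_family,
        "comparisons": df.to_dict(orient="records") if not df.empty else [],
    }
    return {"comparisons": df, "group_means": group_means,
            "summary": summary}
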