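"""Slice-based volumetry, layer areas, ROI intensities and exclusions.

Volume is estimated by the slab rule — Σ (slice area − damaged area) ×
inter-slice spacing — over eight consecutive coronal slices (−2.2 to
−7.0 mm AP, 0.6 mm apart), with hyper-/hypointense damage excluded.
Segmentation itself is an input contract (delineated areas or binary
masks); no image segmentation is performed here. Transduction is scored
0–5 per animal for the granule cell layer and the hilus; animals with a
total score of 0 are excluded from the electrophysiological analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDamage, InvalidROI, UndefinedPercent

__all__ = ["ExpressionScore", "hippocampal_volume", "volume_difference",
           "layer_area", "roi_intensity", "roi_means_from_image",
           "apply_exclusion"]


@dataclass(frozen=True)
class ExpressionScore:
    """Visual transduction score (0–5) per region for one animal."""

    granule: int
    hilus: int

    def __post_init__(self):
        for name, v in [("granule", self.granule), ("hilus", self.hilus)]:
            if not 0 <= v <= 5 or int(v) != v:
                raise ValueError(f"{name} score must be an integer in 0..5")

    @property
    def total(self) -> int:
        return self.granule + self.hilus

    @property
    def excluded(self) -> bool:
        return self.total == 0


def hippocampal_volume(table: pd.DataFrame, side: str,
                       spacing: float | None = None) -> float:
    """Slab-rule volume (mm³) of one side, damage excluded.

    ``table`` needs columns ``side, total_area_mm2, damaged_area_mm2``
    and either a ``spacing_mm`` column or an explicit ``spacing``.
    """
    sub = table[table["side"] == side]
    if sub.empty:
        raise ValueError(f"no slices for side {side!r}")
    total = sub["total_area_mm2"].to_numpy(dtype=float)
    damaged = sub["damaged_area_mm2"].to_numpy(dtype=float)
    if np.any(damaged > total):
        raise InvalidDamage("damaged area exceeds total slice area")
    if spacing is None:
        spacing_col = sub["spacing_mm"].unique()
        if spacing_col.size != 1:
            raise ValueError("ambiguous slice spacing")
        spacing = float(spacing_col[0])
    return float(((total - damaged) * spacing).sum())


def volume_difference(injected: float, non_injected: float
                      ) -> tuple[float, float]:
    """(injected − non-injected) in mm³ and in % of the non-injected side."""
    if injected < 0 or non_injected < 0:
        raise ValueError("volumes must be non-negative")
    diff = injected - non_injected
    if non_injected == 0:
        raise UndefinedPercent("non-injected volume is zero")
    return diff, 100.0 * diff / non_injected


def layer_area(masks=None, areas=None, pixel_size_um: float = 1.0,
               roi_size_um: float = 2508.0) -> pd.DataFrame:
    """Cell-layer area (µm²) per slice within the analysis ROI.

    Either binary ``masks`` (pixel count × pixel area) or pre-measured
    ``areas`` in µm² may be supplied; three slices are expected and
    fewer only warn. The mean over slices is appended as a summary row.

    Raises
    ------
    InvalidROI
        If any mask's physical extent exceeds the square ROI.
    """
    if (masks is None) == (areas is None):
        raise ValueError("supply exactly one of masks or areas")
    if masks is not None:
        vals = []
        for m in masks:
            m = np.asarray(m)
            if max(m.shape) * pixel_size_um > roi_size_um:
                raise InvalidROI("mask extent exceeds the ROI")
            vals.append(float(np.count_nonzero(m)) * pixel_size_um ** 2)
    else:
        vals = [float(a) for a in areas]
    if len(vals) != 3:
        warnings.warn(f"expected 3 slices, got {len(vals)}", stacklevel=2)
    df = pd.DataFrame({"slice": list(range(len(vals))), "area_um2": vals})
    df.attrs["mean_area_um2"] = float(np.mean(vals)) if vals else np.nan
    return df


def roi_intensity(rois: pd.DataFrame) -> pd.DataFrame:
    """Mean staining intensity per slice level and side, with contrast.

    ``rois`` needs columns ``slice_level`` (dorsal/ventral), ``side``
    (injected/non_injected) and ``intensity`` (one row per 250×250 µm
    ROI, four expected per slice-side). Returns one row per slice level
    with both side means and their injected − non-injected difference.
    """
    if rois.empty:
        raise ValueError("no ROI rows")
    means = (rois.groupby(["slice_level", "side"])["intensity"]
             .mean().unstack("side"))
    means["contrast"] = (means.get("injected", np.nan)
                         - means.get("non_injected", np.nan))
    return means.reset_index()


def roi_means_from_image(image: np.ndarray,
                         boxes: list[tuple[int, int, int, int]]
                         ) -> list[float]:
    """Mean pixel intensity inside each (row0, col0, height, width) box."""
    img = np.asarray(image, dtype=float)
    out = []
    for r0, c0, h, w in boxes:
        if r0 < 0 or c0 < 0 or r0 + h > img.shape[0] \
                or c0 + w > img.shape[1]:
            raise InvalidROI("ROI box outside the image")
        out.append(float(img[r0:r0 + h, c0:c0 + w].mean()))
    return out


def apply_exclusion(scores: dict[str, ExpressionScore]
                    ) -> tuple[list[str], list[str]]:
    """Included-animal list plus a human-readable exclusion log.

    Animals with total transduction score 0 are excluded from the
    evoked-potential analysis set.
    """
    included, log = [], []
    for animal in sorted(scores):
        s = scores[animal]
        if s.excluded:
            log.append(f"{animal}: EXCLUDED (granule={s.granule}, "
                       f"hilus={s.hilus}, total=0)")
        else:
            included.append(animal)
            log.append(f"{animal}: included (granule={s.granule}, "
                       f"hilus={s.hilus}, total={s.total})")
    return included, log
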