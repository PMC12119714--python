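"""Threshold and isocontour segmentation.

Three segmentations are implemented:

* whole-brain auto-segmentation at twice the blood-pool SUVmean,
* 41%-of-SUVmax isocontour lesion VOIs (fixed-fraction, no background
  correction),
* metabolic/molecular tumor volume (MTV) at a fixed SUV 4 threshold for the
  glucose tracer and at ``1.5 * SUVmean_liver + 2 * SD_liver`` for the
  SSTR tracer.

Thresholds are strict (``>``) except the 41% isocontour, which keeps voxels
at or above 41% of the local maximum. Connected components use
26-connectivity; MTV components below 0.5 mL are discarded as noise speckle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .quant import UptakeStats
from .volume import VOI, Grid

FDG_MTV_THRESHOLD_SUV = 4.0
ISOCONTOUR_FRACTION = 0.41
MIN_COMPONENT_ML = 0.5
MAX_LESIONS_PER_ORGAN = 5
DEFAULT_SEARCH_RADIUS_MM = 15.0

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class MTVResult:
    """Tumor-volume segmentation result at one SUV threshold."""

    voi: VOI
    threshold_suv: float
    total_volume_mL: float
    per_component: list[tuple[float, float]] = field(default_factory=list)
    """(volume_mL, suv_mean) for each retained connected component."""


def brain_auto_segment(suv_volume: np.ndarray, grid: Grid, bloodpool: UptakeStats,
                       head_region: VOI) -> VOI:
    """Whole-brain VOI: voxels above 2x blood-pool SUVmean inside the head.

    Returns the largest connected component, or an empty VOI when nothing
    exceeds the threshold (the expected outcome for a tracer without
    physiological brain uptake).
    """
    if bloodpool.suv_mean <= 0:
        raise ValueError("blood-pool SUVmean must be > 0")
    if head_region.empty:
        raise ValueError("head region VOI is empty")
    threshold = 2.0 * bloodpool.suv_mean
    mask = head_region.mask & (suv_volume > threshold)
    if not mask.any():
        return VOI(np.zeros(grid.shape, bool), grid, "brain",
                   f"auto threshold {threshold:.3g} (empty)")
    labels, n = ndimage.label(mask, structure=_CONN26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return VOI(labels == keep, grid, "brain", f"auto threshold {threshold:.3g}")


def isocontour_41(
    suv_volume: np.ndarray,
    grid: Grid,
    seed_point_mm,
    search_radius_mm: float = DEFAULT_SEARCH_RADIUS_MM,
    bounding_radius_mm: float | None = None,
    label: str = "lesion",
) -> VOI:
    """41%-of-SUVmax isocontour VOI around a seed point.

    The local maximum is searched within ``search_radius_mm`` of the seed;
    the VOI is the 26-connected component containing that maximum among
    voxels with SUV >= 0.41 * SUVmax. When ``bounding_radius_mm`` is given
    the component is confined to that sphere around the seed — the
    equivalent of the reader's bounding region, which keeps low-contrast
    lesions (SUVmax below ~2.4x background) from flooding into the host
    organ, where 41% of the maximum falls below the background level.
    """
    seed_idx = grid.world_to_index(seed_point_mm)
    x, y, z = grid.coordinate_arrays()
    seed_mm = [grid.origin_mm[k] + seed_idx[k] * grid.voxel_size_mm for k in range(3)]
    dist2 = ((x - seed_mm[0]) ** 2 + (y - seed_mm[1]) ** 2 + (z - seed_mm[2]) ** 2)
    local = np.where(dist2 <= search_radius_mm**2, suv_volume, -np.inf)
    max_idx = np.unravel_index(int(np.argmax(local)), grid.shape)
    suv_max = float(suv_volume[max_idx])
    if suv_max <= 0:
        raise ValueError("seed lies in a zero-uptake region")
    mask = suv_volume >= ISOCONTOUR_FRACTION * suv_max
    if bounding_radius_mm is not None:
        mask &= dist2 <= bounding_radius_mm**2
    labels, _ = ndimage.label(mask, structure=_CONN26)
    comp = labels == labels[max_idx]
    return VOI(comp, grid, label, f"41% isocontour, SUVmax {suv_max:.3g} near {tuple(seed_point_mm)}")


def lesion_filter(lesions: list) -> list:
    """Representative-lesion rule: >= 0.5 mL, at most five per organ.

    ``lesions`` is any sequence of records exposing ``organ``, ``volume_mL``
    and ``suv_max`` attributes (or mapping keys). Within each organ the top
    five by SUVmax are kept; ties prefer the larger volume, then input order.
    """

    def get(rec, name):
        return rec[name] if isinstance(rec, dict) else getattr(rec, name)

    eligible = [(i, rec) for i, rec in enumerate(lesions)
                if get(rec, "volume_mL") >= MIN_COMPONENT_ML]
    by_organ: dict[str, list] = {}
    for i, rec in eligible:
        by_organ.setdefault(get(rec, "organ"), []).append((i, rec))
    kept_idx: set[int] = set()
    for organ_recs in by_organ.values():
        ranked = sorted(
            organ_recs,
            key=lambda t: (-get(t[1], "suv_max"), -get(t[1], "volume_mL"), t[0]),
        )
        kept_idx.update(i for i, _ in ranked[:MAX_LESIONS_PER_ORGAN])
    return [rec for i, rec in enumerate(lesions) if i in kept_idx]


def _threshold_mtv(suv_volume: np.ndarray, grid: Grid, threshold: float,
                   include: np.ndarray, label: str) -> MTVResult:
    mask = include & (suv_volume > threshold)
    labels, n = ndimage.label(mask, structure=_CONN26)
    voxel_mL = grid.voxel_volume_mL
    keep = np.zeros(grid.shape, bool)
    per_component: list[tuple[float, float]] = []
    if n:
        comp_sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                        index=np.arange(1, n + 1))
        for comp_id, size in enumerate(comp_sizes, start=1):
            vol = float(size) * voxel_mL
            if vol < MIN_COMPONENT_ML:
                continue
            comp_mask = labels == comp_id
            keep |= comp_mask
            per_component.append((vol, float(suv_volume[comp_mask].mean())))
    per_component.sort(key=lambda t: -t[0])
    voi = VOI(keep, grid, label, f"threshold SUV > {threshold:.3g}")
    return MTVResult(voi, float(threshold), voi.volume_mL, per_component)


def fdg_mtv(suv_volume: np.ndarray, grid: Grid, body: VOI,
            exclusions: list[VOI] | None = None) -> MTVResult:
    """Glucose-tracer tumor volume: body voxels with SUV > 4.

    ``exclusions`` mask out physiological uptake (brain, myocardium,
    renal/bladder); components below 0.5 mL are discarded.
    """
    if body.empty:
        raise ValueError("body VOI is empty")
    include = body.mask.copy()
    for voi in exclusions or []:
        include &= ~voi.mask
    return _threshold_mtv(suv_volume, grid, FDG_MTV_THRESHOLD_SUV, include, "FDG-MTV")


def sstr_mtv(suv_volume: np.ndarray, grid: Grid, liver: UptakeStats, body: VOI) -> MTVResult:
    """SSTR-tracer tumor volume: SUV > 1.5 * liver SUVmean + 2 * liver SD."""
    if liver.suv_mean <= 0:
        raise ValueError("liver SUVmean must be > 0")
    if body.empty:
        raise ValueError("body VOI is empty")
    threshold = 1.5 * liver.suv_mean + 2.0 * liver.suv_sd
    return _threshold_mtv(suv_volume, grid, threshold, body.mask, "SSTR-MTV")
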