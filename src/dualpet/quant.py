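"""SUV/ACT quantification: decay arithmetic, SUV conversion, VOI statistics.

SUV uses body-weight normalisation with tissue density 1 g/mL:

    SUV = ACT [Bq/mL] * body weight [g] / (injected activity [Bq] decay-corrected
          to acquisition start)

SUVpeak is the maximum, over VOI voxels, of the mean SUV in a 1 mL sphere
centered at the voxel; the sphere may extend past the VOI but is clipped at
the grid boundary. SUVSD uses the population (n) denominator so that the
coefficient of variation of a synthetic uniform region is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .meta import ScanMeta
from .volume import VOI, ActivityVolume, Cylinder, Grid

COV_ADEQUACY_LIMIT_PERCENT = 15.0
"""EANM/EFOMP image-noise adequacy criterion: liver CoV below 15%."""

PEAK_SPHERE_VOLUME_ML = 1.0
PEAK_SPHERE_RADIUS_MM = (3.0 * PEAK_SPHERE_VOLUME_ML * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def decay_factor(delta_t_min: float, half_life_min: float) -> float:
    """Fraction of activity remaining after ``delta_t_min`` minutes.

    Returns ``2 ** (-delta_t_min / half_life_min)``.
    """
    if half_life_min <= 0:
        raise ValueError("half_life_min must be > 0")
    if delta_t_min < 0:
        raise ValueError("delta_t_min must be >= 0")
    return float(2.0 ** (-delta_t_min / half_life_min))


def elapsed_half_lives(meta1: ScanMeta, meta2: ScanMeta) -> float:
    """Half-lives of tracer 1 elapsed between the two acquisitions.

    Convention: end of the first acquisition to start of the second (the
    inter-scan interval is anchored to completion of the first scan).
    """
    interval = meta2.t_acq_start_min - meta1.t_acq_end_min
    if interval <= 0:
        raise ValueError("second acquisition must start after the first ends")
    return interval / meta1.half_life_min


def suv_to_act_factor(meta: ScanMeta) -> float:
    """Bq/mL per unit SUV: decayed injected activity over body weight in grams."""
    if meta.injected_activity_MBq <= 0 or meta.body_weight_kg <= 0:
        raise ValueError("injected activity and body weight must be > 0")
    decayed_bq = (
        meta.injected_activity_MBq
        * 1.0e6
        * decay_factor(meta.t_acq_start_min - meta.t_injection_min, meta.half_life_min)
    )
    return decayed_bq / (meta.body_weight_kg * 1000.0)


def act_to_suv(volume: ActivityVolume, meta: ScanMeta) -> np.ndarray:
    """Convert an activity-concentration volume (Bq/mL) to SUV."""
    return volume.values / suv_to_act_factor(meta)


# ---------------------------------------------------------------------------
# VOI placement


def place_cylinder_voi(
    grid: Grid,
    center_mm,
    radius_mm: float,
    height_mm: float,
    axis: int = 2,
    label: str = "cylinder",
) -> VOI:
    """Cylindrical VOI (default axis: cranio-caudal) from voxel centers inside.

    The center is snapped to the nearest voxel center so the voxelised
    volume does not depend on sub-voxel placement.
    """
    idx = grid.world_to_index(center_mm)
    snapped = tuple(grid.origin_mm[k] + idx[k] * grid.voxel_size_mm for k in range(3))
    cyl = Cylinder(snapped, radius_mm, height_mm, axis)
    mask = cyl.mask(grid)
    if not mask.any():
        raise ValueError("cylinder VOI contains no voxel centers (outside grid?)")
    prov = f"cylinder r={radius_mm}mm h={height_mm}mm axis={axis} at {tuple(center_mm)}"
    return VOI(mask, grid, label, prov)


def place_block_voi(grid: Grid, center_mm, target_volume_mL: float, label: str = "block") -> VOI:
    """Axis-aligned cuboid VOI whose voxel volume best matches the target.

    The edge lengths start from the cube root of the target and each axis is
    adjusted by one voxel to minimise the volume error; the result must land
    within 10% of the target.
    """
    if target_volume_mL < grid.voxel_volume_mL:
        raise ValueError("target volume smaller than one voxel")
    n_vox = target_volume_mL * 1000.0 / grid.voxel_size_mm**3
    n0 = max(1, round(n_vox ** (1.0 / 3.0)))
    best = None
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                ns = (n0 + dx, n0 + dy, n0 + dz)
                if min(ns) < 1:
                    continue
                err = abs(np.prod(ns) * grid.voxel_volume_mL - target_volume_mL)
                if best is None or err < best[0]:
                    best = (err, ns)
    _, ns = best
    center_idx = grid.world_to_index(center_mm)
    mask = np.zeros(grid.shape, dtype=bool)
    slices = []
    for k in range(3):
        lo = center_idx[k] - ns[k] // 2
        hi = lo + ns[k]
        if lo < 0 or hi > grid.shape[k]:
            raise ValueError("block VOI extends past the grid")
        slices.append(slice(lo, hi))
    mask[tuple(slices)] = True
    vol = mask.sum() * grid.voxel_volume_mL
    if abs(vol - target_volume_mL) > 0.10 * target_volume_mL:
        raise ValueError(
            f"block VOI volume {vol:.2f} mL misses target {target_volume_mL} mL by >10% "
            "(block partly outside grid?)"
        )
    prov = f"block target={target_volume_mL}mL at {tuple(center_mm)}"
    return VOI(mask, grid, label, prov)


# ---------------------------------------------------------------------------
# uptake statistics


@dataclass(frozen=True)
class UptakeStats:
    """Per-VOI uptake summary for one scan."""

    act_mean: float
    suv_mean: float
    suv_sd: float
    suv_max: float
    suv_peak: float
    volume_mL: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.suv_sd < 0:
            raise ValueError("suv_sd must be >= 0")


def _sphere_kernel(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    r_vox = radius_mm / voxel_size_mm
    n = int(np.floor(r_vox))
    ax = np.arange(-n, n + 1, dtype=float)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (dx**2 + dy**2 + dz**2) <= r_vox**2


def sphere_mean_map(values: np.ndarray, grid: Grid, mask: np.ndarray) -> np.ndarray:
    """Mean of ``values`` in a 1 mL sphere around each voxel of ``mask``.

    Computed on the mask's bounding box expanded by the sphere radius; sphere
    neighbourhoods are clipped at the grid boundary (voxels outside the grid
    do not contribute). Returns the map restricted to the expanded box shape
    together with nothing else; callers index it with the shifted mask.
    """
    kern = _sphere_kernel(PEAK_SPHERE_RADIUS_MM, grid.voxel_size_mm).astype(float)
    pad = kern.shape[0] // 2
    idx = np.nonzero(mask)
    lo = [max(0, int(idx[k].min()) - pad) for k in range(3)]
    hi = [min(grid.shape[k], int(idx[k].max()) + pad + 1) for k in range(3)]
    box = tuple(slice(lo[k], hi[k]) for k in range(3))
    sub = values[box]
    num = ndimage.convolve(sub, kern, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(sub), kern, mode="constant", cval=0.0)
    # interior voxels of the box whose sphere spills over a *box* edge that is
    # not a grid edge never carry the mask (box was expanded by the radius)
    peak_map = np.full(grid.shape, -np.inf)
    peak_map[box] = num / den
    return peak_map


def voi_stats(volume: ActivityVolume, voi: VOI, meta: ScanMeta) -> UptakeStats:
    """ACT/SUV statistics of a volume inside a VOI (population SD, 1 mL peak)."""
    if voi.grid != volume.grid:
        raise ValueError("VOI and volume are on different grids")
    if voi.empty:
        raise ValueError("VOI is empty")
    act = volume.values[voi.mask]
    factor = suv_to_act_factor(meta)
    suv = act / factor
    peak_map = sphere_mean_map(volume.values, volume.grid, voi.mask) / factor
    return UptakeStats(
        act_mean=float(act.mean()),
        suv_mean=float(suv.mean()),
        suv_sd=float(suv.std(ddof=0)),
        suv_max=float(suv.max()),
        suv_peak=float(peak_map[voi.mask].max()),
        volume_mL=voi.volume_mL,
        n_voxels=voi.n_voxels,
    )


def cov_percent(stats: UptakeStats) -> float:
    """Coefficient of variation, percent: 100 * SUVSD / SUVmean."""
    if stats.suv_mean <= 0:
        raise ValueError("CoV undefined for non-positive mean uptake")
    return 100.0 * stats.suv_sd / stats.suv_mean


def tlr(lesion: UptakeStats, liver: UptakeStats) -> tuple[float, float]:
    """Tumor-to-liver ratios (TLRmean, TLRpeak); denominator is liver SUVmean."""
    if liver.suv_mean <= 0:
        raise ValueError("liver SUVmean must be > 0")
    return lesion.suv_mean / liver.suv_mean, lesion.suv_peak / liver.suv_mean
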