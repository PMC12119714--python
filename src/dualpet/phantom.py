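"""Digital dual-tracer phantom: piecewise-constant organs, planted lesions,
image-space noise and the one-day two-scan acquisition with first-tracer
residual signal.

The phantom emulates the *measured structure* the analysis assumes — organ
SUV levels, lesion classes relative to liver background, reconstructed-image
noise with a realistic liver CoV — not the physics of acquisition. Noise is
Gaussian in image space with voxel SD = k * sqrt(voxel mean ACT); partial
volume and scanner PSF are not modelled (lesions are piecewise constant).

The second scan's activity is the pure second-tracer field plus the
*noiseless* first-scan field scaled by the decay-derived residual fraction
2^(-dt / T1/2); noise is then applied once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .meta import F18_HALF_LIFE_MIN, ProtocolTiming, ScanMeta
from .quant import decay_factor, suv_to_act_factor
from .volume import ActivityVolume, Cylinder, Ellipsoid, Grid, Shape

TRACERS = ("FDG", "SSTR")
CLASSES = ("FDG+/SSTR-", "FDG+/SSTR+", "FDG-/SSTR+")

#: lesion-class mixture of the reference cohort: 55/125, 25/125, 45/125
CLASS_PROBS = {"FDG+/SSTR-": 55 / 125, "FDG+/SSTR+": 25 / 125, "FDG-/SSTR+": 45 / 125}

#: class-mean tumor-to-liver ratios (TLRmean) per tracer, (FDG, SSTR)
CLASS_TLR_MEANS = {
    "FDG+/SSTR+": (3.1, 2.8),
    "FDG+/SSTR-": (3.4, 0.7),
    "FDG-/SSTR+": (0.9, 2.8),
}

ORGAN_LABELS = {"body": 1, "liver": 2, "brain": 3, "myocardium": 4, "blood_pool": 5}
LESION_LABEL_OFFSET = 100


@dataclass(frozen=True)
class OrganSpec:
    """One phantom organ: a geometric shape with per-tracer SUV."""

    name: str
    geometry: Shape
    suv_per_tracer: dict[str, float]

    def __post_init__(self) -> None:
        if self.name not in ORGAN_LABELS:
            raise ValueError(f"unknown organ name {self.name!r}")
        if any(v < 0 for v in self.suv_per_tracer.values()):
            raise ValueError("organ SUVs must be >= 0")
        if self.geometry.volume_mL <= 0:
            raise ValueError("organ geometry must have positive volume")


@dataclass(frozen=True)
class LesionSpec:
    """A planted ellipsoidal lesion inside a host organ."""

    organ: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv_fdg: float
    suv_sstr: float
    true_class: str

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown lesion class {self.true_class!r}")
        if self.suv_fdg < 0 or self.suv_sstr < 0:
            raise ValueError("lesion SUVs must be >= 0")

    @property
    def ellipsoid(self) -> Ellipsoid:
        return Ellipsoid(self.center_mm, self.radii_mm)

    @property
    def volume_mL(self) -> float:
        return self.ellipsoid.volume_mL


@dataclass(frozen=True)
class NoiseModel:
    """Image-space noise: voxel SD = scale * sqrt(voxel mean ACT)."""

    kind: str = "gaussian_sqrt"
    scale: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian_sqrt"):
            raise ValueError("noise kind must be 'none' or 'gaussian_sqrt'")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")


NO_NOISE = NoiseModel(kind="none", scale=0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Complete phantom description: grid, organs, lesions, background."""

    grid: Grid
    organs: tuple[OrganSpec, ...]
    lesions: tuple[LesionSpec, ...] = ()
    background_suv_per_tracer: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TRACERS}
    )

    def __post_init__(self) -> None:
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ValueError("organ names must be unique")
        if any(v < 0 for v in self.background_suv_per_tracer.values()):
            raise ValueError("background SUVs must be >= 0")

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)


@dataclass
class StudyTruth:
    """Ground truth carried alongside a simulated dual study."""

    labels: np.ndarray
    lesions: tuple[LesionSpec, ...]
    residual_fraction: float
    spec: PhantomSpec

    def lesion_mask(self, i: int) -> np.ndarray:
        return self.labels == LESION_LABEL_OFFSET + i


@dataclass
class DualStudy:
    """Two co-registered acquisitions of one phantom patient plus truth."""

    scan1: ActivityVolume
    meta1: ScanMeta
    scan2: ActivityVolume
    meta2: ScanMeta
    truth: StudyTruth
    patient_id: str = "p00"

    def __post_init__(self) -> None:
        if self.scan1.grid != self.scan2.grid:
            raise ValueError("the two scans must share one grid")
        if not 0.0 <= self.truth.residual_fraction <= 1.0:
            raise ValueError("residual fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# phantom construction


def build_phantom(spec: PhantomSpec) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Rasterise a phantom: per-tracer SUV volumes and an integer label volume.

    Priority: lesion over organ over body over background. Non-body organs
    must be pairwise disjoint and each lesion must lie inside its host organ.
    """
    grid = spec.grid
    suv = {t: np.full(grid.shape, spec.background_suv_per_tracer.get(t, 0.0)) for t in TRACERS}
    labels = np.zeros(grid.shape, dtype=np.int32)

    organ_masks: dict[str, np.ndarray] = {}
    body = next((o for o in spec.organs if o.name == "body"), None)
    if body is not None:
        organ_masks["body"] = body.geometry.mask(grid)
    occupied = np.zeros(grid.shape, bool)
    for organ in spec.organs:
        if organ.name == "body":
            continue
        mask = organ.geometry.mask(grid)
        if (mask & occupied).any():
            raise ValueError(f"organ {organ.name!r} overlaps another organ")
        occupied |= mask
        organ_masks[organ.name] = mask

    paint_order = [o for o in spec.organs if o.name == "body"] + [
        o for o in spec.organs if o.name != "body"
    ]
    for organ in paint_order:
        mask = organ_masks[organ.name]
        labels[mask] = ORGAN_LABELS[organ.name]
        for t in TRACERS:
            suv[t][mask] = organ.suv_per_tracer.get(t, 0.0)

    for i, lesion in enumerate(spec.lesions):
        mask = lesion.ellipsoid.mask(grid)
        if lesion.organ not in organ_masks:
            raise ValueError(f"lesion host organ {lesion.organ!r} not in phantom")
        if not mask.any():
            raise ValueError("lesion encloses no voxel centers")
        if not (labels[mask] == ORGAN_LABELS[lesion.organ]).all():
            raise ValueError(
                f"lesion {i} extends outside its host organ {lesion.organ!r} "
                "(or overlaps another structure)"
            )
        labels[mask] = LESION_LABEL_OFFSET + i
        suv["FDG"][mask] = lesion.suv_fdg
        suv["SSTR"][mask] = lesion.suv_sstr

    return suv, labels


def apply_noise(act: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Add image-space noise to a mean ACT field; negatives are clipped at 0."""
    if noise.kind == "none" or noise.scale == 0.0:
        return act.copy()
    sd = noise.scale * np.sqrt(np.clip(act, 0.0, None))
    noisy = act + rng.standard_normal(act.shape) * sd
    n_neg = int((noisy < 0).sum())
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative voxels to 0 after noise", stacklevel=2)
        noisy = np.clip(noisy, 0.0, None)
    return noisy


def simulate_acquisition(
    suv_volume: np.ndarray,
    grid: Grid,
    meta: ScanMeta,
    noise: NoiseModel = NO_NOISE,
    seed: int | np.random.Generator = 0,
) -> ActivityVolume:
    """Turn a SUV field into a measured ACT volume (inverse SUV + noise)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    act = np.asarray(suv_volume, float) * suv_to_act_factor(meta)
    return ActivityVolume(apply_noise(act, noise, rng), grid)


def simulate_dual_study(
    spec: PhantomSpec,
    protocol: ProtocolTiming = ProtocolTiming(),
    noise: NoiseModel = NO_NOISE,
    seed: int | np.random.SeedSequence = 0,
    body_weight_kg: float = 75.0,
    patient_id: str = "p00",
    residual_fraction: float | None = None,
) -> DualStudy:
    """Simulate the one-day dual-tracer protocol on a phantom.

    The residual fraction planted in scan 2 is ``2^(-dt/T1/2)`` with ``dt``
    the end-of-scan-1 to start-of-scan-2 interval (override it with
    ``residual_fraction`` for scenario experiments); the residual is added
    from the noiseless first-tracer field before scan-2 noise is applied once.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng1, rng2 = (np.random.default_rng(s) for s in seq.spawn(2))
    meta1, meta2 = protocol.scan_metas(body_weight_kg)
    suv, labels = build_phantom(spec)

    act1_clean = suv["FDG"] * suv_to_act_factor(meta1)
    scan1 = ActivityVolume(apply_noise(act1_clean, noise, rng1), spec.grid)

    if residual_fraction is not None:
        if not 0.0 <= residual_fraction <= 1.0:
            raise ValueError("residual_fraction must be in [0, 1]")
        fraction = float(residual_fraction)
    else:
        fraction = decay_factor(meta2.t_acq_start_min - meta1.t_acq_end_min,
                                meta1.half_life_min)
    act2_clean = suv["SSTR"] * suv_to_act_factor(meta2) + act1_clean * fraction
    scan2 = ActivityVolume(apply_noise(act2_clean, noise, rng2), spec.grid)

    truth = StudyTruth(labels=labels, lesions=spec.lesions,
                       residual_fraction=fraction, spec=spec)
    return DualStudy(scan1, meta1, scan2, meta2, truth, patient_id)


# ---------------------------------------------------------------------------
# default anthropomorphic-ish phantom


def default_organs() -> tuple[OrganSpec, ...]:
    """Compact whole-body phantom organs with the study's measured SUV levels.

    FDG scan: brain 6.0, myocardium 2.9, liver 2.0, blood 1.5, body 0.8.
    SSTR scan: liver 2.9, blood pool 1.1, myocardium at blood level 1.0,
    no brain uptake.
    """
    return (
        OrganSpec("body", Ellipsoid((0, 0, 0), (80, 75, 94)),
                  {"FDG": 0.8, "SSTR": 0.5}),
        OrganSpec("liver", Ellipsoid((30, -25, -35), (38, 28, 24)),
                  {"FDG": 2.0, "SSTR": 2.9}),
        OrganSpec("brain", Ellipsoid((0, 0, 62), (24, 24, 24)),
                  {"FDG": 6.0, "SSTR": 0.0}),
        OrganSpec("myocardium", Ellipsoid((-30, 18, 20), (13, 13, 13)),
                  {"FDG": 2.9, "SSTR": 1.0}),
        OrganSpec("blood_pool", Cylinder((0, 18, 0), 10.0, 70.0, axis=2),
                  {"FDG": 1.5, "SSTR": 1.1}),
    )


def default_grid(n: int = 96, voxel_size_mm: float = 2.0) -> Grid:
    """Default simulation grid: 96^3 at 2 mm (clinical 1.65 mm via config)."""
    return Grid.centered((n, n, n), voxel_size_mm)


def default_spec(grid: Grid | None = None,
                 lesions: tuple[LesionSpec, ...] = ()) -> PhantomSpec:
    return PhantomSpec(grid=grid or default_grid(), organs=default_organs(),
                       lesions=lesions)


#: offset of the healthy-liver background block from the liver center (mm);
#: lesions are kept out of this region so the background VOI stays clean
LIVER_BLOCK_OFFSET_MM = (14.0, 0.0, 0.0)


def liver_block_center(spec: PhantomSpec) -> tuple[float, float, float]:
    c = spec.organ("liver").geometry.center
    return tuple(c[k] + LIVER_BLOCK_OFFSET_MM[k] for k in range(3))


# ---------------------------------------------------------------------------
# (de)serialisation of phantom specs for the study-directory sidecars


def _shape_to_dict(shape: Shape) -> dict:
    if isinstance(shape, Ellipsoid):
        return {"kind": "ellipsoid", "center_mm": list(shape.center),
                "radii_mm": list(shape.radii)}
    if isinstance(shape, Cylinder):
        return {"kind": "cylinder", "center_mm": list(shape.center),
                "radius_mm": shape.radius_mm, "height_mm": shape.height_mm,
                "axis": shape.axis}
    raise TypeError(f"unsupported shape {type(shape).__name__}")


def _shape_from_dict(d: dict) -> Shape:
    if d["kind"] == "ellipsoid":
        return Ellipsoid(tuple(d["center_mm"]), tuple(d["radii_mm"]))
    if d["kind"] == "cylinder":
        return Cylinder(tuple(d["center_mm"]), d["radius_mm"], d["height_mm"], d["axis"])
    raise ValueError(f"unknown shape kind {d['kind']!r}")


def spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "grid": {"shape": list(spec.grid.shape),
                 "voxel_size_mm": spec.grid.voxel_size_mm,
                 "origin_mm": list(spec.grid.origin_mm)},
        "organs": [
            {"name": o.name, "geometry": _shape_to_dict(o.geometry),
             "suv_per_tracer": dict(o.suv_per_tracer)}
            for o in spec.organs
        ],
        "lesions": [
            {"organ": l.organ, "center_mm": list(l.center_mm),
             "radii_mm": list(l.radii_mm), "suv_fdg": l.suv_fdg,
             "suv_sstr": l.suv_sstr, "true_class": l.true_class}
            for l in spec.lesions
        ],
        "background_suv_per_tracer": dict(spec.background_suv_per_tracer),
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    grid = Grid(tuple(d["grid"]["shape"]), d["grid"]["voxel_size_mm"],
                tuple(d["grid"]["origin_mm"]))
    organs = tuple(
        OrganSpec(o["name"], _shape_from_dict(o["geometry"]), dict(o["suv_per_tracer"]))
        for o in d["organs"]
    )
    lesions = tuple(
        LesionSpec(l["organ"], tuple(l["center_mm"]), tuple(l["radii_mm"]),
                   l["suv_fdg"], l["suv_sstr"], l["true_class"])
        for l in d["lesions"]
    )
    return PhantomSpec(grid, organs, lesions, dict(d["background_suv_per_tracer"]))


# ---------------------------------------------------------------------------
# cohort generator


def _sample_lesion_tlrs(true_class: str, rng: np.random.Generator) -> tuple[float, float]:
    """Draw per-lesion (TLR_fdg, TLR_sstr) around the class means.

    Positive TLRs: lognormal around the class mean (sigma 0.25), truncated to
    [1.2, 6]. Negative TLRs: normal truncated below 1 (upper bound 0.93 keeps
    the planted class consistent with the measured-TLR rule after residual
    first-tracer signal is added to the second scan).
    """

    def positive(mean: float) -> float:
        for _ in range(100):
            v = float(np.exp(np.log(mean) + 0.25 * rng.standard_normal()))
            if 1.2 <= v <= 6.0:
                return v
        return mean

    def negative(mean: float, sd: float) -> float:
        for _ in range(100):
            v = float(mean + sd * rng.standard_normal())
            if 0.3 <= v <= 0.93:
                return v
        return min(mean, 0.93)

    m_fdg, m_sstr = CLASS_TLR_MEANS[true_class]
    tlr_fdg = positive(m_fdg) if true_class.startswith("FDG+") else negative(0.88, 0.05)
    tlr_sstr = positive(m_sstr) if true_class.endswith("SSTR+") else negative(m_sstr, 0.10)
    return tlr_fdg, tlr_sstr


def _place_lesions(
    organs: tuple[OrganSpec, ...],
    n_lesions: int,
    rng: np.random.Generator,
    liver_suv: dict[str, float],
) -> tuple[LesionSpec, ...]:
    """Rejection-sample non-overlapping ellipsoidal lesions in liver and body."""
    liver = next(o for o in organs if o.name == "liver").geometry
    body = next(o for o in organs if o.name == "body").geometry
    keepout: list[Ellipsoid] = [
        Ellipsoid(o.geometry.center, (r + 6.0,) * 3)
        for o, r in (
            (next(o for o in organs if o.name == "brain"), 24.0),
            (next(o for o in organs if o.name == "myocardium"), 13.0),
            (next(o for o in organs if o.name == "blood_pool"), 36.0),
        )
    ]
    counts = {"liver": 0, "body": 0}
    placed: list[LesionSpec] = []
    classes = rng.choice(list(CLASS_PROBS), size=n_lesions, p=list(CLASS_PROBS.values()))
    block_center = tuple(liver.center[k] + LIVER_BLOCK_OFFSET_MM[k] for k in range(3))
    block_keepout = Ellipsoid(block_center, (19.0,) * 3)
    liver_keepout = Ellipsoid(liver.center, tuple(r + 4 for r in liver.radii))

    def try_place(host_name: str, radii: tuple[float, float, float]):
        host = liver if host_name == "liver" else body
        rmax = max(radii)
        for _ in range(400):
            u = rng.uniform(-1, 1, size=3)
            cand = tuple(host.center[k] + u[k] * (host.radii[k] - rmax - 2.0)
                         for k in range(3))
            cand_el = Ellipsoid(cand, radii)
            # conservative containment: center inside host shrunk by the
            # lesion's bounding-sphere radius (Minkowski inner bound)
            margin = sum(((cand[k] - host.center[k]) / (host.radii[k] - rmax - 1.0)) ** 2
                         for k in range(3))
            if margin > 1.0:
                continue
            # healthy-liver background block stays lesion-free
            if _ellipsoids_close(cand_el, block_keepout):
                continue
            if host_name == "body":
                if any(_ellipsoids_close(cand_el, ko) for ko in keepout):
                    continue
                if _ellipsoids_close(cand_el, liver_keepout):
                    continue
            if any(_ellipsoids_close(cand_el, p.ellipsoid) for p in placed):
                continue
            return cand
        return None

    for true_class in classes:
        # hosts alternate, capped at five representative lesions per organ
        preferred = "liver" if counts["liver"] <= counts["body"] else "body"
        other = "body" if preferred == "liver" else "liver"
        radii = tuple(float(np.clip(rng.lognormal(np.log(6.5), 0.2), 5.0, 9.0))
                      for _ in range(3))
        center = None
        host_name = preferred
        for host_name in (preferred, other):
            if counts[host_name] >= 5:
                continue
            center = try_place(host_name, radii)
            if center is not None:
                break
        if center is None:
            continue
        tlr_fdg, tlr_sstr = _sample_lesion_tlrs(str(true_class), rng)
        placed.append(
            LesionSpec(
                organ=host_name,
                center_mm=center,
                radii_mm=radii,
                suv_fdg=tlr_fdg * liver_suv["FDG"],
                suv_sstr=tlr_sstr * liver_suv["SSTR"],
                true_class=str(true_class),
            )
        )
        counts[host_name] += 1
    return tuple(placed)


def _ellipsoids_close(a: Ellipsoid, b: Ellipsoid) -> bool:
    # 6 mm margin keeps bounded lesion VOIs (lesion extent + 4 mm) disjoint
    d = np.linalg.norm(np.subtract(a.center, b.center))
    return d < max(a.radii) + max(b.radii) + 6.0


def paper_like_cohort(
    n_patients: int,
    seed: int | np.random.SeedSequence = 0,
    noise: NoiseModel = NoiseModel(),
    grid: Grid | None = None,
    mean_lesions_per_patient: float = 6.25,
    protocol: ProtocolTiming = ProtocolTiming(),
) -> list[DualStudy]:
    """Simulate a cohort with the reference study's lesion-class structure.

    Lesion classes are drawn with probabilities 55/125, 25/125, 45/125 and
    per-lesion TLRs around the class means; patient weights vary around
    75 kg and the inter-scan interval around 4.2 h (SD 0.09 h).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    grid = grid or default_grid()
    organs = default_organs()
    liver_suv = next(o for o in organs if o.name == "liver").suv_per_tracer
    total = int(round(mean_lesions_per_patient * n_patients))
    base, extra = divmod(total, n_patients)
    studies: list[DualStudy] = []
    for i, child in enumerate(seq.spawn(n_patients)):
        rng = np.random.default_rng(child)
        n_lesions = base + (1 if i < extra else 0)
        lesions = _place_lesions(organs, n_lesions, rng, liver_suv)
        spec = PhantomSpec(grid=grid, organs=organs, lesions=lesions)
        weight = float(np.clip(rng.normal(75.0, 10.0), 50.0, 110.0))
        interval = float(max(protocol.interval_after_scan1_min + rng.normal(0.0, 0.09 * 60.0),
                             30.0))
        proto = replace(protocol, interval_after_scan1_min=interval)
        studies.append(
            simulate_dual_study(spec, proto, noise, seed=child.spawn(1)[0],
                                body_weight_kg=weight, patient_id=f"p{i:02d}")
        )
    return studies
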