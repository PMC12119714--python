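"""End-to-end orchestration: simulate -> quantify -> segment -> residual ->
classify -> report, with a plain study-directory layout for every stage.

A *study directory* holds one patient's co-registered dual-tracer study:

    pNN/
      scan1_act.nii, scan2_act.nii      activity volumes (Bq/mL)
      scan1_meta.json, scan2_meta.json  acquisition metadata
      truth_labels.nii                  structure labels (phantom ground truth)
      truth.json                        phantom spec + planted residual fraction

Stage outputs (``organ_stats.csv``, ``lesions.csv``, ``crosstalk_*.csv/json``)
land next to the inputs; cohort-level tables land in the run root. Outputs
are written deterministically (sorted keys, fixed float format, uncompressed
NIfTI) so a fixed seed reproduces the bundle bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CohortSummary, LesionRecord, cohort_tables, records_to_frame
from .meta import ProtocolTiming, ScanMeta
from .phantom import (
    DualStudy,
    NoiseModel,
    PhantomSpec,
    StudyTruth,
    default_grid,
    default_organs,
    liver_block_center,
    paper_like_cohort,
    simulate_dual_study,
    spec_from_dict,
    spec_to_dict,
)
from .quant import act_to_suv, place_block_voi, place_cylinder_voi, tlr, voi_stats
from .residual import (
    DEFAULT_SCENARIOS,
    CrossTalkReport,
    ResidualScenario,
    crosstalk_from_study,
    organ_carryover_tests,
)
from .segmentation import (
    MTVResult,
    brain_auto_segment,
    fdg_mtv,
    isocontour_41,
    lesion_filter,
    sstr_mtv,
)
from .volume import VOI, ActivityVolume, Box, Grid, load_nifti, save_nifti

LIVER_BLOCK_ML = 14.0
BLOOD_CYL_MM = (8.0, 14.9)   # radius, height -> 3 cm^3
MYO_CYL_MM = (5.0, 12.7)     # radius, height -> 1 cm^3
_FLOAT_FMT = "%.8g"


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


# ---------------------------------------------------------------------------
# configuration


def validate_config(config: dict) -> dict:
    """Check a run configuration before any compute; returns the config."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    if ("cohort" in config) == ("study" in config):
        raise ConfigError("config needs exactly one of 'cohort' or 'study'")
    if "cohort" in config:
        if "n_patients" not in config["cohort"]:
            raise ConfigError("cohort config requires 'n_patients'")
        if int(config["cohort"]["n_patients"]) < 1:
            raise ConfigError("n_patients must be >= 1")
    else:
        if "body_weight_kg" not in config["study"]:
            raise ConfigError("study config requires 'body_weight_kg'")
        if float(config["study"]["body_weight_kg"]) <= 0:
            raise ConfigError("body_weight_kg must be > 0")
    noise = config.get("noise", {})
    if noise and noise.get("kind", "gaussian_sqrt") not in ("none", "gaussian_sqrt"):
        raise ConfigError("noise.kind must be 'none' or 'gaussian_sqrt'")
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _grid_from_config(config: dict) -> Grid:
    g = config.get("grid", {})
    return default_grid(int(g.get("n", 96)), float(g.get("voxel_size_mm", 2.0)))


def _noise_from_config(config: dict) -> NoiseModel:
    n = config.get("noise", {})
    return NoiseModel(kind=n.get("kind", "gaussian_sqrt"), scale=float(n.get("scale", 4.0)))


def _protocol_from_config(config: dict) -> ProtocolTiming:
    return ProtocolTiming(**config.get("protocol", {}))


def _scenarios_from_config(config: dict) -> tuple[ResidualScenario, ...]:
    names = config.get("scenarios")
    if not names:
        return DEFAULT_SCENARIOS
    out = []
    for name in names:
        if str(name).lower() == "decay":
            out.append(ResidualScenario("decay", None))
        else:
            frac = float(str(name).rstrip("%").lstrip("rR")) / 100.0
            out.append(ResidualScenario(f"R{frac * 100:g}%", frac))
    return tuple(out)


# ---------------------------------------------------------------------------
# study directory IO


def write_study_dir(study: DualStudy, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = study.scan1.grid
    save_nifti(study.scan1.values.astype(np.float32), grid, out / "scan1_act.nii")
    save_nifti(study.scan2.values.astype(np.float32), grid, out / "scan2_act.nii")
    study.meta1.to_json(out / "scan1_meta.json")
    study.meta2.to_json(out / "scan2_meta.json")
    save_nifti(study.truth.labels.astype(np.int16), grid, out / "truth_labels.nii")
    truth = {
        "patient_id": study.patient_id,
        "residual_fraction": study.truth.residual_fraction,
        "spec": spec_to_dict(study.truth.spec),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return out


def load_study_dir(study_dir: str | Path) -> DualStudy:
    d = Path(study_dir)
    v1, grid = load_nifti(d / "scan1_act.nii")
    v2, _ = load_nifti(d / "scan2_act.nii")
    labels, _ = load_nifti(d / "truth_labels.nii")
    truth_meta = json.loads((d / "truth.json").read_text())
    spec = spec_from_dict(truth_meta["spec"])
    truth = StudyTruth(labels.astype(np.int32), spec.lesions,
                       truth_meta["residual_fraction"], spec)
    return DualStudy(
        ActivityVolume(v1, grid), ScanMeta.from_json(d / "scan1_meta.json"),
        ActivityVolume(v2, grid), ScanMeta.from_json(d / "scan2_meta.json"),
        truth, truth_meta["patient_id"],
    )


# ---------------------------------------------------------------------------
# per-study analysis


@dataclass
class StudyAnalysis:
    """All quantification products of one dual-tracer study."""

    patient_id: str
    records: list[LesionRecord]
    organ_pairs: pd.DataFrame
    crosstalk: CrossTalkReport
    fdg_mtv_mL: float
    sstr_mtv_mL: float
    discordant_mtv_mL: float
    organ_vois: dict[str, VOI]
    mtv_results: dict[str, MTVResult] | None = None
    lesion_vois: dict[str, VOI] | None = None


def place_organ_vois(study: DualStudy) -> dict[str, VOI]:
    """Fixed-geometry organ VOIs from the phantom's known placement.

    Liver: 14 mL block in the healthy lobe; blood pool: 3 cm^3 cylinder in
    the descending aorta; myocardium: 1 cm^3 cylinder in the posterior wall.
    The brain VOI is threshold-derived separately.
    """
    spec = study.truth.spec
    grid = study.scan1.grid
    vois = {
        "liver": place_block_voi(grid, liver_block_center(spec), LIVER_BLOCK_ML, "liver"),
        "blood_pool": place_cylinder_voi(
            grid, spec.organ("blood_pool").geometry.center, *BLOOD_CYL_MM,
            label="blood_pool"),
        "myocardium": place_cylinder_voi(
            grid, spec.organ("myocardium").geometry.center, *MYO_CYL_MM,
            label="myocardium"),
    }
    return vois


def analyze_study(
    study: DualStudy,
    scenarios: tuple[ResidualScenario, ...] = DEFAULT_SCENARIOS,
) -> StudyAnalysis:
    """Quantify, segment and classify one dual-tracer study.

    Lesion VOIs are 41% isocontours seeded at the planted lesion centers on
    the scan with the higher seed-voxel SUV; statistics are then read from
    both co-registered scans in that VOI. The representative-lesion rule
    (>= 0.5 mL, top five per organ) is applied before classification.
    """
    grid = study.scan1.grid
    spec = study.truth.spec
    suv1 = act_to_suv(study.scan1, study.meta1)
    suv2 = act_to_suv(study.scan2, study.meta2)

    vois = place_organ_vois(study)
    blood1 = voi_stats(study.scan1, vois["blood_pool"], study.meta1)
    brain_geom = spec.organ("brain").geometry
    head = VOI(Box(brain_geom.center, (52.0, 52.0, 52.0)).mask(grid), grid, "head", "box")
    vois["brain"] = brain_auto_segment(suv1, grid, blood1, head)

    liver1 = voi_stats(study.scan1, vois["liver"], study.meta1)
    liver2 = voi_stats(study.scan2, vois["liver"], study.meta2)

    organ_rows = []
    for name in ("brain", "myocardium", "blood_pool", "liver"):
        voi = vois[name]
        if voi.empty:
            continue
        organ_rows.append({
            "patient_id": study.patient_id,
            "organ": name,
            "suv_mean_scan1": voi_stats(study.scan1, voi, study.meta1).suv_mean,
            "suv_mean_scan2": voi_stats(study.scan2, voi, study.meta2).suv_mean,
            "volume_mL": voi.volume_mL,
        })
    organ_pairs = pd.DataFrame(organ_rows)

    # lesion segmentation on the dominant scan, statistics on both scans
    records: list[LesionRecord] = []
    lesion_vois: dict[str, VOI] = {}
    for i, lesion in enumerate(study.truth.lesions):
        idx = grid.world_to_index(lesion.center_mm)
        dominant = suv1 if suv1[idx] >= suv2[idx] else suv2
        lesion_id = f"{study.patient_id}-L{i:02d}"
        # seeds are lesion centers, so the local-max search stays within the
        # lesion's own extent (a wider radius could leak to a hotter neighbor);
        # the bounding sphere plays the reader's bounding region and keeps
        # low-contrast lesions from flooding into the host organ
        voi = isocontour_41(dominant, grid, lesion.center_mm,
                            search_radius_mm=max(lesion.radii_mm),
                            bounding_radius_mm=max(lesion.radii_mm) + 4.0,
                            label=lesion_id)
        lesion_vois[lesion_id] = voi
        stats = {
            "FDG": voi_stats(study.scan1, voi, study.meta1),
            "SSTR": voi_stats(study.scan2, voi, study.meta2),
        }
        tlr_fdg = tlr(stats["FDG"], liver1)
        tlr_sstr = tlr(stats["SSTR"], liver2)
        rec = LesionRecord(
            lesion_id=lesion_id,
            patient_id=study.patient_id,
            organ=lesion.organ,
            stats=stats,
            tlr_mean={"FDG": tlr_fdg[0], "SSTR": tlr_sstr[0]},
            tlr_peak={"FDG": tlr_fdg[1], "SSTR": tlr_sstr[1]},
            volume_mL=voi.volume_mL,
            true_class=lesion.true_class,
        )
        records.append(rec)
    records = lesion_filter(records)
    for rec in records:
        rec.classify()

    # tumor volumes; physiological uptake excluded from the glucose MTV
    body_voi = VOI(study.truth.labels > 0, grid, "body", "truth labels")
    exclusions = [vois["brain"]]
    for name, lab in (("myocardium", 4), ("blood_pool", 5)):
        exclusions.append(VOI(study.truth.labels == lab, grid, name, "truth labels"))
    mtv_f = fdg_mtv(suv1, grid, body_voi, exclusions)
    mtv_s = sstr_mtv(suv2, grid, liver2, body_voi)
    discordant = float((mtv_f.voi.mask & ~mtv_s.voi.mask).sum()) * grid.voxel_volume_mL

    kept_vois = {r.lesion_id: lesion_vois[r.lesion_id] for r in records}
    crosstalk = crosstalk_from_study(study, kept_vois, vois, scenarios)

    return StudyAnalysis(
        patient_id=study.patient_id,
        records=records,
        organ_pairs=organ_pairs,
        crosstalk=crosstalk,
        fdg_mtv_mL=mtv_f.total_volume_mL,
        sstr_mtv_mL=mtv_s.total_volume_mL,
        discordant_mtv_mL=discordant,
        organ_vois=vois,
        mtv_results={"FDG": mtv_f, "SSTR": mtv_s},
        lesion_vois=kept_vois,
    )


# ---------------------------------------------------------------------------
# cohort analysis and the full run


@dataclass
class RunResult:
    """Bundle of a full pipeline run."""

    analyses: list[StudyAnalysis]
    summary: CohortSummary
    organ_tests: pd.DataFrame
    crosstalk_cohort: pd.DataFrame
    out_dir: Path | None = None


def analyze_cohort(
    studies: list[DualStudy],
    scenarios: tuple[ResidualScenario, ...] = DEFAULT_SCENARIOS,
) -> RunResult:
    analyses = [analyze_study(s, scenarios) for s in studies]
    records = [r for a in analyses for r in a.records]
    mtvs = pd.DataFrame([
        {"patient_id": a.patient_id, "fdg_mtv_mL": a.fdg_mtv_mL,
         "sstr_mtv_mL": a.sstr_mtv_mL, "discordant_mtv_mL": a.discordant_mtv_mL,
         "fdg_mtv_threshold_suv": a.mtv_results["FDG"].threshold_suv,
         "sstr_mtv_threshold_suv": a.mtv_results["SSTR"].threshold_suv,
         "fdg_mtv_n_components": len(a.mtv_results["FDG"].per_component),
         "sstr_mtv_n_components": len(a.mtv_results["SSTR"].per_component)}
        for a in analyses
    ])
    summary = cohort_tables(records, mtvs)
    organ_pairs = pd.concat([a.organ_pairs for a in analyses], ignore_index=True)
    organ_tests = organ_carryover_tests(organ_pairs)
    lesion_rows = pd.concat([a.crosstalk.lesion_rows for a in analyses], ignore_index=True)
    return RunResult(analyses, summary, organ_tests, lesion_rows)


def simulate_from_config(config: dict, seed: int) -> list[DualStudy]:
    validate_config(config)
    grid = _grid_from_config(config)
    noise = _noise_from_config(config)
    protocol = _protocol_from_config(config)
    if "cohort" in config:
        c = config["cohort"]
        return paper_like_cohort(
            int(c["n_patients"]), seed=seed, noise=noise, grid=grid,
            mean_lesions_per_patient=float(c.get("mean_lesions_per_patient", 6.25)),
            protocol=protocol,
        )
    s = config["study"]
    spec = PhantomSpec(grid=grid, organs=default_organs())
    return [simulate_dual_study(spec, protocol, noise, seed=seed,
                                body_weight_kg=float(s["body_weight_kg"]))]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: dict, seed: int, out_dir: str | Path) -> RunResult:
    """Execute the full pipeline and write a deterministic output bundle."""
    try:
        validate_config(config)
    except ConfigError:
        raise
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = _scenarios_from_config(config)

    stage = "simulate"
    try:
        studies = simulate_from_config(config, seed)
        for study in studies:
            write_study_dir(study, out / study.patient_id)
        stage = "analyze"
        result = analyze_cohort(studies, scenarios)
        stage = "report"
        for a in result.analyses:
            sdir = out / a.patient_id
            _write_csv(a.organ_pairs, sdir / "organ_stats.csv")
            _write_csv(records_to_frame(a.records), sdir / "lesions.csv")
            _write_csv(a.crosstalk.lesion_rows, sdir / "crosstalk_lesions.csv")
            _write_mask_volumes(a, sdir)
            (sdir / "crosstalk_summary.json").write_text(
                json.dumps(a.crosstalk.cohort_means(), indent=2, sort_keys=True) + "\n")
        result.summary.counts.to_csv(out / "class_counts.csv", float_format=_FLOAT_FMT)
        result.summary.tlr_groups.to_csv(out / "tlr_groups.csv", float_format=_FLOAT_FMT)
        _write_csv(result.summary.mtv_per_patient, out / "mtv.csv")
        _write_csv(result.organ_tests, out / "organ_tests.csv")
        _write_csv(result.crosstalk_cohort, out / "crosstalk_cohort.csv")
        (out / "cohort.json").write_text(
            json.dumps(result.summary.to_json_dict(), indent=2, sort_keys=True,
                       default=float) + "\n")
        _write_run_log(config, seed, out)
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    result.out_dir = out
    return result


def _write_mask_volumes(analysis: StudyAnalysis, sdir: Path) -> None:
    """Segmentation outputs as NIfTI label volumes.

    ``mtv_labels.nii``: 1 = FDG-MTV only, 2 = SSTR-MTV only, 3 = both.
    ``lesion_labels.nii``: representative-lesion VOIs numbered from 1 in
    ``lesions.csv`` row order.
    """
    mtv_f = analysis.mtv_results["FDG"]
    mtv_s = analysis.mtv_results["SSTR"]
    grid = mtv_f.voi.grid
    labels = mtv_f.voi.mask.astype(np.int16) + 2 * mtv_s.voi.mask.astype(np.int16)
    save_nifti(labels, grid, sdir / "mtv_labels.nii")
    lesion_labels = np.zeros(grid.shape, dtype=np.int16)
    for i, rec in enumerate(analysis.records, start=1):
        lesion_labels[analysis.lesion_vois[rec.lesion_id].mask] = i
    save_nifti(lesion_labels, grid, sdir / "lesion_labels.nii")


def _write_run_log(config: dict, seed: int, out: Path) -> None:
    import scipy

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    lines = [
        f"dualpet {__version__}",
        f"numpy {np.__version__}  scipy {scipy.__version__}  pandas {pd.__version__}",
        f"seed {seed}",
        f"config sha256 {cfg_hash}",
    ]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def demo_config() -> dict:
    """The packaged demo configuration (two-patient cohort, default noise)."""
    path = Path(__file__).parent / "data" / "demo_config.yaml"
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))
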