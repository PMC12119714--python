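"""Dual-tracer lesion classification and cohort summary tables.

A lesion is negative for a tracer when its tumor-to-liver ratio (TLRmean) is
at or below 1.0, positive when strictly above. The dual-tracer classes are
FDG+/SSTR-, FDG+/SSTR+ and FDG-/SSTR+; lesions negative on both scans fall
outside that scheme and are retained as ``double-negative`` with a warning
rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import UptakeStats

TLR_NEGATIVITY_LIMIT = 1.0
DOUBLE_NEGATIVE = "double-negative"
CLASS_ORDER = ("FDG+/SSTR-", "FDG+/SSTR+", "FDG-/SSTR+", DOUBLE_NEGATIVE)


def classify_lesion(tlr_fdg: float, tlr_sstr: float) -> str:
    """Dual-tracer class from the two TLRmean values (negativity at <= 1.0)."""
    if tlr_fdg < 0 or tlr_sstr < 0:
        raise ValueError("TLRs must be >= 0")
    fdg_pos = tlr_fdg > TLR_NEGATIVITY_LIMIT
    sstr_pos = tlr_sstr > TLR_NEGATIVITY_LIMIT
    if fdg_pos and sstr_pos:
        return "FDG+/SSTR+"
    if fdg_pos:
        return "FDG+/SSTR-"
    if sstr_pos:
        return "FDG-/SSTR+"
    warnings.warn("lesion negative on both tracers (double-negative)", stacklevel=2)
    return DOUBLE_NEGATIVE


@dataclass
class LesionRecord:
    """Per-lesion, per-tracer quantification used for classification."""

    lesion_id: str
    patient_id: str
    organ: str
    stats: dict[str, UptakeStats]
    tlr_mean: dict[str, float]
    tlr_peak: dict[str, float]
    dual_class: str = ""
    volume_mL: float = 0.0
    true_class: str | None = None

    @property
    def suv_max(self) -> float:
        return max(s.suv_max for s in self.stats.values())

    def classify(self) -> str:
        self.dual_class = classify_lesion(self.tlr_mean["FDG"], self.tlr_mean["SSTR"])
        return self.dual_class


@dataclass
class CohortSummary:
    """Cohort tables: class counts by organ, group TLRs, per-patient MTVs."""

    counts: pd.DataFrame
    """organ x class count matrix with a Total row."""
    tlr_groups: pd.DataFrame
    """per class: n, TLRmean/TLRpeak mean +/- SE for each tracer."""
    mtv_per_patient: pd.DataFrame
    """patient_id, fdg_mtv_mL, sstr_mtv_mL, discordant_mtv_mL, discordant flag."""
    n_lesions: int = 0

    def to_json_dict(self) -> dict:
        return {
            "n_lesions": self.n_lesions,
            "counts": {
                organ: {c: int(v) for c, v in row.items()}
                for organ, row in self.counts.iterrows()
            },
            "tlr_groups": self.tlr_groups.to_dict(orient="index"),
            "mtv_per_patient": self.mtv_per_patient.to_dict(orient="records"),
        }


def records_to_frame(records: list[LesionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "lesion_id": r.lesion_id,
            "patient_id": r.patient_id,
            "organ": r.organ,
            "volume_mL": r.volume_mL,
            "dual_class": r.dual_class,
            "true_class": r.true_class,
        }
        for tracer, s in r.stats.items():
            t = tracer.lower()
            row.update({
                f"act_mean_{t}": s.act_mean,
                f"suv_mean_{t}": s.suv_mean,
                f"suv_sd_{t}": s.suv_sd,
                f"suv_max_{t}": s.suv_max,
                f"suv_peak_{t}": s.suv_peak,
                f"tlr_mean_{t}": r.tlr_mean[tracer],
                f"tlr_peak_{t}": r.tlr_peak[tracer],
            })
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_tables(records: list[LesionRecord],
                  mtvs: pd.DataFrame | None = None) -> CohortSummary:
    """Build the cohort summary from classified lesion records.

    ``mtvs`` carries one row per patient with ``patient_id``, ``fdg_mtv_mL``,
    ``sstr_mtv_mL`` and optionally ``discordant_mtv_mL`` (glucose-avid volume
    outside the SSTR volume). The discordant flag is true when the patient
    has any FDG+/SSTR- lesion or a positive discordant MTV.
    """
    classes = list(CLASS_ORDER)
    organs = sorted({r.organ for r in records})
    counts = pd.DataFrame(0, index=organs + ["Total"], columns=classes, dtype=int)
    for r in records:
        if not r.dual_class:
            raise ValueError(f"lesion {r.lesion_id} is not classified")
        counts.loc[r.organ, r.dual_class] += 1
        counts.loc["Total", r.dual_class] += 1

    group_rows = {}
    df = records_to_frame(records) if records else pd.DataFrame()
    for cls in classes:
        sub = df[df["dual_class"] == cls] if len(df) else df
        n = len(sub)
        row: dict[str, float] = {"n": n}
        for col in ("tlr_mean_fdg", "tlr_mean_sstr", "tlr_peak_fdg", "tlr_peak_sstr"):
            if n:
                vals = sub[col].to_numpy(float)
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            else:
                row[f"{col}_mean"] = float("nan")
                row[f"{col}_se"] = float("nan")
        group_rows[cls] = row
    tlr_groups = pd.DataFrame.from_dict(group_rows, orient="index")

    if mtvs is None:
        mtvs = pd.DataFrame(columns=["patient_id", "fdg_mtv_mL", "sstr_mtv_mL"])
    mtvs = mtvs.copy()
    if "discordant_mtv_mL" not in mtvs.columns:
        mtvs["discordant_mtv_mL"] = 0.0
    discordant_patients = {r.patient_id for r in records if r.dual_class == "FDG+/SSTR-"}
    mtvs["discordant"] = mtvs.apply(
        lambda row: bool(row["patient_id"] in discordant_patients
                         or row["discordant_mtv_mL"] > 0),
        axis=1,
    ) if len(mtvs) else pd.Series(dtype=bool)

    return CohortSummary(counts, tlr_groups, mtvs, n_lesions=len(records))
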