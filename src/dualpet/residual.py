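"""Residual first-tracer activity scenarios and second-scan contamination.

The one-day protocol leaves a decaying remnant of the first tracer in the
second acquisition. Scenarios are multiplicative fractions applied to the
first-scan lesion ACTs: the physical-decay fraction ``2^(-dt/T1/2)`` or fixed
worst cases such as R15% (shortest-interval decay) and R20% (decay plus a
margin for continued first-tracer trapping). Contamination is the residual
as a percentage of the *measured* second-scan ACT, and cohort summaries are
means of per-lesion percentages (mean of ratios, not ratio of means) with
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import DualStudy
from .quant import decay_factor
from .stats import paired_rank_test
from .volume import VOI


@dataclass(frozen=True)
class ResidualScenario:
    """Named residual-fraction assumption applied to first-scan ACTs."""

    label: str
    fraction: float | None = None
    """Fixed fraction in [0, 1]; ``None`` means compute from the decay timing."""

    def __post_init__(self) -> None:
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValueError("scenario fraction must be in [0, 1]")

    @property
    def is_decay(self) -> bool:
        return self.fraction is None

    def resolve(self, delta_t_min: float | None = None,
                half_life_min: float | None = None) -> float:
        if not self.is_decay:
            return float(self.fraction)
        if delta_t_min is None or half_life_min is None:
            raise ValueError("decay scenario needs the inter-scan timing")
        return decay_factor(delta_t_min, half_life_min)


R15 = ResidualScenario("R15%", 0.15)
R20 = ResidualScenario("R20%", 0.20)
DECAY = ResidualScenario("decay", None)
DEFAULT_SCENARIOS = (R15, R20, DECAY)


def residual_act(act_scan1: float, scenario: ResidualScenario,
                 delta_t_min: float | None = None,
                 half_life_min: float | None = None) -> float:
    """Residual first-tracer ACT (Bq/mL) under a scenario."""
    if act_scan1 < 0:
        raise ValueError("act_scan1 must be >= 0")
    return act_scan1 * scenario.resolve(delta_t_min, half_life_min)


def contamination_percent(residual: float, act_scan2: float) -> float:
    """Residual ACT as a percentage of the measured second-scan ACT."""
    if act_scan2 <= 0:
        raise ValueError("second-scan ACT must be > 0 (flag lesion as SSTR-absent)")
    return 100.0 * residual / act_scan2


def infer_residual_fraction(study: DualStudy, organ_voi: VOI) -> tuple[float, float]:
    """Estimate the planted residual fraction from an organ without
    second-tracer uptake (brain): ratio of scan-2 to scan-1 mean ACT.

    Returns (fraction, standard error) with the SE from the delta method.
    """
    if organ_voi.empty:
        raise ValueError("organ VOI is empty")
    a1 = study.scan1.values[organ_voi.mask]
    a2 = study.scan2.values[organ_voi.mask]
    m1, m2 = float(a1.mean()), float(a2.mean())
    if m1 <= 0:
        raise ValueError("scan-1 organ mean must be > 0")
    n = a1.size
    frac = m2 / m1
    if n > 1 and m2 > 0:
        se = frac * np.sqrt((a1.std(ddof=1) / m1) ** 2 + (a2.std(ddof=1) / m2) ** 2) / np.sqrt(n)
    else:
        se = 0.0
    return frac, float(se)


@dataclass
class CrossTalkReport:
    """Per-lesion residual/contamination rows plus organ carry-over section."""

    lesion_rows: pd.DataFrame
    organ_rows: pd.DataFrame
    scenarios: tuple[ResidualScenario, ...]
    delta_t_min: float
    half_life_min: float

    def cohort_means(self) -> dict[str, dict[str, float]]:
        """Mean +/- SE of residual ACT and contamination % per scenario.

        Means are taken over per-lesion rows, so contamination is a mean of
        per-lesion ratios — not the ratio of cohort mean ACTs.
        """
        out: dict[str, dict[str, float]] = {}
        n = len(self.lesion_rows)
        for sc in self.scenarios:
            res = self.lesion_rows[f"residual_act_{sc.label}"]
            con = self.lesion_rows[f"contamination_pct_{sc.label}"].dropna()
            out[sc.label] = {
                "residual_act_mean": float(res.mean()) if n else float("nan"),
                "residual_act_se": float(res.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "contamination_pct_mean": float(con.mean()) if len(con) else float("nan"),
                "contamination_pct_se": (
                    float(con.std(ddof=1) / np.sqrt(len(con))) if len(con) > 1 else 0.0
                ),
            }
        return out

    def summary(self) -> str:
        lines = [
            f"Cross-talk assessment: {len(self.lesion_rows)} lesions, "
            f"dt = {self.delta_t_min:.1f} min "
            f"({self.delta_t_min / self.half_life_min:.2f} half-lives)"
        ]
        for label, m in self.cohort_means().items():
            lines.append(
                f"  {label:>6}: residual {m['residual_act_mean']:.1f} "
                f"+/- {m['residual_act_se']:.1f} Bq/mL, "
                f"contamination {m['contamination_pct_mean']:.2f} "
                f"+/- {m['contamination_pct_se']:.2f} %"
            )
        for _, row in self.organ_rows.iterrows():
            lines.append(
                f"  organ {row['organ']:>11}: SUVmean scan1 {row['suv_mean_scan1']:.2f} "
                f"-> scan2 {row['suv_mean_scan2']:.2f}"
            )
        return "\n".join(lines)


def crosstalk_assessment(
    lesion_table: pd.DataFrame,
    organ_table: pd.DataFrame | None,
    delta_t_min: float,
    half_life_min: float,
    scenarios: tuple[ResidualScenario, ...] = DEFAULT_SCENARIOS,
) -> CrossTalkReport:
    """Apply residual scenarios to quantified lesions of one (or a pooled) study.

    Parameters
    ----------
    lesion_table : DataFrame
        One row per lesion with at least ``act_fdg`` and ``act_sstr``
        (mean ACT in Bq/mL on each co-registered scan).
    organ_table : DataFrame or None
        One row per organ with ``organ``, ``suv_mean_scan1``, ``suv_mean_scan2``.
    delta_t_min, half_life_min : float
        End-of-scan-1 to start-of-scan-2 interval and first-tracer half-life,
        used by the decay scenario.
    """
    rows = lesion_table.copy()
    for sc in scenarios:
        frac = sc.resolve(delta_t_min, half_life_min)
        rows[f"residual_act_{sc.label}"] = rows["act_fdg"] * frac
        rows[f"contamination_pct_{sc.label}"] = np.where(
            rows["act_sstr"] > 0,
            100.0 * rows["act_fdg"] * frac / rows["act_sstr"],
            np.nan,
        )
    organ_rows = organ_table.copy() if organ_table is not None else pd.DataFrame(
        columns=["organ", "suv_mean_scan1", "suv_mean_scan2"]
    )
    return CrossTalkReport(rows, organ_rows, tuple(scenarios), delta_t_min, half_life_min)


def crosstalk_from_study(
    study: DualStudy,
    lesion_vois: dict[str, VOI],
    organ_vois: dict[str, VOI],
    scenarios: tuple[ResidualScenario, ...] = DEFAULT_SCENARIOS,
) -> CrossTalkReport:
    """Quantify lesion/organ VOIs on both co-registered scans and apply scenarios.

    Co-registration between the two scans is identity on the shared phantom
    grid. Organs whose VOI is missing or empty are omitted with a warning.
    """
    import warnings

    from .quant import suv_to_act_factor

    lesion_rows = []
    for lesion_id, voi in lesion_vois.items():
        if voi.empty:
            warnings.warn(f"lesion {lesion_id} VOI is empty; skipped", stacklevel=2)
            continue
        lesion_rows.append({
            "lesion_id": lesion_id,
            "act_fdg": float(study.scan1.values[voi.mask].mean()),
            "act_sstr": float(study.scan2.values[voi.mask].mean()),
        })
    f1 = suv_to_act_factor(study.meta1)
    f2 = suv_to_act_factor(study.meta2)
    organ_rows = []
    for name in ("brain", "myocardium", "blood_pool"):
        voi = organ_vois.get(name)
        if voi is None or voi.empty:
            warnings.warn(f"organ VOI {name!r} missing or empty; row omitted", stacklevel=2)
            continue
        organ_rows.append({
            "organ": name,
            "patient_id": study.patient_id,
            "suv_mean_scan1": float(study.scan1.values[voi.mask].mean()) / f1,
            "suv_mean_scan2": float(study.scan2.values[voi.mask].mean()) / f2,
        })
    delta_t = study.meta2.t_acq_start_min - study.meta1.t_acq_end_min
    return crosstalk_assessment(
        pd.DataFrame(lesion_rows, columns=["lesion_id", "act_fdg", "act_sstr"]),
        pd.DataFrame(organ_rows, columns=["organ", "patient_id",
                                          "suv_mean_scan1", "suv_mean_scan2"]),
        delta_t,
        study.meta1.half_life_min,
        scenarios,
    )


def organ_carryover_tests(organ_pairs: pd.DataFrame) -> pd.DataFrame:
    """Paired scan-1 vs scan-2 organ comparisons across a cohort.

    ``organ_pairs`` has columns ``organ``, ``patient_id``, ``suv_mean_scan1``,
    ``suv_mean_scan2``. Returns per-organ Wilcoxon signed-rank p values; the
    myocardium scan-2 values are additionally compared against the blood pool.
    """
    out = []
    for organ, grp in organ_pairs.groupby("organ", sort=True):
        stat, p = paired_rank_test(grp["suv_mean_scan1"].to_numpy(),
                                   grp["suv_mean_scan2"].to_numpy())
        out.append({
            "organ": organ,
            "n": len(grp),
            "suv_mean_scan1": float(grp["suv_mean_scan1"].mean()),
            "suv_mean_scan2": float(grp["suv_mean_scan2"].mean()),
            "wilcoxon_p": p,
        })
    df = pd.DataFrame(out)
    myo = organ_pairs[organ_pairs["organ"] == "myocardium"]
    blood = organ_pairs[organ_pairs["organ"] == "blood_pool"]
    if len(myo) and len(myo) == len(blood):
        merged = myo.merge(blood, on="patient_id", suffixes=("_myo", "_blood"))
        _, p = paired_rank_test(merged["suv_mean_scan2_myo"].to_numpy(),
                                merged["suv_mean_scan2_blood"].to_numpy())
        df.attrs["myocardium_vs_bloodpool_scan2_p"] = p
    return df
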