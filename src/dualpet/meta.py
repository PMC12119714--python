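"""Per-acquisition metadata and the one-day dual-tracer protocol timing.

Clock times are minutes on a shared study clock (t = 0 at the first-tracer
injection), which keeps the arithmetic explicit and the JSON sidecars plain.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

F18_HALF_LIFE_MIN = 109.8
"""Physical half-life of fluorine-18, minutes."""


@dataclass(frozen=True)
class ScanMeta:
    """Metadata of one PET acquisition.

    Parameters
    ----------
    tracer : str
        Tracer label, e.g. ``"FDG"`` or ``"SSTR"``.
    half_life_min : float
        Radionuclide half-life in minutes.
    injected_activity_MBq : float
        Activity at injection time, MBq.
    body_weight_kg : float
        Patient weight, kg (tissue density taken as 1 g/mL for SUV).
    t_injection_min, t_acq_start_min, t_acq_end_min : float
        Clock times (minutes) of injection and of acquisition start/end.
    """

    tracer: str
    half_life_min: float
    injected_activity_MBq: float
    body_weight_kg: float
    t_injection_min: float
    t_acq_start_min: float
    t_acq_end_min: float

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be > 0")
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected_activity_MBq must be > 0")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be > 0")
        if not (self.t_injection_min <= self.t_acq_start_min <= self.t_acq_end_min):
            raise ValueError("require t_injection <= t_acq_start <= t_acq_end")

    @property
    def uptake_time_min(self) -> float:
        return self.t_acq_start_min - self.t_injection_min

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanMeta":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ProtocolTiming:
    """One-day dual-tracer protocol: low-activity first tracer, standard second.

    Defaults are the study protocol: 0.5 MBq/kg first tracer scanned for
    10 min at 60 min p.i.; after a 4.2 h interval from completion of the
    first scan, 3.0 MBq/kg second tracer scanned for 5 min at 90 min p.i.
    """

    dose1_MBq_per_kg: float = 0.5
    uptake1_min: float = 60.0
    scan1_duration_min: float = 10.0
    interval_after_scan1_min: float = 4.2 * 60.0
    dose2_MBq_per_kg: float = 3.0
    uptake2_min: float = 90.0
    scan2_duration_min: float = 5.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if min(
            self.dose1_MBq_per_kg,
            self.uptake1_min,
            self.scan1_duration_min,
            self.dose2_MBq_per_kg,
            self.uptake2_min,
            self.scan2_duration_min,
            self.half_life_min,
        ) <= 0:
            raise ValueError("all protocol durations and doses must be > 0")
        if self.interval_after_scan1_min <= 0:
            raise ValueError("inter-scan interval must be > 0")

    def scan_metas(self, body_weight_kg: float) -> tuple[ScanMeta, ScanMeta]:
        """Build the two :class:`ScanMeta` records for a given patient weight."""
        t_inj1 = 0.0
        t_start1 = t_inj1 + self.uptake1_min
        t_end1 = t_start1 + self.scan1_duration_min
        t_inj2 = t_end1 + self.interval_after_scan1_min
        t_start2 = t_inj2 + self.uptake2_min
        t_end2 = t_start2 + self.scan2_duration_min
        meta1 = ScanMeta(
            tracer="FDG",
            half_life_min=self.half_life_min,
            injected_activity_MBq=self.dose1_MBq_per_kg * body_weight_kg,
            body_weight_kg=body_weight_kg,
            t_injection_min=t_inj1,
            t_acq_start_min=t_start1,
            t_acq_end_min=t_end1,
        )
        meta2 = ScanMeta(
            tracer="SSTR",
            half_life_min=self.half_life_min,
            injected_activity_MBq=self.dose2_MBq_per_kg * body_weight_kg,
            body_weight_kg=body_weight_kg,
            t_injection_min=t_inj2,
            t_acq_start_min=t_start2,
            t_acq_end_min=t_end2,
        )
        return meta1, meta2
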