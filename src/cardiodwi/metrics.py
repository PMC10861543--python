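"""Non-diffusion cardiac quantification: LV volumes, ejection fraction and
extracellular volume (ECV) fraction.

Volumes use Simpson's disk summation over short-axis slice areas; LVEF is
100*(EDV-ESV)/EDV.  ECV combines the hematocrit with pre/post-contrast
longitudinal relaxation rates of myocardium and blood:

    ECV = (1 - Hct) * (1/T1_myo_post - 1/T1_myo_pre)
                    / (1/T1_blood_post - 1/T1_blood_pre) * 100%

the standard delta-R1 ratio form.  Contour segmentation and T1-map fitting
are out of scope: slice areas and T1 values are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "VentricularVolumes",
    "T1Panel",
    "simpson_volume",
    "ejection_fraction",
    "ecv_fraction",
]


@dataclass(frozen=True)
class VentricularVolumes:
    """End-diastolic and end-systolic LV volumes in µL."""

    edv: float
    esv: float

    def __post_init__(self) -> None:
        if self.edv <= 0:
            raise ValueError("edv must be positive")
        if not 0 <= self.esv <= self.edv:
            raise ValueError("esv must satisfy 0 <= esv <= edv")


@dataclass(frozen=True)
class T1Panel:
    """Pre/post-contrast T1 (ms) of myocardium and blood, plus hematocrit."""

    t1_myo_pre: float
    t1_myo_post: float
    t1_blood_pre: float
    t1_blood_post: float
    hct: float

    def __post_init__(self) -> None:
        for name in ("t1_myo_pre", "t1_myo_post",
                     "t1_blood_pre", "t1_blood_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t1_myo_post > self.t1_myo_pre or \
                self.t1_blood_post > self.t1_blood_pre:
            raise ValueError("post-contrast T1 must not exceed native T1")
        if not 0 < self.hct < 1:
            raise ValueError("hct must be a fraction in (0, 1)")


def simpson_volume(slice_areas: Sequence[float], thickness: float) -> float:
    """Disk-summation volume: sum(area_i) * thickness, in µL (1 mm³ = 1 µL).

    ``slice_areas`` in mm², ``thickness`` in mm.
    """
    areas = list(slice_areas)
    if not areas:
        raise ValueError("at least one slice area is required")
    if any(a < 0 for a in areas):
        raise ValueError("slice areas must be non-negative")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    return float(sum(areas) * thickness)


def ejection_fraction(v: VentricularVolumes) -> float:
    """LV ejection fraction in percent: 100*(EDV - ESV)/EDV."""
    return 100.0 * (v.edv - v.esv) / v.edv


def ecv_fraction(p: T1Panel) -> float:
    """Myocardial extracellular volume fraction in percent.

    (1 - Hct) times the ratio of myocardial to blood delta-R1
    (R1 = 1/T1, post minus pre).
    """
    dr1_myo = 1.0 / p.t1_myo_post - 1.0 / p.t1_myo_pre
    dr1_blood = 1.0 / p.t1_blood_post - 1.0 / p.t1_blood_pre
    if dr1_blood <= 0:
        raise ValueError("blood delta-R1 must be positive")
    return 100.0 * (1.0 - p.hct) * dr1_myo / dr1_blood
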