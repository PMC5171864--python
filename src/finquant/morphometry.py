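"""Histomorphometric quantities of the regenerating fin and their
size-corrected ratios.

Measured quantities (areas in mm^2, lengths in mm):

========  ==========================================================
REG       total regenerated area, amputation plane to distal edge
EMA       estimated mineralized area (tip polygon; includes inter-ray)
RMA       real mineralized area (colour-thresholded; rays only)
RAY       mean mineralized-ray width at the first proximal joint
STU       stump width (length of the amputation plane)
WEI       total fish weight (mg), optional
LEN       snout-to-amputation-plane length (mm), optional
========  ==========================================================

Because fish stocks vary in size, raw areas are corrected: REG/STU for
regeneration, RMA/RAY for mineralization, and the dimensionless
mineralized fraction (RMA/RAY)/(REG/STU) for mineralogenic performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .exceptions import InvalidSpecimenError, MissingCorrectionError
from .records import FinRecord, MineralMask, RegionMask
from .segmentation import shoelace_area


@dataclass(frozen=True)
class Morphometrics:
    """The measured quantities for one specimen at one time point."""

    reg_mm2: float
    ema_mm2: float
    rma_mm2: float
    ray_mm: Optional[float]
    stu_mm: float
    wei_mg: Optional[float] = None
    len_mm: Optional[float] = None


@dataclass(frozen=True)
class CorrectedMetrics:
    """Size-corrected ratios derived from :class:`Morphometrics`."""

    reg_over_stu: float  # mm
    rma_over_ray: float  # mm
    mineral_fraction: float  # dimensionless, (RMA/RAY)/(REG/STU)
    reg_over_wei: Optional[float] = None  # mm^2/mg
    reg_over_len: Optional[float] = None  # mm


def measure(
    record: FinRecord,
    regenerate: RegionMask,
    mineral_distal: MineralMask,
    ema_polygon: Optional[Sequence[tuple[float, float]]] = None,
    ray_widths_px: Optional[Sequence[float]] = None,
) -> Morphometrics:
    """Convert masks and annotations into calibrated morphometrics.

    ``mineral_distal`` should already be restricted to the regenerate so
    its pixel count is RMA; ``ema_polygon`` is the distal-tip polygon
    (EMA = 0 when absent); ``ray_widths_px`` are the per-ray first-joint
    widths (RAY absent when None).
    """
    s = record.mm_per_px
    if s <= 0:
        raise InvalidSpecimenError("missing or invalid calibration")
    reg = regenerate.n_pixels * s**2
    rma = mineral_distal.n_pixels * s**2
    ema = shoelace_area(ema_polygon) * s**2 if ema_polygon is not None else 0.0
    stu = record.plane.width_px * s
    ray = None
    if ray_widths_px is not None and len(ray_widths_px) > 0:
        ray = float(sum(ray_widths_px) / len(ray_widths_px)) * s
    return Morphometrics(
        reg_mm2=float(reg),
        ema_mm2=float(ema),
        rma_mm2=float(rma),
        ray_mm=ray,
        stu_mm=float(stu),
        wei_mg=record.wei_mg,
        len_mm=record.len_mm,
    )


def correct(m: Morphometrics) -> CorrectedMetrics:
    """Size-corrected ratios.

    RMA = 0 maps to RMA/RAY = 0 and mineral fraction 0 regardless of RAY
    (the pre-mineralization regime P1); a zero stump width is a specimen
    error, and a missing RAY with nonzero RMA cannot be corrected.
    """
    if m.stu_mm <= 0:
        raise InvalidSpecimenError("stump width STU must be positive")
    reg_over_stu = m.reg_mm2 / m.stu_mm
    if m.rma_mm2 == 0:
        rma_over_ray = 0.0
    else:
        if m.ray_mm is None or m.ray_mm <= 0:
            raise MissingCorrectionError("RAY is absent but RMA > 0")
        rma_over_ray = m.rma_mm2 / m.ray_mm
    fraction = rma_over_ray / reg_over_stu if reg_over_stu > 0 else 0.0
    return CorrectedMetrics(
        reg_over_stu=float(reg_over_stu),
        rma_over_ray=float(rma_over_ray),
        mineral_fraction=float(fraction),
        reg_over_wei=(m.reg_mm2 / m.wei_mg) if m.wei_mg else None,
        reg_over_len=(m.reg_mm2 / m.len_mm) if m.len_mm else None,
    )


#: Column order of the per-record results table written by the pipeline.
TABLE_COLUMNS = [
    "specimen_id",
    "group",
    "time_hpa",
    "reg_mm2",
    "ema_mm2",
    "rma_mm2",
    "ray_mm",
    "stu_mm",
    "wei_mg",
    "len_mm",
    "reg_over_stu_mm",
    "rma_over_ray_mm",
    "mineral_fraction",
    "reg_over_wei_mm2_per_mg",
    "reg_over_len_mm",
    "low_15_29",
    "high_30_44",
    "red_min_used",
]


def as_row(
    record: FinRecord,
    m: Morphometrics,
    c: CorrectedMetrics,
    low: Optional[float] = None,
    high: Optional[float] = None,
    red_min: Optional[int] = None,
) -> dict:
    """One results-table row (units embedded in the column names)."""
    return {
        "specimen_id": record.specimen_id,
        "group": record.group_label,
        "time_hpa": record.time_hpa,
        "reg_mm2": m.reg_mm2,
        "ema_mm2": m.ema_mm2,
        "rma_mm2": m.rma_mm2,
        "ray_mm": m.ray_mm,
        "stu_mm": m.stu_mm,
        "wei_mg": m.wei_mg,
        "len_mm": m.len_mm,
        "reg_over_stu_mm": c.reg_over_stu,
        "rma_over_ray_mm": c.rma_over_ray,
        "mineral_fraction": c.mineral_fraction,
        "reg_over_wei_mm2_per_mg": c.reg_over_wei,
        "reg_over_len_mm": c.reg_over_len,
        "low_15_29": low,
        "high_30_44": high,
        "red_min_used": red_min,
    }
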