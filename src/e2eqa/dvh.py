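"""Cumulative dose-volume histograms and planning-constraint evaluation.

The constraint template mirrors a standard prostate adaptive protocol
(prescription 2.5 Gy/fraction to 70 Gy): PTV D98% >= 100% of Rx and
Dmax <= 110% of Rx; bladder V35Gy < 50% and V57Gy < 25%; rectum V35Gy < 35%
and V57Gy < 17%; bowel V45Gy < 150 cm^3; each femur V45Gy < 10%.

DVHs are cumulative with configurable bin width (default 0.05 Gy) and linear
interpolation between bin edges.  Dmax is the point maximum voxel dose
(a D0.03cc variant is available via ``dmax_volume_cc``).  Percent-of-Rx
limits are evaluated against the total-course prescription by default; a
per-fraction Rx can be supplied instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import UndefinedInputError, ValidationError
from .volumes import BinaryMask, ImageVolume, StructureSet, mask_volume_cc

DEFAULT_BIN_WIDTH_GY = 0.05


@dataclass
class DVHCurve:
    """Cumulative DVH: volume fraction receiving at least each edge dose."""

    edges_gy: np.ndarray  # ascending, starts at 0
    fraction: np.ndarray  # in [0, 1], non-increasing, fraction[0] == 1
    total_cc: float

    def fraction_at(self, dose_gy: float) -> float:
        """Linearly interpolated fraction of volume receiving >= dose_gy."""
        if dose_gy < 0:
            raise ValidationError("dose must be >= 0")
        if dose_gy >= self.edges_gy[-1]:
            return float(self.fraction[-1])
        return float(np.interp(dose_gy, self.edges_gy, self.fraction))


def cumulative_dvh(
    dose: ImageVolume, mask: BinaryMask, bin_width_gy: float = DEFAULT_BIN_WIDTH_GY
) -> DVHCurve:
    """Cumulative DVH of a dose grid over a structure."""
    if dose.geometry != mask.geometry:
        raise ValidationError("dose and mask geometries differ")
    if mask.is_empty():
        raise UndefinedInputError("DVH is undefined for an empty mask")
    if bin_width_gy <= 0:
        raise ValidationError("bin width must be > 0")
    doses = np.sort(dose.values[mask.inside].astype(float))
    n = doses.size
    top = float(doses[-1])
    n_edges = int(np.ceil(max(top, 0.0) / bin_width_gy)) + 2
    edges = np.arange(n_edges) * bin_width_gy
    # fraction of voxels with dose >= edge
    fraction = 1.0 - np.searchsorted(doses, edges, side="left") / n
    return DVHCurve(edges, fraction, mask_volume_cc(mask))


def dose_at_volume(dvh: DVHCurve, volume_pct: float) -> float:
    """D_v: the dose (Gy) received by at least ``volume_pct`` % of the volume.

    Found where the cumulative curve crosses v/100, linearly interpolated
    between bin edges; D100% returns the minimum dose in the structure (to
    bin resolution).  Non-increasing in v.
    """
    if not (0.0 < volume_pct <= 100.0):
        raise ValidationError("volume percentage must be in (0, 100]")
    target = volume_pct / 100.0
    frac = dvh.fraction
    edges = dvh.edges_gy
    below = np.nonzero(frac < target)[0]
    if below.size == 0:  # whole curve >= target
        return float(edges[-1])
    i = int(below[0])  # first edge where fraction drops below target
    if i == 0:
        return float(edges[0])
    f_hi, f_lo = frac[i - 1], frac[i]
    if f_hi == f_lo:
        return float(edges[i - 1])
    t = (f_hi - target) / (f_hi - f_lo)
    return float(edges[i - 1] + t * (edges[i] - edges[i - 1]))


def volume_at_dose(dvh: DVHCurve, dose_gy: float, unit: str = "%") -> float:
    """V_d: volume receiving at least ``dose_gy``, as % or cm^3."""
    if dose_gy < 0:
        raise ValidationError("dose must be >= 0")
    frac = dvh.fraction_at(dose_gy)
    if unit == "%":
        return 100.0 * frac
    if unit in ("cc", "cm3"):
        return frac * dvh.total_cc
    raise ValidationError(f"unknown unit {unit!r}")


def d_max(dose: ImageVolume, mask: BinaryMask) -> float:
    """Point-maximum voxel dose (Gy) within a structure."""
    if dose.geometry != mask.geometry:
        raise ValidationError("dose and mask geometries differ")
    if mask.is_empty():
        raise UndefinedInputError("Dmax is undefined for an empty mask")
    return float(dose.values[mask.inside].max())


def dmax_volume_cc(dose: ImageVolume, mask: BinaryMask, volume_cc: float = 0.03) -> float:
    """Near-maximum dose: minimum dose of the hottest ``volume_cc`` cm^3."""
    if mask.is_empty():
        raise UndefinedInputError("Dmax is undefined for an empty mask")
    doses = np.sort(dose.values[mask.inside].astype(float))[::-1]
    voxel_cc = dose.geometry.voxel_volume_mm3 / 1000.0
    k = max(int(np.ceil(volume_cc / voxel_cc)), 1)
    return float(doses[min(k, doses.size) - 1])


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintSpec:
    """One planning rule, e.g. ``Bladder V35 Gy < 50%``."""

    roi: str
    kind: str  # D_at_volume | V_at_dose | D_max
    query: float  # volume % for D_at_volume; dose Gy for V_at_dose; unused for D_max
    limit: float
    unit: str  # %Rx | Gy | %vol | cc
    comparator: str  # <= | >=
    rx_gy: float = 70.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("D_at_volume", "V_at_dose", "D_max"):
            raise ValidationError(f"unknown constraint kind {self.kind!r}")
        if self.comparator not in ("<=", ">="):
            raise ValidationError("comparator must be '<=' or '>='")
        if self.limit <= 0 or (self.kind != "D_max" and self.query <= 0):
            raise ValidationError("query and limit must be positive")
        if self.kind == "V_at_dose" and self.unit not in ("%vol", "cc"):
            raise ValidationError("V_at_dose limits must be %vol or cc")
        if self.kind in ("D_at_volume", "D_max") and self.unit not in ("%Rx", "Gy"):
            raise ValidationError("dose limits must be %Rx or Gy")
        if not self.label:
            object.__setattr__(self, "label", _default_label(self))


def _default_label(spec: ConstraintSpec) -> str:
    if spec.kind == "D_max":
        return "Dmax"
    if spec.kind == "D_at_volume":
        return f"D{spec.query:g}%"
    return f"V{spec.query:g}Gy"


_CONSTRAINT_RE = re.compile(
    r"^\s*(?:(?P<dmax>Dmax)|D(?P<dvol>[\d.]+)\s*%|V(?P<vdose>[\d.]+)\s*Gy)\s*"
    r"(?P<cmp>[<>]\s*=?)\s*(?P<limit>[\d.]+)\s*(?P<unit>%(?:\s*of\s*Rx)?|Gy|cm3|cm\^?3|cc)\s*$",
    re.IGNORECASE,
)


def parse_constraint(roi: str, expression: str, rx_gy: float = 70.0) -> ConstraintSpec:
    """Parse constraint shorthand such as ``"D98% >= 100% of Rx"``,
    ``"Dmax <= 110% of Rx"``, ``"V45 Gy < 150cm3"``, ``"V35 Gy < 50%"``."""
    m = _CONSTRAINT_RE.match(expression)
    if m is None:
        raise ValidationError(f"cannot parse constraint {expression!r}")
    comparator = "<=" if m.group("cmp").startswith("<") else ">="
    limit = float(m.group("limit"))
    unit_raw = m.group("unit").lower().replace(" ", "")
    if m.group("dmax") is not None:
        kind, query = "D_max", 0.0
        unit = "%Rx" if unit_raw.startswith("%") else "Gy"
    elif m.group("dvol") is not None:
        kind, query = "D_at_volume", float(m.group("dvol"))
        unit = "%Rx" if unit_raw.startswith("%") else "Gy"
    else:
        kind, query = "V_at_dose", float(m.group("vdose"))
        unit = "%vol" if unit_raw == "%" else "cc"
    return ConstraintSpec(roi, kind, query if kind != "D_max" else 1.0, limit, unit, comparator, rx_gy)


#: The prostate protocol template: (ROI, rule) pairs.
TABLE_CONSTRAINTS = (
    ("PTV_7000", "D98% >= 100% of Rx"),
    ("PTV_7000", "Dmax <= 110% of Rx"),
    ("Bladder", "V35 Gy < 50%"),
    ("Bladder", "V57 Gy < 25%"),
    ("Rectum", "V35 Gy < 35%"),
    ("Rectum", "V57 Gy < 17%"),
    ("Bowel", "V45 Gy < 150cm3"),
    ("Femur_L", "V45 Gy < 10%"),
    ("Femur_R", "V45 Gy < 10%"),
)


def default_constraints(rx_gy: float = 70.0) -> list[ConstraintSpec]:
    """The nine-rule prostate planning template at the given prescription."""
    return [parse_constraint(roi, expr, rx_gy) for roi, expr in TABLE_CONSTRAINTS]


def load_constraints(path: str | Path) -> list[ConstraintSpec]:
    """Read a YAML constraint template: list of {roi, rule, rx_gy} entries."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [parse_constraint(e["roi"], e["rule"], float(e.get("rx_gy", 70.0))) for e in entries]


@dataclass
class ConstraintResult:
    spec: ConstraintSpec
    achieved: float | None  # in the limit's unit; None when the ROI is missing
    passed: bool | None
    error: str | None = None


def _achieved_value(
    dose: ImageVolume, mask: BinaryMask, spec: ConstraintSpec, bin_width_gy: float
) -> float:
    if spec.kind == "D_max":
        val_gy = d_max(dose, mask)
    elif spec.kind == "D_at_volume":
        val_gy = dose_at_volume(cumulative_dvh(dose, mask, bin_width_gy), spec.query)
    else:
        return volume_at_dose(
            cumulative_dvh(dose, mask, bin_width_gy), spec.query, "%" if spec.unit == "%vol" else "cc"
        )
    return 100.0 * val_gy / spec.rx_gy if spec.unit == "%Rx" else val_gy


def evaluate_constraints(
    dose: ImageVolume,
    structures: StructureSet,
    specs: list[ConstraintSpec] | None = None,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
) -> list[ConstraintResult]:
    """Evaluate a constraint template against one dose grid.

    A missing or empty ROI yields an error entry for that rule; evaluation
    continues for the remaining rules.
    """
    if specs is None:
        specs = default_constraints()
    results = []
    for spec in specs:
        if spec.roi not in structures or structures[spec.roi].is_empty():
            results.append(ConstraintResult(spec, None, None, f"ROI {spec.roi!r} missing or empty"))
            continue
        achieved = _achieved_value(dose, structures[spec.roi], spec, bin_width_gy)
        passed = achieved <= spec.limit if spec.comparator == "<=" else achieved >= spec.limit
        results.append(ConstraintResult(spec, achieved, bool(passed)))
    return results
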