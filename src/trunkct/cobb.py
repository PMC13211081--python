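"""Supine thoracic Cobb angle from endplate line annotations.

All geometry lives in the mid-sagittal plane with coordinates
``(cc, ap)`` = (craniocaudal mm, antero-posterior mm).  Inclinations are
measured against the antero-posterior axis and folded into (-90, 90];
angles between the two (undirected) endplate lines therefore live in
[0, 90].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

Point = tuple[float, float]


@dataclass(frozen=True)
class EndplatePair:
    """Two endplate lines, each given by two distinct 2D points (mm).

    ``superior_line`` is the T1 superior endplate; ``inferior_line`` the
    T12 (or L1 — recorded in ``inferior_level``, mathematically identical)
    inferior endplate.
    """

    superior_line: tuple[Point, Point]
    inferior_line: tuple[Point, Point]
    inferior_level: str = "T12"
    plane_convention: str = "cc-ap"

    def __post_init__(self) -> None:
        for name, line in (("superior", self.superior_line),
                           ("inferior", self.inferior_line)):
            (a, b) = line
            if math.isclose(a[0], b[0], abs_tol=1e-12) and \
               math.isclose(a[1], b[1], abs_tol=1e-12):
                raise ValueError(f"{name} endplate line has coincident points")


@dataclass(frozen=True)
class CobbResult:
    angle_deg: float
    superior_inclination_deg: float
    inferior_inclination_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 90.0 + 1e-9:
            raise ValueError("Cobb angle must lie in [0, 90]")


def _inclination_deg(line: tuple[Point, Point]) -> float:
    """Line inclination vs the antero-posterior axis, folded to (-90, 90]."""
    (c0, a0), (c1, a1) = line
    theta = math.degrees(math.atan2(c1 - c0, a1 - a0))
    # undirected line: fold to (-90, 90]
    if theta > 90.0:
        theta -= 180.0
    elif theta <= -90.0:
        theta += 180.0
    return theta


def cobb_angle(pair: EndplatePair) -> CobbResult:
    """Acute intersection angle between the two endplate lines, degrees."""
    sup = _inclination_deg(pair.superior_line)
    inf = _inclination_deg(pair.inferior_line)
    angle = abs(sup - inf)
    if angle > 90.0:
        angle = 180.0 - angle
    return CobbResult(angle_deg=angle,
                      superior_inclination_deg=sup,
                      inferior_inclination_deg=inf)


def cobb_from_arc(arc_length_mm: float, radius_mm: float) -> float:
    """Tangent rotation (degrees) of a circular arc between its endpoints.

    Closed form for phantom ground truth: the spine centerline is a circular
    arc, so the Cobb angle equals arc_length / radius (radians).  An infinite
    radius encodes a straight spine.
    """
    if arc_length_mm < 0 or radius_mm <= 0:
        raise ValueError("arc length must be >= 0 and radius > 0")
    if math.isinf(radius_mm):
        return 0.0
    return math.degrees(arc_length_mm / radius_mm)


# ---------------------------------------------------------------------------
# Annotation sidecar I/O: {case_id, superior: [[cc,ap],[cc,ap]], inferior: ..., units: "mm"}

def write_annotations(pairs: dict[str, EndplatePair], path: str | Path) -> None:
    payload = [
        {
            "case_id": cid,
            "superior": [list(p) for p in pair.superior_line],
            "inferior": [list(p) for p in pair.inferior_line],
            "inferior_level": pair.inferior_level,
            "units": "mm",
        }
        for cid, pair in pairs.items()
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_annotations(path: str | Path) -> dict[str, EndplatePair]:
    records = json.loads(Path(path).read_text())
    out: dict[str, EndplatePair] = {}
    for rec in records:
        sup = tuple(tuple(float(v) for v in p) for p in rec["superior"])
        inf = tuple(tuple(float(v) for v in p) for p in rec["inferior"])
        out[str(rec["case_id"])] = EndplatePair(
            superior_line=sup, inferior_line=inf,
            inferior_level=rec.get("inferior_level", "T12"),
        )
    return out
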