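"""PVV result container and the cross-sectional-area partition.

Both estimators partition vessel-like volume by cross-sectional area into
PVV5 (< 5 mm^2), PVV10 (5–10 mm^2, inclusive at both edges) and PVV10+
(> 10 mm^2).  The partition is exact by construction: every measured piece
of volume lands in exactly one bin, so pvv5 + pvv10 + pvv10plus == pvv_total
identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["PVVResult", "area_bin", "DEFAULT_AREA_THRESHOLDS"]

#: bin edges in mm^2: [0, 5) -> pvv5, [5, 10] -> pvv10, (10, inf) -> pvv10plus
DEFAULT_AREA_THRESHOLDS: tuple[float, float] = (5.0, 10.0)


def area_bin(area_mm2: float, thresholds: tuple[float, float] = DEFAULT_AREA_THRESHOLDS) -> str:
    """Sub-volume bin for a cross-sectional area: 'pvv5', 'pvv10' or 'pvv10plus'."""
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError(f"thresholds must be strictly increasing, got {thresholds}")
    if area_mm2 < lo:
        return "pvv5"
    if area_mm2 <= hi:
        return "pvv10"
    return "pvv10plus"


@dataclass
class PVVResult:
    """Total PVV and its sub-volume partition for one scan and one method.

    All volumes are in mL.  ``pvv_total`` is stored as the exact sum of the
    three bins.
    """

    method: str                       # "unfiltered" | "graph"
    pvv5: float = 0.0
    pvv10: float = 0.0
    pvv10plus: float = 0.0
    lung_volume: float | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("pvv5", "pvv10", "pvv10plus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def pvv_total(self) -> float:
        return self.pvv5 + self.pvv10 + self.pvv10plus

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "pvv_total_ml": self.pvv_total,
            "pvv5_ml": self.pvv5,
            "pvv10_ml": self.pvv10,
            "pvv10plus_ml": self.pvv10plus,
            "lung_volume_ml": self.lung_volume,
            "parameters": self.parameters,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def __str__(self) -> str:
        lv = f", lung {self.lung_volume:.1f} mL" if self.lung_volume else ""
        return (
            f"PVV[{self.method}] total {self.pvv_total:.2f} mL "
            f"(PVV5 {self.pvv5:.2f}, PVV10 {self.pvv10:.2f}, "
            f"PVV10+ {self.pvv10plus:.2f}{lv})"
        )
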