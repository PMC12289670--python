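"""The ``Detection`` record passed between prediction, evaluation and localization."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class Detection:
    """One predicted object.

    ``box`` is pixel-space ``(x1, y1, x2, y2)``, 0-based, half-open.
    ``position_3d`` (camera frame, centimeters) and ``distance_cm`` are filled
    in by RGB-D localization when an aligned depth map is available.
    """

    class_id: int
    confidence: float
    box: tuple
    position_3d: tuple | None = None
    distance_cm: float | None = None

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0,1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["box"] = list(self.box)
        if self.position_3d is not None:
            d["position_3d"] = list(self.position_3d)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Detection":
        return cls(class_id=int(d["class_id"]), confidence=float(d["confidence"]),
                   box=tuple(d["box"]),
                   position_3d=tuple(d["position_3d"]) if d.get("position_3d") else None,
                   distance_cm=d.get("distance_cm"))
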