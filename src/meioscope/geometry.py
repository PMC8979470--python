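"""Chromosome-arm geometry.

An arm is described by its physical length and the *detectable interval*:
the span (first to last diagnostic SNP, minus any edge filters) within which
a crossover could have been localized.  All landscape statistics are computed
relative to the detectable span, not the assembly length.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ArmGeometry:
    """Geometry of one chromosome arm.

    Parameters
    ----------
    name
        Arm label, e.g. ``"X"`` or ``"2L"``.
    length
        Physical arm length in bp.
    detectable_start, detectable_end
        Half-open interval ``[start, end)`` in bp within which crossovers are
        observable.
    centromere_side
        ``"left"`` or ``"right"``: which end of the coordinate system carries
        the centromere.
    """

    name: str
    length: int
    detectable_start: int
    detectable_end: int
    centromere_side: str = "right"

    def __post_init__(self) -> None:
        if not (0 <= self.detectable_start < self.detectable_end <= self.length):
            raise ValueError(
                f"invalid detectable interval [{self.detectable_start}, "
                f"{self.detectable_end}) for arm {self.name!r} of length {self.length}"
            )
        if self.centromere_side not in ("left", "right"):
            raise ValueError("centromere_side must be 'left' or 'right'")

    @property
    def detectable_span(self) -> int:
        """Length in bp of the interval where crossovers can be detected."""
        return self.detectable_end - self.detectable_start

    def end_position(self, side: str) -> int:
        """Coordinate of the requested chromosome end (within the detectable span)."""
        if side == "centromere":
            side = self.centromere_side
        elif side == "telomere":
            side = "left" if self.centromere_side == "right" else "right"
        if side == "left":
            return self.detectable_start
        if side == "right":
            return self.detectable_end
        raise ValueError(f"unknown side {side!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ArmGeometry":
        return cls(
            name=str(d["name"]),
            length=int(d["length"]),
            detectable_start=int(d.get("detectable_start", 0)),
            detectable_end=int(d.get("detectable_end", d["length"])),
            centromere_side=str(d.get("centromere_side", "right")),
        )
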