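"""Mass tolerance specification: absolute Daltons or relative ppm."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Tolerance:
    """A symmetric mass tolerance.

    ``unit`` is ``"da"`` (absolute Daltons) or ``"ppm"`` (parts per
    million of the reference mass at which the window is evaluated).
    """

    value: float
    unit: str = "da"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be > 0")
        if self.unit not in ("da", "ppm"):
            raise ValueError(f"unknown tolerance unit: {self.unit!r}")

    def half_width(self, reference_mass: float) -> float:
        """Half-width of the window in Daltons at `reference_mass`."""
        if self.unit == "da":
            return self.value
        return abs(reference_mass) * self.value * 1e-6

    def window(self, reference_mass: float) -> tuple[float, float]:
        """The inclusive window [ref - hw, ref + hw] in Daltons."""
        hw = self.half_width(reference_mass)
        return reference_mass - hw, reference_mass + hw

    @classmethod
    def parse(cls, text: str) -> "Tolerance":
        """Parse strings like ``"10ppm"``, ``"0.02da"``, ``"0.5"`` (Da)."""
        s = text.strip().lower()
        for unit in ("ppm", "da"):
            if s.endswith(unit):
                return cls(float(s[:-len(unit)]), unit)
        return cls(float(s), "da")
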