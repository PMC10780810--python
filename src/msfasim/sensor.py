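"""Default sensor profile constants (monochrome CMOS, global shutter)."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SensorProfile", "DEFAULT_SENSOR"]


@dataclass(frozen=True)
class SensorProfile:
    """Geometry and digitization of the target image sensor."""

    width_px: int = 1600
    height_px: int = 1200
    pixel_pitch_um: float = 4.5
    bit_depth: int = 10

    @property
    def image_width_mm(self) -> float:
        return self.width_px * self.pixel_pitch_um / 1000.0

    @property
    def image_height_mm(self) -> float:
        return self.height_px * self.pixel_pitch_um / 1000.0

    @property
    def max_dn(self) -> int:
        return 2**self.bit_depth - 1


DEFAULT_SENSOR = SensorProfile()
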