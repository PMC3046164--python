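"""Display geometry and degree/pixel/texel conversions.

The display model is an 8-bit grayscale monitor tiled with square texture
elements ("texels") of a few pixels each.  All stimulus dimensions are given
in degrees of visual angle and converted to integer texel counts for
rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: 8-bit luminance codes used throughout the package.
BLACK: int = 0
GRAY: int = 128
WHITE: int = 255


@dataclass(frozen=True)
class DisplayGeometry:
    """Screen, texel and viewing parameters.

    Parameters
    ----------
    screen_px
        Screen resolution in pixels, (width, height).
    refresh_hz
        Vertical refresh rate in frames per second.
    texel_px
        Side of one background texture square, in pixels.  Screen dimensions
        must be integer multiples of this.
    px_per_deg
        Pixels per degree of visual angle.  The default 30.77 corresponds to
        a 17-inch 4:3 monitor at 1024x768 viewed from 58 cm, under which a
        0.13 deg bar width is exactly one 4-px texel column.
    """

    screen_px: tuple[int, int] = (1024, 768)
    refresh_hz: float = 75.0
    texel_px: int = 4
    px_per_deg: float = 30.77

    def __post_init__(self) -> None:
        w, h = self.screen_px
        if w <= 0 or h <= 0:
            raise ValueError("screen dimensions must be positive")
        if self.texel_px <= 0:
            raise ValueError("texel_px must be positive")
        if w % self.texel_px or h % self.texel_px:
            raise ValueError(
                f"screen {self.screen_px} is not an integer multiple of "
                f"texel_px={self.texel_px}"
            )
        if self.px_per_deg <= 0:
            raise ValueError("px_per_deg must be positive")
        if self.refresh_hz <= 0:
            raise ValueError("refresh_hz must be positive")

    @property
    def screen_texels(self) -> tuple[int, int]:
        """Screen size in texels, (columns, rows)."""
        return (self.screen_px[0] // self.texel_px,
                self.screen_px[1] // self.texel_px)

    @property
    def texel_deg(self) -> float:
        """Angular side of one texel, in degrees."""
        return self.texel_px / self.px_per_deg

    @property
    def texel_area_deg2(self) -> float:
        return self.texel_deg ** 2

    def deg_to_px(self, deg: float) -> float:
        if deg < 0:
            raise ValueError(f"negative angular size: {deg}")
        return deg * self.px_per_deg

    def texels_to_deg(self, texels: float) -> float:
        return texels * self.texel_deg


def deg_to_texels(deg: float, geometry: DisplayGeometry) -> int:
    """Convert an angular size to the nearest whole number of texels.

    Rounds half away from zero, so e.g. 0.13 deg at the default geometry
    (4.0 px) is exactly one 4-px texel column.
    """
    if deg < 0:
        raise ValueError(f"negative angular size: {deg}")
    return int(math.floor(deg * geometry.px_per_deg / geometry.texel_px + 0.5))
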