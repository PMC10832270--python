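"""Flight-geometry helpers for UAV survey planning.

The survey platform's full-frame sensor (4.4 um pixel pitch behind a 35 mm
lens) maps a relative flying height of H metres to a ground sample distance
of H * 0.44 / 35 ~= H / 80 centimetres per pixel.
"""

from __future__ import annotations

__all__ = ["ground_sample_distance"]


def ground_sample_distance(altitude_m: float, cm_per_px_per_80m: float = 80.0) -> float:
    """Ground sample distance in cm/pixel at the given relative altitude.

    With the default sensor constant, 100 m of altitude gives 1.25 cm/px.
    """
    if altitude_m <= 0:
        raise ValueError("altitude must be positive")
    return altitude_m / cm_per_px_per_80m
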