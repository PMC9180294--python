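"""Published per-stage quantile summaries used as synthetic-data defaults.

The ten MOS e-nose sensors (S1–S10, conductance ratio G/G0) and the five
CIELAB colour features are summarised for each maturity stage as
median and 5th/95th percentiles.  These tabulated values are the default
targets the synthetic-data generator reproduces, so that downstream
statistics see stage separations of realistic magnitude (e.g. S7 and S9
have disjoint 5th–95th ranges between stages, while S4 and S10 barely move).
"""

from __future__ import annotations

from .design import QuantileSpec

SENSOR_NAMES: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 11))

COLOUR_FEATURE_NAMES: tuple[str, ...] = ("L", "a", "b", "Chroma", "Hue")

#: sensor -> stage -> QuantileSpec, conductance ratio G/G0 (dimensionless).
SENSOR_QUANTILES: dict[str, dict[str, QuantileSpec]] = {
    "S1": {"half-red": QuantileSpec(0.439, 0.415, 0.456),
           "red": QuantileSpec(0.408, 0.364, 0.429)},
    "S2": {"half-red": QuantileSpec(3.812, 3.416, 4.185),
           "red": QuantileSpec(4.710, 3.924, 5.541)},
    "S3": {"half-red": QuantileSpec(0.430, 0.409, 0.443),
           "red": QuantileSpec(0.389, 0.359, 0.414)},
    "S4": {"half-red": QuantileSpec(1.075, 1.061, 1.084),
           "red": QuantileSpec(1.077, 1.067, 1.085)},
    "S5": {"half-red": QuantileSpec(0.421, 0.398, 0.443),
           "red": QuantileSpec(0.380, 0.356, 0.406)},
    "S6": {"half-red": QuantileSpec(3.907, 3.691, 4.225),
           "red": QuantileSpec(4.198, 3.845, 4.669)},
    "S7": {"half-red": QuantileSpec(1.322, 1.234, 1.445),
           "red": QuantileSpec(1.930, 1.506, 2.198)},
    "S8": {"half-red": QuantileSpec(5.713, 5.349, 6.303),
           "red": QuantileSpec(6.370, 5.671, 6.974)},
    "S9": {"half-red": QuantileSpec(1.800, 1.642, 1.950),
           "red": QuantileSpec(2.283, 2.042, 2.555)},
    "S10": {"half-red": QuantileSpec(1.196, 1.160, 1.224),
            "red": QuantileSpec(1.204, 1.172, 1.226)},
}

#: colour feature -> stage -> QuantileSpec (L*, a*, b*, Chroma unitless
#: CIELAB; Hue in radians).  All five are higher in half-red fruit.
COLOUR_QUANTILES: dict[str, dict[str, QuantileSpec]] = {
    "L": {"half-red": QuantileSpec(15.71, 13.61, 16.81),
          "red": QuantileSpec(10.58, 9.78, 11.40)},
    "a": {"half-red": QuantileSpec(25.78, 23.28, 27.46),
          "red": QuantileSpec(20.23, 19.02, 21.58)},
    "b": {"half-red": QuantileSpec(16.40, 14.03, 17.72),
          "red": QuantileSpec(10.16, 9.14, 11.31)},
    "Chroma": {"half-red": QuantileSpec(30.51, 27.23, 32.56),
               "red": QuantileSpec(22.62, 21.20, 24.36)},
    "Hue": {"half-red": QuantileSpec(0.56, 0.53, 0.59),
            "red": QuantileSpec(0.46, 0.44, 0.48)},
}

#: Sensors whose printed 5th–95th ranges do not overlap between stages.
DISJOINT_SENSORS: tuple[str, ...] = ("S7", "S9")

#: Sensors with near-identical stage distributions (no discrimination).
FLAT_SENSORS: tuple[str, ...] = ("S4", "S10")
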