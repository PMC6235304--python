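"""Ground footprint and ground-sample-distance model for nadir drone imagery.

The footprint of a nadir photo scales linearly with flight height above
ground level (AGL).  Rather than deriving the footprint from nominal sensor
and lens physics, the model is calibrated by a single measured
(height, strip width) reference pair; this reproduces measured footprints
exactly and absorbs any unknown in-camera cropping or focal-length error.
The default calibration (47.6 m strip at 40 m AGL for a 6000x4000 frame)
corresponds to the survey camera used for hippo school counts.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CameraSpec", "strip_width", "gsd", "frame_area"]


@dataclass(frozen=True)
class CameraSpec:
    """Camera and calibration constants for the footprint model.

    Parameters
    ----------
    pixels_across_track : int
        Image width in pixels (across the flight line).
    pixels_along_track : int
        Image height in pixels (along the flight line).
    reference_height : float
        Calibration flight height AGL in metres.
    reference_strip_width : float
        Measured ground width in metres covered at ``reference_height``.
    """

    pixels_across_track: int = 6000
    pixels_along_track: int = 4000
    reference_height: float = 40.0
    reference_strip_width: float = 47.6

    def __post_init__(self) -> None:
        for name in (
            "pixels_across_track",
            "pixels_along_track",
            "reference_height",
            "reference_strip_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"CameraSpec.{name} must be strictly positive")

    @property
    def aspect_ratio(self) -> float:
        """Along-track / across-track pixel ratio (frame length / width)."""
        return self.pixels_along_track / self.pixels_across_track


def _check_height(height: float) -> None:
    if height < 0:
        raise ValueError(f"flight height must be non-negative, got {height}")


def strip_width(height: float, camera: CameraSpec = CameraSpec()) -> float:
    """Ground width (m) covered across-track by one photo at ``height`` m AGL.

    Linear in height through the calibration pair:
    ``reference_strip_width * height / reference_height``.
    """
    _check_height(height)
    return camera.reference_strip_width * height / camera.reference_height


def gsd(height: float, camera: CameraSpec = CameraSpec()) -> float:
    """Ground sample distance (m/pixel) at ``height`` m AGL."""
    return strip_width(height, camera) / camera.pixels_across_track


def frame_area(height: float, camera: CameraSpec = CameraSpec()) -> float:
    """Ground area (m^2) covered by one full frame at ``height`` m AGL.

    The frame length along track is the strip width scaled by the pixel
    aspect ratio, so area grows quadratically with height.
    """
    w = strip_width(height, camera)
    return w * w * camera.aspect_ratio
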