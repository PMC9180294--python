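"""Berry image analysis: segmentation, red/green partition, colour features.

Pipeline: Otsu threshold on the R channel (highest contrast against the
dark background) gives a coarse berry mask, refined by erosion and hole
filling; the red surface is isolated by thresholding the R-G enhanced
image inside the berry mask; colour is summarised as mean CIELAB values
over a mask, from which Chroma and hue angle (radians) derive.  An
optional 24-patch chart supports affine colour calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion

#: Minimum Otsu class separation (intensity levels) on the enhanced R-G
#: image; below it the berry surface is treated as single-toned and
#: classified against a fixed threshold instead.
MIN_RED_GREEN_CONTRAST = 30.0
FALLBACK_RED_THRESHOLD = 40.0


@dataclass
class SegmentationResult:
    """Berry mask with its red/green partition and area percentages."""

    primary_mask: np.ndarray
    red_mask: np.ndarray
    green_mask: np.ndarray
    red_pct: float
    green_pct: float


@dataclass(frozen=True)
class ColourFeatures:
    """Mask-averaged CIELAB colour summary of a berry lot."""

    L: float
    a: float
    b: float

    @property
    def chroma(self) -> float:
        return float(np.hypot(self.a, self.b))

    @property
    def hue_angle(self) -> float:
        """Hue angle in radians, atan(b*/a*) — first-quadrant convention."""
        return float(np.arctan(self.b / self.a))


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return image


def segment_primary(
    image: np.ndarray,
    erosion_radius: int | None = None,
    restore_boundary: bool = True,
) -> np.ndarray:
    """Coarse berry segmentation on the R channel.

    Otsu threshold on R, erosion with a disk element (default radius 2 px
    at ~864-px frames, scaled with image size) to strip ragged edge
    defects, then hole filling so interior dark specks do not punch holes
    in the mask.  By default the eroded rim is restored with a matching
    dilation afterwards (an opening with hole closure), so the cleanup
    does not bias the berry area.  Raises if no foreground survives.
    """
    image = _check_image(image)
    r = image[..., 0].astype(float)
    if np.ptp(r) == 0:
        raise ValueError("empty segmentation: R channel is constant")
    mask = r > threshold_otsu(r)
    if erosion_radius is None:
        erosion_radius = max(1, round(2 * min(image.shape[:2]) / 864))
    footprint = disk(erosion_radius)
    mask = erosion(mask, footprint)
    mask = ndimage.binary_fill_holes(mask)
    if restore_boundary:
        mask = dilation(mask, footprint)
    if not mask.any():
        raise ValueError("empty segmentation: no foreground after thresholding")
    return mask


def partition_red_green(image: np.ndarray, primary_mask: np.ndarray) -> SegmentationResult:
    """Split the berry mask into red and green surface areas.

    The enhanced image clip(R - G, 0, 255) is Otsu-thresholded inside the
    berry mask; if the two Otsu classes are closer than
    ``MIN_RED_GREEN_CONTRAST`` the surface is effectively single-toned and
    the fixed ``FALLBACK_RED_THRESHOLD`` decides red vs green for the
    whole mask.  Red and green masks partition the berry pixels exactly.
    """
    image = _check_image(image)
    primary_mask = np.asarray(primary_mask, bool)
    if not primary_mask.any():
        raise ValueError("primary mask is empty")
    enhanced = np.clip(
        image[..., 0].astype(float) - image[..., 1].astype(float), 0.0, 255.0
    )
    vals = enhanced[primary_mask]
    use_fixed = np.ptp(vals) == 0
    if not use_fixed:
        t = threshold_otsu(vals)
        hi, lo = vals[vals > t], vals[vals <= t]
        if hi.size == 0 or lo.size == 0 or hi.mean() - lo.mean() < MIN_RED_GREEN_CONTRAST:
            use_fixed = True
    if use_fixed:
        t = FALLBACK_RED_THRESHOLD
    red_mask = primary_mask & (enhanced > t)
    green_mask = primary_mask & ~red_mask
    n = int(primary_mask.sum())
    red_pct = 100.0 * int(red_mask.sum()) / n
    return SegmentationResult(
        primary_mask=primary_mask,
        red_mask=red_mask,
        green_mask=green_mask,
        red_pct=red_pct,
        green_pct=100.0 - red_pct,
    )


@dataclass
class CalibrationResult:
    """Affine RGB calibration fitted on chart patches."""

    matrix: np.ndarray  # 3 x 3
    offset: np.ndarray  # 3
    residual_rms: float
    image: np.ndarray  # calibrated uint8 image (clipped)
    image_float: np.ndarray  # calibrated float image, unclipped

    def apply(self, rgb: np.ndarray) -> np.ndarray:
        return np.asarray(rgb, float) @ self.matrix.T + self.offset


def colour_calibrate(
    image: np.ndarray, measured_patches: np.ndarray, reference_patches: np.ndarray
) -> CalibrationResult:
    """Least-squares affine colour calibration against 24 chart patches.

    Fits reference ~ M @ measured + offset over the 24 patch pairs and
    applies the map to every pixel.  The clipped 8-bit result is in
    ``image`` and the raw float mapping in ``image_float``; the RMS patch
    residual quantifies the fit.
    """
    image = _check_image(image)
    measured = np.asarray(measured_patches, float)
    reference = np.asarray(reference_patches, float)
    if measured.shape != (24, 3) or reference.shape != (24, 3):
        raise ValueError("exactly 24 measured and 24 reference RGB patches required")
    design = np.hstack([measured, np.ones((24, 1))])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("patch set is rank-deficient; cannot fit affine map")
    coef, *_ = np.linalg.lstsq(design, reference, rcond=None)
    matrix = coef[:3].T
    offset = coef[3]
    fitted = measured @ matrix.T + offset
    residual_rms = float(np.sqrt(np.mean((fitted - reference) ** 2)))
    flat = image.reshape(-1, 3).astype(float)
    mapped = flat @ matrix.T + offset
    image_float = mapped.reshape(image.shape)
    image_u8 = np.clip(np.round(image_float), 0, 255).astype(np.uint8)
    return CalibrationResult(matrix, offset, residual_rms, image_u8, image_float)


def measure_checker_patches(image: np.ndarray, boxes) -> np.ndarray:
    """Mean RGB of each chart patch given (r0, r1, c0, c1) boxes."""
    image = _check_image(image)
    return np.array(
        [image[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0) for r0, r1, c0, c1 in boxes]
    )


def rgb_to_lab(rgb, illuminant: str = "D65") -> tuple[float, float, float]:
    """Convert an 8-bit sRGB triple to CIELAB (D65, 2° observer)."""
    rgb = np.asarray(rgb, float)
    if rgb.shape != (3,):
        raise ValueError("expected a single RGB triple")
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("RGB channels must lie in [0, 255]")
    lab = skcolor.rgb2lab(
        rgb.reshape(1, 1, 3) / 255.0, illuminant=illuminant, observer="2"
    )[0, 0]
    return float(lab[0]), float(lab[1]), float(lab[2])


def colour_features(
    image: np.ndarray,
    mask: np.ndarray,
    calibration: CalibrationResult | None = None,
    illuminant: str = "D65",
) -> ColourFeatures:
    """Mask-averaged CIELAB features of a berry lot.

    Per-pixel Lab values over the mask are averaged; Chroma and hue angle
    derive from the averaged a*/b* (see :class:`ColourFeatures`).
    """
    image = _check_image(image)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if calibration is not None:
        image = calibration.image
    lab = skcolor.rgb2lab(
        image.astype(float) / 255.0, illuminant=illuminant, observer="2"
    )
    mean = lab[mask].mean(axis=0)
    return ColourFeatures(L=float(mean[0]), a=float(mean[1]), b=float(mean[2]))


def analyze_image(
    image: np.ndarray, calibration: CalibrationResult | None = None
) -> dict:
    """Full single-image pipeline -> one feature row (dict).

    Segments the berry lot, partitions red/green, and extracts colour
    features over the whole berry mask.  Returns L, a, b, Chroma, Hue,
    red_pct and green_pct.
    """
    if calibration is not None:
        image = calibration.image
    mask = segment_primary(image)
    seg = partition_red_green(image, mask)
    feats = colour_features(image, mask)
    return {
        "L": feats.L,
        "a": feats.a,
        "b": feats.b,
        "Chroma": feats.chroma,
        "Hue": feats.hue_angle,
        "red_pct": seg.red_pct,
        "green_pct": seg.green_pct,
    }
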