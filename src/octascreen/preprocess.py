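"""Loading and photometric conditioning of en-face OCTA angiograms.

An en-face angiogram is a square grayscale image of retinal blood flow for
one vascular plexus (superficial, SCP, or deep, DCP), acquired as a
macula-centered scan with a known physical field of view (6 mm by default).
Before any vessel segmentation the image is windowed to [0, 1] and corrected
for slowly varying illumination (bias field), so that downstream adaptive
thresholds see comparable contrast across the field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

LAYERS = ("SCP", "DCP")

#: luminance weights for collapsing RGB input to gray
_RGB_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])


@dataclass(frozen=True)
class AngiogramImage:
    """One en-face plexus image with its physical scale.

    Parameters
    ----------
    pixels:
        2-D float array of nonnegative intensities (internally kept in
        [0, 1] after windowing).
    layer:
        ``"SCP"`` or ``"DCP"``.
    fov_mm:
        Physical width of the (square) field of view in millimetres.
    """

    pixels: np.ndarray
    layer: str = "SCP"
    fov_mm: float = 6.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if px.shape[0] != px.shape[1]:
            raise ValueError(
                f"angiogram must be square, got {px.shape[0]}x{px.shape[1]}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0:
            raise ValueError("image contains negative intensities")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def mm_per_pixel(self) -> float:
        return self.fov_mm / self.width_px

    @property
    def pixel_area_um2(self) -> float:
        """Area of a single pixel in square micrometres."""
        return (self.mm_per_pixel * 1000.0) ** 2

    def with_pixels(self, pixels: np.ndarray) -> "AngiogramImage":
        return replace(self, pixels=pixels)


def load_angiogram(path, layer: str = "SCP", fov_mm: float = 6.0) -> AngiogramImage:
    """Read a PNG/TIFF angiogram and attach layer and physical scale.

    Multi-channel input is collapsed to luminance; integer images are
    scaled by their dtype maximum so intensities land in [0, 1].
    """
    raw = iio.imread(path)
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.astype(float) @ _RGB_WEIGHTS
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(np.asarray(raw).dtype).max
    else:
        arr = arr.astype(float)
    return AngiogramImage(pixels=arr, layer=layer, fov_mm=fov_mm)


def normalize_window(img: AngiogramImage) -> AngiogramImage:
    """Linearly rescale intensities to [0, 1] from the observed min/max.

    A constant image has no contrast to window; it is returned as all
    zeros with a warning.
    """
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        warnings.warn("constant image: no contrast to normalize", stacklevel=2)
        return img.with_pixels(np.zeros_like(px))
    return img.with_pixels((px - lo) / (hi - lo))


def _polynomial_background(px: np.ndarray, order: int = 2) -> np.ndarray:
    """Least-squares polynomial surface fit, the illumination estimate.

    A quadratic surface (6 coefficients) reproduces linear and gently
    curved illumination ramps exactly and has too few degrees of freedom
    to chase individual vessels.  Unlike a large convolution kernel it has
    no boundary bias, which matters because the ramp is steepest relative
    to the kernel exactly at the image border.
    """
    h, w = px.shape
    y, x = np.mgrid[0:h, 0:w]
    x = (x / (w - 1) - 0.5).ravel()
    y = (y / (h - 1) - 0.5).ravel()
    cols = [np.ones_like(x)]
    for total in range(1, order + 1):
        for i in range(total + 1):
            cols.append(x ** (total - i) * y**i)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, px.ravel(), rcond=None)
    return (design @ coef).reshape(px.shape)


def correct_bias_field(
    img: AngiogramImage,
    background_scale_mm: float = 1.5,
    method: str = "poly",
) -> AngiogramImage:
    """Divide out a smooth multiplicative illumination estimate.

    The background is estimated either by a low-order polynomial surface
    fit (default, boundary-bias free) or by Gaussian smoothing at a
    physical scale much larger than any vessel (default 1.5 mm), so
    vessels average out and only the illumination ramp survives.  The
    corrected image is re-windowed to [0, 1]; consequently the correction
    is invariant to a global intensity scale of the input.
    """
    if background_scale_mm <= 0:
        raise ValueError("background_scale_mm must be positive")
    if method == "poly":
        background = _polynomial_background(img.pixels)
    elif method == "gaussian":
        sigma_px = background_scale_mm / img.mm_per_pixel
        background = ndimage.gaussian_filter(img.pixels, sigma=sigma_px, mode="nearest")
    else:
        raise ValueError(f"unknown bias-field method {method!r}")
    # floor the estimate well above zero: a polynomial (or smoothed) field
    # can dip toward zero at corners, and dividing by a near-zero estimate
    # would blow up isolated pixels and squash the re-windowed image
    med = float(np.median(background))
    eps = max(1e-6, 0.05 * med) if med > 0 else 1e-6
    n_floored = int(np.count_nonzero(background < eps))
    if n_floored:
        logger.info("bias-field estimate floored at %d pixels", n_floored)
    background = np.maximum(background, eps)
    corrected = img.pixels / background
    lo = float(corrected.min())
    hi = float(np.percentile(corrected, 99.5))  # robust to floored outliers
    if hi <= lo:
        hi = float(corrected.max())
    if hi - lo <= 1e-9 * max(abs(hi), 1.0):
        # flat field: constant output, keep mid-gray so flatness is visible
        return img.with_pixels(np.full_like(corrected, 0.5))
    return img.with_pixels(np.clip((corrected - lo) / (hi - lo), 0.0, 1.0))


def preprocess(
    img: AngiogramImage, background_scale_mm: float = 1.5
) -> AngiogramImage:
    """Standard conditioning chain: window, flatten illumination, re-window."""
    return correct_bias_field(normalize_window(img), background_scale_mm)
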