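"""Image I/O, denoising, ROI segmentation and CIELAB color summarization.

Each sample image (a coated fruit slice photographed on a near-white
background) is reduced to one :class:`ColorMeasurement`: the mean and
standard deviation of L*, a*, b* over the slice region of interest.

Conventions used throughout the package: pixel coordinates are 0-based and
row-major; rectangles are half-open ``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, erosion as _gray_erosion

__all__ = [
    "RGBImage",
    "ROIMask",
    "ColorMeasurement",
    "load_image",
    "median_filter",
    "segment_roi",
    "rgb_to_lab",
    "lab_to_rgb",
    "summarize_roi",
]

Illuminant = Literal["D65", "D50"]

# Reference whites (2-degree observer), Y normalised to 1.
_WHITE = {"D65": np.array([0.95047, 1.0, 1.08883]), "D50": np.array([0.96422, 1.0, 0.82521])}

# sRGB linear RGB -> XYZ (D65), IEC 61966-2-1 primaries; rows rescaled so
# that RGB (1,1,1) maps exactly onto the D65 white point.
_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_M_RGB2XYZ *= (_WHITE["D65"] / _M_RGB2XYZ.sum(axis=1))[:, None]
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)

# Bradford chromatic adaptation.
_M_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)


def _bradford_adaptation(src_white: np.ndarray, dst_white: np.ndarray) -> np.ndarray:
    """XYZ-to-XYZ matrix adapting colors from one reference white to another."""
    cone_src = _M_BRADFORD @ src_white
    cone_dst = _M_BRADFORD @ dst_white
    return np.linalg.inv(_M_BRADFORD) @ np.diag(cone_dst / cone_src) @ _M_BRADFORD


_ADAPT_D65_TO_D50 = _bradford_adaptation(_WHITE["D65"], _WHITE["D50"])
_ADAPT_D50_TO_D65 = np.linalg.inv(_ADAPT_D65_TO_D50)


@dataclass
class RGBImage:
    """An 8-bit RGB image with its source path (if any)."""

    pixels: np.ndarray
    path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"RGBImage requires an H x W x 3 array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("RGB channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class ROIMask:
    """Boolean region-of-interest mask over an image."""

    mask: np.ndarray
    mode: Literal["fixed_rect", "auto"]
    bbox: tuple[int, int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask contains no pixels")
        if self.bbox is None:
            rows, cols = np.nonzero(self.mask)
            self.bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ColorMeasurement:
    """ROI mean/SD of CIELAB channels for one image, with sample metadata."""

    L_mean: float
    a_mean: float
    b_mean: float
    L_sd: float
    a_sd: float
    b_sd: float
    day: int
    treatment: str
    replicate: int
    n_pixels: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.L_mean <= 100.0:
            raise ValueError(f"L* mean {self.L_mean} outside [0, 100]")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if min(self.L_sd, self.a_sd, self.b_sd) < 0:
            raise ValueError("standard deviations must be non-negative")


def load_image(path: str | Path) -> RGBImage:
    """Read a JPEG/PNG file as an 8-bit RGB image (alpha dropped if present)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("L", "I", "I;16", "F", "1"):
                raise ValueError(
                    f"{path} is a grayscale image; 3-channel RGB input is required"
                )
            if mode == "P":
                im = im.convert("RGBA")
            arr = np.asarray(im)
    except (OSError, UnidentifiedImageError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path} did not decode to a 3-channel RGB image")
    return RGBImage(pixels=arr, path=str(path))


def median_filter(img: RGBImage, kernel: int = 3) -> RGBImage:
    """Per-channel spatial median filter with edge replication.

    The default kernel is the smallest useful window, 3x3; larger odd
    kernels trade boundary sharpness for stronger denoising.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be a positive odd integer, got {kernel}")
    h, w, _ = img.pixels.shape
    if kernel > min(h, w):
        raise ValueError(f"kernel {kernel} exceeds image extent {min(h, w)}")
    filtered = ndimage.median_filter(img.pixels, size=(kernel, kernel, 1), mode="nearest")
    return RGBImage(pixels=filtered, path=img.path)


def segment_roi(
    img: RGBImage,
    mode: Literal["fixed_rect", "auto"] = "auto",
    *,
    rect: tuple[int, int, int, int] | None = None,
    erosion: int = 3,
    background: tuple[int, int, int] = (255, 255, 255),
) -> ROIMask:
    """Locate the slice region of interest.

    ``fixed_rect`` reproduces a manual crop (half-open 0-based rectangle).
    ``auto`` thresholds per-pixel Euclidean distance from white (Otsu),
    keeps the largest connected component, and erodes the boundary by
    ``erosion`` pixels to avoid edge glare.
    """
    h, w, _ = img.pixels.shape
    if mode == "fixed_rect":
        if rect is None:
            raise ValueError("fixed_rect mode requires rect=(row0, col0, row1, col1)")
        r0, c0, r1, c1 = rect
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"rectangle {rect} outside image bounds {h}x{w}")
        mask = np.zeros((h, w), dtype=bool)
        mask[r0:r1, c0:c1] = True
        return ROIMask(mask=mask, mode="fixed_rect", bbox=(r0, c0, r1, c1))

    if mode != "auto":
        raise ValueError(f"unknown segmentation mode {mode!r}")
    dist = np.linalg.norm(
        img.pixels.astype(np.float64) - np.asarray(background, dtype=np.float64), axis=2
    )
    if dist.max() < 1e-9:
        raise ValueError("no foreground found: image is uniformly background")
    thr = threshold_otsu(dist)
    fg = dist > thr
    if not fg.any():
        raise ValueError("no foreground found after thresholding")
    labels = label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    if erosion > 0:
        mask = _gray_erosion(mask, disk(erosion)).astype(bool)
    if not mask.any():
        raise ValueError("foreground vanished after erosion; reduce the erosion margin")
    return ROIMask(mask=mask, mode="auto")


def _srgb_decode(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _srgb_encode(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * np.maximum(v, 0.0) ** (1 / 2.4) - 0.055)


_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _lab_f_inv(u: np.ndarray) -> np.ndarray:
    return np.where(u > _DELTA, u**3, 3 * _DELTA**2 * (u - 4.0 / 29.0))


def rgb_to_lab(pixels: np.ndarray, illuminant: Illuminant = "D65") -> np.ndarray:
    """Convert 8-bit sRGB values to CIELAB.

    The pipeline is the standard one: sRGB transfer-function decoding,
    linear RGB -> XYZ under the sRGB (D65) primaries, then XYZ -> CIELAB
    under the chosen reference white.  For D50 the XYZ values are first
    chromatically adapted with the Bradford transform, matching the
    behavior of desktop image-editing software that works in a D50 Lab
    space.

    Parameters
    ----------
    pixels : array_like, shape (..., 3)
        Channel values in [0, 255].
    illuminant : {"D65", "D50"}
        Reference white for the Lab stage.

    Returns
    -------
    ndarray, shape (..., 3)
        L* in [0, 100], a*, b* in CIELAB units.
    """
    if illuminant not in _WHITE:
        raise ValueError(f"illuminant must be 'D65' or 'D50', got {illuminant!r}")
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold the 3 RGB channels")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    linear = _srgb_decode(arr / 255.0)
    xyz = linear @ _M_RGB2XYZ.T
    if illuminant == "D50":
        xyz = xyz @ _ADAPT_D65_TO_D50.T
    white = _WHITE[illuminant]
    f = _lab_f(xyz / white)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_rgb(
    lab: np.ndarray, illuminant: Illuminant = "D65", *, clip_gamut: bool = False
) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`: CIELAB to 8-bit sRGB.

    Raises a gamut error (naming the offending channel) if the color falls
    outside the sRGB gamut by more than rounding tolerance, unless
    ``clip_gamut`` is set, in which case out-of-range linear values are
    clamped (used for noise-perturbed colors that may leave the gamut by a
    hair).
    """
    if illuminant not in _WHITE:
        raise ValueError(f"illuminant must be 'D65' or 'D50', got {illuminant!r}")
    arr = np.asarray(lab, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold L*, a*, b*")
    L, a, b = arr[..., 0], arr[..., 1], arr[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    white = _WHITE[illuminant]
    xyz = np.stack([_lab_f_inv(fx), _lab_f_inv(fy), _lab_f_inv(fz)], axis=-1) * white
    if illuminant == "D50":
        xyz = xyz @ _ADAPT_D50_TO_D65.T
    linear = xyz @ _M_XYZ2RGB.T
    tol = 1e-6
    if not clip_gamut:
        for ch, name in enumerate("RGB"):
            lo, hi = linear[..., ch].min(), linear[..., ch].max()
            if lo < -tol or hi > 1 + tol:
                raise ValueError(
                    f"CIELAB color out of sRGB gamut in channel {name} "
                    f"(linear value range [{lo:.4f}, {hi:.4f}])"
                )
    encoded = np.clip(_srgb_encode(np.clip(linear, 0.0, 1.0)) * 255.0, 0.0, 255.0)
    # Per-channel rounding is not Delta-E-optimal (errors up to ~0.8); pick
    # the best of the 8 surrounding integer-RGB corners instead.
    lo = np.floor(encoded)
    hi = np.ceil(encoded)
    corners = np.empty(encoded.shape[:-1] + (8, 3))
    for i in range(8):
        corners[..., i, :] = np.stack(
            [(hi if i >> ch & 1 else lo)[..., ch] for ch in range(3)], axis=-1
        )
    cand_lab = rgb_to_lab(corners, illuminant=illuminant)
    target = np.stack([L, a, b], axis=-1)[..., None, :]
    best = np.argmin(np.linalg.norm(cand_lab - target, axis=-1), axis=-1)
    chosen = np.take_along_axis(corners, best[..., None, None], axis=-2)[..., 0, :]
    return np.clip(chosen, 0, 255).astype(np.uint8)


def summarize_roi(
    img: RGBImage,
    mask: ROIMask,
    *,
    day: int,
    treatment: str,
    replicate: int,
    illuminant: Illuminant = "D65",
) -> ColorMeasurement:
    """Reduce the masked pixels of an image to one CIELAB mean/SD record."""
    if mask.mask.shape != img.pixels.shape[:2]:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match image {img.pixels.shape[:2]}"
        )
    pix = img.pixels[mask.mask]
    if pix.size == 0:
        raise ValueError("ROI mask selects no pixels")
    lab = rgb_to_lab(pix, illuminant=illuminant)
    means = lab.mean(axis=0)
    sds = lab.std(axis=0)
    return ColorMeasurement(
        L_mean=float(means[0]),
        a_mean=float(means[1]),
        b_mean=float(means[2]),
        L_sd=float(sds[0]),
        a_sd=float(sds[1]),
        b_sd=float(sds[2]),
        day=int(day),
        treatment=str(treatment),
        replicate=int(replicate),
        n_pixels=int(pix.shape[0]),
    )
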