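"""k-space zero-padding, Fourier reconstruction and SNR mapping.

Conventions, declared once and used everywhere:

* The DFT is unitary (``norm="ortho"``), so Parseval holds with unit
  constant: sum|image|^2 == sum|k|^2.
* k-space is stored FFT-shift centered: the DC sample sits at index N//2 on
  each (even) axis.  Zero-padding inserts zeros symmetrically around that
  center, which for even sizes puts any odd remainder on the
  high-frequency side.
* Noise statistics: complex Gaussian k-space noise makes the *background*
  of a magnitude image Rayleigh distributed, with std equal to
  sqrt(2 - pi/2) times the per-component Gaussian sd.  SNR maps divide by
  the plain standard deviation of the selected noise region -- no Rayleigh
  correction by default; pass ``rayleigh_correction=True`` to rescale the
  estimate to the underlying per-component sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateNoiseError, ValidationError
from .phantom import KSpaceSeries, RAYLEIGH_STD_FACTOR

__all__ = [
    "MagnitudeImage",
    "RegionSpec",
    "zero_pad_kspace",
    "crop_kspace",
    "reconstruct_magnitude",
    "reconstruct_series",
    "noise_std",
    "snr_map",
    "snr_series",
    "image_snr",
    "RAYLEIGH_STD_FACTOR",
]


@dataclass
class MagnitudeImage:
    """A reconstructed magnitude image with its provenance."""

    pixels: np.ndarray
    fov: tuple[float, float] | None = None
    tau: float | None = None
    dynamic_index: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("MagnitudeImage must be 2-D")
        if np.any(self.pixels < 0):
            raise ValidationError("magnitude pixels must be >= 0")


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, MagnitudeImage) else np.asarray(img)


@dataclass(frozen=True)
class RegionSpec:
    """A pixel region: 0-based half-open rectangle or explicit mask.

    Rectangles are given as ``x0:x1,y0:y1`` (x = column, y = row); the CLI
    string form is parsed by :meth:`parse`.
    """

    kind: str = "rectangle"
    x0: int = 0
    x1: int = 0
    y0: int = 0
    y1: int = 0
    mask: np.ndarray | None = None

    @classmethod
    def rectangle(cls, x0: int, x1: int, y0: int, y1: int) -> "RegionSpec":
        if x1 <= x0 or y1 <= y0:
            raise ValidationError("rectangle region must be nonempty")
        if min(x0, y0) < 0:
            raise ValidationError("rectangle indices must be >= 0")
        return cls(kind="rectangle", x0=x0, x1=x1, y0=y0, y1=y1)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RegionSpec":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValidationError("mask region must be nonempty")
        return cls(kind="mask", mask=mask)

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse the CLI form ``x0:x1,y0:y1``."""
        try:
            xs, ys = text.split(",")
            x0, x1 = (int(v) for v in xs.split(":"))
            y0, y1 = (int(v) for v in ys.split(":"))
        except ValueError as err:
            raise ValidationError(
                f"region {text!r} is not of the form x0:x1,y0:y1"
            ) from err
        return cls.rectangle(x0, x1, y0, y1)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.kind == "mask":
            if self.mask.shape != tuple(shape):
                raise ValidationError("region mask does not match image shape")
            return self.mask
        ny, nx = shape
        if self.x1 > nx or self.y1 > ny:
            raise ValidationError(
                f"region x0:x1,y0:y1 = {self.x0}:{self.x1},{self.y0}:{self.y1}"
                f" exceeds image shape {shape}"
            )
        out = np.zeros(shape, dtype=bool)
        out[self.y0 : self.y1, self.x0 : self.x1] = True
        return out

    def extract(self, arr: np.ndarray) -> np.ndarray:
        """Values of ``arr`` inside the region, flattened."""
        return np.asarray(arr)[self.to_mask(np.asarray(arr).shape)]


# --------------------------------------------------------------------------
# k-space operations
# --------------------------------------------------------------------------

def zero_pad_kspace(k: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Embed a centered k-space into a larger centered grid of zeros.

    The original samples land so that their DC index N//2 maps onto the
    target DC index T//2; all added samples are exactly zero.
    """
    k = np.asarray(k)
    if k.ndim != 2:
        raise ValidationError("k-space must be 2-D")
    ty, tx = target
    ny, nx = k.shape
    if ty < ny or tx < nx:
        raise ValidationError(f"target {target} smaller than input {k.shape}")
    out = np.zeros((ty, tx), dtype=complex)
    oy, ox = ty // 2 - ny // 2, tx // 2 - nx // 2
    out[oy : oy + ny, ox : ox + nx] = k
    return out


def crop_kspace(k: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`zero_pad_kspace` (exact on padded data)."""
    k = np.asarray(k)
    ty, tx = target
    ny, nx = k.shape
    if ty > ny or tx > nx:
        raise ValidationError(f"crop target {target} larger than input")
    oy, ox = ny // 2 - ty // 2, nx // 2 - tx // 2
    return k[oy : oy + ty, ox : ox + tx].copy()


def forward_kspace(img: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT of an image (DC at N//2)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(np.asarray(img)),
                                       norm="ortho"))


def reconstruct_magnitude(
    k: np.ndarray,
    fov: tuple[float, float] | None = None,
    tau: float | None = None,
    dynamic_index: int | None = None,
) -> MagnitudeImage:
    """Magnitude of the centered unitary inverse 2-D DFT of a k-space."""
    k = np.asarray(k, dtype=complex)
    if not np.all(np.isfinite(k)):
        raise ValidationError("k-space contains non-finite samples")
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))
    return MagnitudeImage(
        pixels=np.abs(img), fov=fov, tau=tau, dynamic_index=dynamic_index
    )


def reconstruct_series(series: KSpaceSeries) -> np.ndarray:
    """Zero-pad every dynamic to the acquisition's reconstruction matrix and
    return the stack of magnitude images, shape (n_dynamics, ny, nx)."""
    target = series.acq.zero_pad_to
    out = [
        reconstruct_magnitude(zero_pad_kspace(k, target)).pixels
        for k in series.kspace
    ]
    return np.stack(out)


# --------------------------------------------------------------------------
# SNR mapping
# --------------------------------------------------------------------------

def noise_std(img, region: RegionSpec, rayleigh_correction: bool = False) -> float:
    """Sample std of the region's pixels; optionally rescaled from the
    Rayleigh magnitude std to the underlying per-component Gaussian sd."""
    values = region.extract(_pixels(img))
    if values.size < 2:
        raise ValidationError("noise region must contain >= 2 pixels")
    sigma = float(np.std(values, ddof=1))
    if rayleigh_correction:
        sigma /= RAYLEIGH_STD_FACTOR
    return sigma


def snr_map(
    img, noise_region: RegionSpec, rayleigh_correction: bool = False
) -> np.ndarray:
    """Pixel-wise SNR: image divided by the noise-region std.

    Scale-invariant by construction: multiplying the whole image by any
    positive constant leaves the map unchanged.
    """
    pixels = _pixels(img)
    sigma = noise_std(img, noise_region, rayleigh_correction)
    scale = float(np.abs(pixels).max())
    if sigma <= 0 or (scale > 0 and sigma / scale < 1e-12):
        raise DegenerateNoiseError(
            "noise region has (near-)zero standard deviation"
        )
    return pixels / sigma


def snr_series(
    images: np.ndarray,
    noise_region: RegionSpec,
    rayleigh_correction: bool = False,
    noise_from: int | None = None,
) -> np.ndarray:
    """SNR maps for a stack of magnitude images.

    By default each dynamic is divided by its own noise-region std.  The
    noise level is a property of the receive chain, not of the dynamic, so
    ``noise_from=i`` shares dynamic ``i``'s estimate across the stack --
    estimating from the first (shortest-delay, lowest-signal) dynamic
    minimizes contamination of the region by object truncation ringing.
    """
    images = np.asarray(images)
    if noise_from is None:
        return np.stack(
            [snr_map(im, noise_region, rayleigh_correction) for im in images]
        )
    if not 0 <= noise_from < images.shape[0]:
        raise ValidationError("noise_from must index a dynamic")
    sigma = noise_std(images[noise_from], noise_region, rayleigh_correction)
    scale = float(np.abs(images).max())
    if sigma <= 0 or (scale > 0 and sigma / scale < 1e-12):
        raise DegenerateNoiseError(
            "noise region has (near-)zero standard deviation"
        )
    return images / sigma


def image_snr(img, roi: RegionSpec, background: RegionSpec) -> float:
    """Scalar image SNR: mean(roi) / std(background).

    Overlapping regions raise a warning (the estimate is then biased);
    a constant background raises :class:`DegenerateNoiseError`.
    """
    pixels = _pixels(img)
    roi_mask = roi.to_mask(pixels.shape)
    bg_mask = background.to_mask(pixels.shape)
    if (roi_mask & bg_mask).any():
        warnings.warn(
            "ROI and background regions overlap; image SNR is biased",
            stacklevel=2,
        )
    sigma = float(np.std(pixels[bg_mask], ddof=1))
    scale = float(np.abs(pixels).max())
    if sigma == 0 or (scale > 0 and sigma / scale < 1e-12):
        raise DegenerateNoiseError("background region std is (near) zero")
    return float(pixels[roi_mask].mean()) / sigma
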