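"""Image preparation: background removal, square padding, uniform resizing,
and resize-quality assessment with SSIM and PSNR.

Background removal is deterministic: the background color is estimated from
a border strip, pixels are classified by chroma distance, the mask is closed
morphologically, reduced to the largest connected component and hole-filled.
Images are interpolated bilinearly; label masks always travel through the
same geometric operations with nearest-neighbor interpolation so that no new
class labels appear and image/mask alignment is preserved.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity
from skimage.transform import resize

__all__ = [
    "remove_background",
    "pad_to_square",
    "resize_uniform",
    "ssim",
    "psnr",
    "quality_report",
    "QualityReport",
    "NoForegroundError",
]

#: RGB fill for removed background and padding; maps to class "remaining"
FILL_VALUE = (0, 0, 0)


class NoForegroundError(ValueError):
    """No foreground object was found in the image."""


def remove_background(
    img: np.ndarray,
    chroma_threshold: float = 40.0,
    border_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace the background with a constant fill; return (image, mask).

    The background color is the median of a border strip
    (``border_fraction`` of each edge); foreground candidates are pixels
    whose Euclidean RGB distance from it exceeds ``chroma_threshold``.  The
    result is idempotent: the fill color is itself background on a second
    pass.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("expected a nonempty HxWx3 image")
    h, w = img.shape[:2]
    b = max(1, int(round(border_fraction * min(h, w))))
    border = np.concatenate([
        img[:b].reshape(-1, 3), img[-b:].reshape(-1, 3),
        img[:, :b].reshape(-1, 3), img[:, -b:].reshape(-1, 3),
    ])
    bg_color = np.median(border.astype(float), axis=0)
    dist = np.linalg.norm(img.astype(float) - bg_color, axis=-1)
    fg = dist > chroma_threshold
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3)), iterations=2)
    labels, n_comp = ndimage.label(fg)
    if n_comp == 0:
        raise NoForegroundError("no foreground object found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
    fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    if fg.sum() < 1e-3 * fg.size:
        raise NoForegroundError("foreground object implausibly small")
    out = img.copy()
    out[~fg] = FILL_VALUE
    return out, fg


def pad_to_square(img: np.ndarray) -> np.ndarray:
    """Center the content on a square canvas, padding with the fill value."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    side = max(h, w)
    if h == w:
        return img.copy()
    if img.ndim == 3:
        out = np.empty((side, side, img.shape[2]), dtype=img.dtype)
        out[...] = np.asarray(FILL_VALUE, dtype=img.dtype)
    else:
        out = np.zeros((side, side), dtype=img.dtype)
    top = (side - h) // 2
    left = (side - w) // 2
    out[top:top + h, left:left + w] = img
    return out


def resize_uniform(arr: np.ndarray, size: int, is_mask: bool = False) -> np.ndarray:
    """Resize a square image (bilinear) or mask (nearest-neighbor) to size².

    Nearest-neighbor on masks guarantees the output label set is a subset of
    the input's.
    """
    arr = np.asarray(arr)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(
            f"input must be square (pad first), got {arr.shape[0]}x{arr.shape[1]}"
        )
    if arr.shape[0] == size:
        return arr.copy()
    if is_mask:
        out = resize(arr, (size, size), order=0, preserve_range=True,
                     anti_aliasing=False)
        return out.astype(arr.dtype)
    out = resize(arr.astype(float), (size, size) + arr.shape[2:], order=1,
                 preserve_range=True, anti_aliasing=arr.shape[0] > size)
    if np.issubdtype(arr.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(arr.dtype)
    return out


def ssim(a: np.ndarray, b: np.ndarray, win_size: int = 7) -> float:
    """Structural similarity in [−1, 1]; 1 means identical structure.

    Uniform 7-px windows with the standard stabilization constants
    (K1=0.01, K2=0.03) on the 0–255 dynamic range; for RGB input the channel
    SSIMs are averaged.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    channel_axis = -1 if a.ndim == 3 else None
    return float(structural_similarity(
        a, b, win_size=win_size, data_range=255, channel_axis=channel_axis,
        gaussian_weights=False,
    ))


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on the 8-bit scale.

    ``10·log10(255² / MSE)``; identical inputs return ``inf``.  Values of
    30–50 dB indicate low quality loss for 24-bit images.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    mse = np.mean((a - b) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(255.0**2 / mse))


@dataclasses.dataclass
class QualityReport:
    """Per-image resize-quality scores with cohort summary statistics."""

    ssim_values: list[float]
    psnr_values: list[float]

    @staticmethod
    def _iqr(values: np.ndarray) -> float:
        finite = values[np.isfinite(values)]
        if finite.size == 0:
            return 0.0
        q1, q3 = np.percentile(finite, [25, 75])
        return float(q3 - q1)

    @property
    def ssim_median(self) -> float:
        return float(np.median(self.ssim_values))

    @property
    def ssim_iqr(self) -> float:
        return self._iqr(np.asarray(self.ssim_values))

    @property
    def psnr_median(self) -> float:
        return float(np.median(self.psnr_values))

    @property
    def psnr_iqr(self) -> float:
        return self._iqr(np.asarray(self.psnr_values))

    def summary(self) -> dict:
        return {
            "ssim_median": self.ssim_median, "ssim_iqr": self.ssim_iqr,
            "psnr_median_db": self.psnr_median, "psnr_iqr_db": self.psnr_iqr,
            "n_images": len(self.ssim_values),
        }


def quality_report(images, target_size: int) -> QualityReport:
    """Quantify the quality loss of resizing a cohort to ``target_size``.

    Each image is resized down to the target and back to its native
    dimensions; SSIM and PSNR between original and round-tripped image are
    reported per image together with cohort median and IQR.
    """
    images = list(images)
    if not images:
        raise ValueError("empty cohort")
    ssim_vals, psnr_vals = [], []
    for img in images:
        img = pad_to_square(np.asarray(img))
        down = resize_uniform(img, target_size)
        back = resize_uniform(down, img.shape[0])
        ssim_vals.append(ssim(img, back))
        psnr_vals.append(psnr(img, back))
    return QualityReport(ssim_values=ssim_vals, psnr_values=psnr_vals)
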