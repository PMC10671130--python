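"""Pixel classification for membrane-layer scans.

A dried membrane layer scanned on a white background contains four kinds of
pixels: achromatic scanner noise (gray/white/black), white melted-polymer
square domains, and chromatic blue pixels in two shades — the darker shade of
methylene blue hydrogen-bonded to gelatin and the lighter shade of the free
dye.  The workflow here mirrors the analysis the scans call for:

1. reject achromatic pixels (near the diagonal of a two-channel histogram),
2. histogram the blue channel of the remaining blue-dominant pixels,
3. deconvolve the two peaks of that histogram as a two-Gaussian mixture,
4. assign each blue pixel to a shade by maximum posterior under the fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.optimize import least_squares
from scipy.signal import find_peaks

__all__ = [
    "ACHROMATIC", "WHITE_DOMAIN", "CHROMATIC",
    "EXCLUDED", "SHADE1", "SHADE2",
    "LayerScan", "PixelMask", "Histogram1D", "MixtureFit", "PixelClassMap",
    "ScanFormatError", "EmptyHistogramError", "MixtureFitError",
    "read_scan", "write_scan", "histogram2d", "mask_pixels",
    "blue_histogram", "fit_two_gaussians", "classify_pixels",
]

# PixelMask labels
ACHROMATIC, WHITE_DOMAIN, CHROMATIC = 0, 1, 2
# PixelClassMap labels
EXCLUDED, SHADE1, SHADE2 = 0, 1, 2

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


class ScanFormatError(ValueError):
    """Input file is not an 8-bit-per-channel RGB bitmap."""


class EmptyHistogramError(ValueError):
    """No blue-dominant chromatic pixels to histogram."""


class MixtureFitError(RuntimeError):
    """Two-Gaussian deconvolution failed to converge."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class LayerScan:
    """One membrane layer's RGB scan plus its position in the stack.

    ``layer_index`` is 1-based, counted from the side facing the source
    (dye) solution; orientation is preserved when the stack is dissected.
    """

    pixels: np.ndarray           # (H, W, 3) uint8
    layer_index: int
    n_layers: int
    dpi: float | None = None

    def __post_init__(self):
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be an (H, W, 3) uint8 array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("scan must contain at least one pixel")
        if not (1 <= self.layer_index <= self.n_layers):
            raise ValueError(
                f"layer_index {self.layer_index} outside 1..{self.n_layers}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class PixelMask:
    """Per-pixel noise/domain labels: ACHROMATIC, WHITE_DOMAIN, CHROMATIC."""

    labels: np.ndarray           # (H, W) uint8

    def __post_init__(self):
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D grid")
        if not np.isin(self.labels, (ACHROMATIC, WHITE_DOMAIN, CHROMATIC)).all():
            raise ValueError("mask contains unknown labels")


@dataclass(frozen=True)
class Histogram1D:
    """256-bin histogram of an 8-bit channel (bin width 1 level)."""

    counts: np.ndarray           # (256,) int64
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(257, dtype=np.int64))

    def __post_init__(self):
        if self.counts.shape != (256,):
            raise ValueError("expected 256 bins for 8-bit data")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MixtureFit:
    """Two-Gaussian deconvolution of a blue-channel histogram.

    Component 1 is the lower-mean (darker, gelatin-bound) shade and
    component 2 the higher-mean (lighter, free-dye) shade; weights sum to 1.
    ``degenerate`` is set when the fitted means are closer than the wider
    fitted sigma, i.e. the histogram is effectively unimodal.
    """

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    w1: float
    w2: float
    converged: bool
    n_pixels: int
    degenerate: bool = False

    def __post_init__(self):
        if not (self.mu1 < self.mu2):
            raise ValueError("components must be ordered mu1 < mu2")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigmas must be positive")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class PixelClassMap:
    """Per-pixel shade assignment: EXCLUDED, SHADE1 (dark), SHADE2 (light)."""

    labels: np.ndarray           # (H, W) uint8
    layer_index: int
    n_layers: int

    def __post_init__(self):
        if self.labels.ndim != 2:
            raise ValueError("class labels must be a 2-D grid")

    @property
    def counts(self) -> dict[str, int]:
        lab = self.labels
        return {
            "excluded": int(np.count_nonzero(lab == EXCLUDED)),
            "shade1": int(np.count_nonzero(lab == SHADE1)),
            "shade2": int(np.count_nonzero(lab == SHADE2)),
        }

    @property
    def total(self) -> int:
        return int(self.labels.size)

    def fraction(self, which: str) -> float:
        return self.counts[which] / self.total


def read_scan(path, layer_index: int, n_layers: int,
              dpi: float | None = None) -> LayerScan:
    """Load an 8-bit/channel RGB bitmap (BMP or PNG) as a :class:`LayerScan`.

    Pixel values are taken verbatim; anything other than 8-bit RGB (e.g.
    grayscale, palette or 16-bit data) raises :class:`ScanFormatError`
    naming the offending property.
    """
    with Image.open(path) as img:
        if img.mode != "RGB":
            raise ScanFormatError(
                f"{path}: image mode is {img.mode!r}, expected 8-bit RGB")
        if dpi is None:
            info_dpi = img.info.get("dpi")
            if info_dpi:
                dpi = float(info_dpi[0])
        pixels = np.asarray(img, dtype=np.uint8)
    return LayerScan(pixels=pixels, layer_index=layer_index,
                     n_layers=n_layers, dpi=dpi)


def write_scan(scan: LayerScan, path) -> None:
    """Write a scan back to disk (format chosen from the file suffix)."""
    img = Image.fromarray(scan.pixels, mode="RGB")
    kwargs = {}
    if scan.dpi:
        kwargs["dpi"] = (scan.dpi, scan.dpi)
    img.save(Path(path), **kwargs)


def histogram2d(scan: LayerScan, ch_x: str = "R", ch_y: str = "B") -> np.ndarray:
    """256x256 joint histogram of two distinct channels over all pixels.

    Achromatic pixels fall on the diagonal of this grid, which is what makes
    the gray-rejection rule visible.
    """
    if ch_x not in _CHANNEL_INDEX or ch_y not in _CHANNEL_INDEX:
        raise ValueError("channels must be one of 'R', 'G', 'B'")
    if ch_x == ch_y:
        raise ValueError("ch_x and ch_y must be distinct channels")
    x = scan.pixels[..., _CHANNEL_INDEX[ch_x]].ravel().astype(np.int64)
    y = scan.pixels[..., _CHANNEL_INDEX[ch_y]].ravel().astype(np.int64)
    counts = np.bincount(x * 256 + y, minlength=256 * 256)
    return counts.reshape(256, 256)


def mask_pixels(scan: LayerScan, gray_tol: int = 20,
                white_floor: int = 245) -> PixelMask:
    """Label pixels as achromatic noise, white melted domain, or chromatic.

    A pixel is achromatic when its maximum pairwise channel difference is at
    most ``gray_tol`` (the diagonal band of the 2-D histogram); otherwise it
    is a white domain when every channel is at least ``white_floor``;
    everything else is chromatic.  The achromatic rule is applied first, so
    a near-white pixel with negligible chroma is excluded either way.
    """
    if not (0 <= gray_tol <= 255):
        raise ValueError("gray_tol must lie in [0, 255]")
    px = scan.pixels.astype(np.int16)
    spread = px.max(axis=2) - px.min(axis=2)
    labels = np.full(scan.shape, CHROMATIC, dtype=np.uint8)
    labels[px.min(axis=2) >= white_floor] = WHITE_DOMAIN
    labels[spread <= gray_tol] = ACHROMATIC
    return PixelMask(labels=labels)


def _blue_dominant(scan: LayerScan, mask: PixelMask) -> np.ndarray:
    """Chromatic pixels whose blue channel strictly exceeds red and green."""
    if mask.labels.shape != scan.shape:
        raise ValueError("mask shape does not match scan")
    px = scan.pixels
    return ((mask.labels == CHROMATIC)
            & (px[..., 2] > px[..., 0])
            & (px[..., 2] > px[..., 1]))


def blue_histogram(scan: LayerScan, mask: PixelMask) -> Histogram1D:
    """Histogram the blue channel over blue-dominant chromatic pixels."""
    selected = scan.pixels[..., 2][_blue_dominant(scan, mask)]
    if selected.size == 0:
        raise EmptyHistogramError("no blue-dominant chromatic pixels in scan")
    counts = np.bincount(selected.astype(np.int64), minlength=256)
    return Histogram1D(counts=counts)


def _mixture_model(x, mu1, mu2, s1, s2, w1, n):
    g1 = w1 / (s1 * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
    g2 = (1 - w1) / (s2 * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - mu2) / s2) ** 2)
    return n * (g1 + g2)


MIN_HISTOGRAM_TOTAL = 100
SIGMA_FLOOR = 1.0


def _initial_guess(counts: np.ndarray) -> tuple[float, float, float, float, float]:
    """Deterministic starting point: two most prominent smoothed maxima.

    The saturated boundary bins (0 and 255) are left out of the peak search
    so that clipped mass piled up at the range limits cannot masquerade as
    a component.
    """
    kernel = np.ones(5) / 5.0
    smoothed = np.convolve(counts[1:255].astype(float), kernel, mode="same")
    peaks, props = find_peaks(smoothed, prominence=0.0)
    x = np.arange(256, dtype=float)
    total = counts.sum()
    mean = float((x * counts).sum() / total)
    sd = float(np.sqrt(((x - mean) ** 2 * counts).sum() / total))
    sd = max(sd, SIGMA_FLOOR)
    if peaks.size >= 2:
        order = np.argsort(props["prominences"])[::-1]
        m1, m2 = sorted(float(peaks[i]) + 1.0 for i in order[:2])
    elif peaks.size == 1:
        m1, m2 = float(peaks[0]) + 1.0 - sd, float(peaks[0]) + 1.0 + sd
    else:
        m1, m2 = mean - sd, mean + sd
    if m2 - m1 < 1.0:
        m1, m2 = m1 - 1.0, m2 + 1.0
    split = 0.5 * (m1 + m2)
    w1 = float(counts[: int(round(split)) + 1].sum()) / total
    w1 = min(max(w1, 0.05), 0.95)
    lo = counts[: int(round(split)) + 1]
    hi = counts[int(round(split)) + 1:]

    def _seg_sd(seg_counts, offset, center):
        n = seg_counts.sum()
        if n == 0:
            return sd
        xs = np.arange(offset, offset + seg_counts.size, dtype=float)
        return max(float(np.sqrt(((xs - center) ** 2 * seg_counts).sum() / n)),
                   SIGMA_FLOOR)

    s1 = _seg_sd(lo, 0, m1)
    s2 = _seg_sd(hi, int(round(split)) + 1, m2)
    return m1, m2, s1, s2, w1


def fit_two_gaussians(hist: Histogram1D) -> MixtureFit:
    """Deconvolve a blue-channel histogram into two Gaussian components.

    A two-Gaussian density scaled by the pixel count is fitted to the bin
    counts by (unweighted) nonlinear least squares with deterministic
    initialization, so repeated runs on the same histogram are bit-identical.
    The boundary bins 0 and 255 are excluded from the residuals: 8-bit
    saturation piles all out-of-range mass into them, which would otherwise
    bias components near the range limits.  Histograms with fewer than 100
    pixels are refused; an effectively unimodal result (|mu2 - mu1| smaller
    than the wider sigma) is returned with ``degenerate=True`` and a
    warning.
    """
    total = hist.total
    if total < MIN_HISTOGRAM_TOTAL:
        raise ValueError(
            f"histogram holds {total} pixels; at least {MIN_HISTOGRAM_TOTAL} "
            "are required for a stable deconvolution")
    counts = hist.counts.astype(float)[1:255]
    x = np.arange(256, dtype=float)[1:255]
    m1, m2, s1, s2, w1 = _initial_guess(hist.counts)

    def residuals(p):
        return _mixture_model(x, p[0], p[1], p[2], p[3], p[4], total) - counts

    lower = [0.0, 0.0, SIGMA_FLOOR, SIGMA_FLOOR, 1e-6]
    upper = [255.0, 255.0, 128.0, 128.0, 1 - 1e-6]
    p0 = np.clip([m1, m2, s1, s2, w1], lower, upper)
    result = least_squares(residuals, p0, bounds=(lower, upper), method="trf")
    if result.status <= 0:
        raise MixtureFitError(
            f"deconvolution did not converge: {result.message}",
            last_params=result.x)
    mu1, mu2, sig1, sig2, w = (float(v) for v in result.x)
    if mu1 > mu2:
        mu1, mu2, sig1, sig2, w = mu2, mu1, sig2, sig1, 1.0 - w
    elif mu1 == mu2:
        mu2 = mu1 + 1e-6
    # Effectively unimodal: overlapping components, or one component left
    # holding a negligible share of the mass.
    degenerate = (mu2 - mu1) < max(sig1, sig2) or min(w, 1.0 - w) < 0.02
    if degenerate:
        warnings.warn(
            "fitted components overlap or one is negligible; histogram is "
            "effectively unimodal", RuntimeWarning, stacklevel=2)
    return MixtureFit(mu1=mu1, mu2=mu2, sigma1=sig1, sigma2=sig2,
                      w1=w, w2=1.0 - w, converged=True,
                      n_pixels=total, degenerate=degenerate)


def _log_posterior_lut(fit: MixtureFit) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized log posteriors of each component at blue levels 0..255."""
    b = np.arange(256, dtype=float)
    lp1 = (math.log(fit.w1) - math.log(fit.sigma1)
           - 0.5 * ((b - fit.mu1) / fit.sigma1) ** 2)
    lp2 = (math.log(fit.w2) - math.log(fit.sigma2)
           - 0.5 * ((b - fit.mu2) / fit.sigma2) ** 2)
    return lp1, lp2


def classify_pixels(scan: LayerScan, mask: PixelMask,
                    fit: MixtureFit) -> PixelClassMap:
    """Assign each blue-dominant chromatic pixel to a shade class.

    Assignment is by maximum posterior under the fitted mixture, evaluated
    on the pixel's blue level; exact ties go to shade 1 (the lower-mean,
    gelatin-bound shade).  All other pixels are labeled EXCLUDED.
    """
    if not fit.converged:
        raise ValueError("cannot classify with a non-converged mixture fit")
    dominant = _blue_dominant(scan, mask)
    lp1, lp2 = _log_posterior_lut(fit)
    blue = scan.pixels[..., 2].astype(np.int64)
    labels = np.full(scan.shape, EXCLUDED, dtype=np.uint8)
    shade1 = lp1[blue] >= lp2[blue]
    labels[dominant & shade1] = SHADE1
    labels[dominant & ~shade1] = SHADE2
    return PixelClassMap(labels=labels, layer_index=scan.layer_index,
                         n_layers=scan.n_layers)
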