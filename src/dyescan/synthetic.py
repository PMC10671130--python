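"""Synthetic layer scans and diffusion traces with exact ground truth.

No scans or trace tables accompany the experiments this package analyzes, so
every downstream operation is validated on synthetic data that carries the
same statistical structure the analysis assumes:

* layer scans: a white background with regularly spaced white melted-polymer
  squares, two blue-shade pixel populations with Gaussian blue-channel
  distributions (dark, gelatin-bound around 195; light, free dye around
  240), and achromatic scanner-noise pixels;
* thickness profiles that are uniform (thin, equilibrated membranes),
  sigmoidal (the diffusion interface of thick membranes), or edge-peaked
  (the bound-dye/gelatin pattern);
* two-wave concentration traces built by inverting the quasi-steady
  relation, so the generating coefficient is recoverable by construction;
* gelatin weights proportional to the bound-dye fraction plus noise.

All generators are pure functions of (recipe, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import LayerScan
from .diffusion import DiffusionTrace

__all__ = [
    "ScanRecipe", "TraceRecipe", "CapacityError",
    "LBL_BACKGROUND", "LBL_SQUARE", "LBL_GRAY", "LBL_SHADE1", "LBL_SHADE2",
    "generate_scan", "generate_profile", "generate_trace",
    "generate_gelatin_weights",
]

# Ground-truth label codes for generated scans.
LBL_BACKGROUND, LBL_SQUARE, LBL_GRAY, LBL_SHADE1, LBL_SHADE2 = range(5)

# Red/green channels of shade pixels as fixed ratios of blue, bracketing the
# channel ratios of both resonance-state colors while keeping every shade
# pixel blue-dominant and clearly chromatic (B - R = 0.67 B > any reasonable
# gray tolerance).
RED_RATIO = 0.33
GREEN_RATIO = 0.37

# Minimum blue level so that spread (B - R) stays above the default gray
# tolerance even for extreme low draws.
_BLUE_MIN = 31


class CapacityError(ValueError):
    """Requested class fractions exceed the available non-square area."""


@dataclass(frozen=True)
class ScanRecipe:
    """Recipe for a stack of synthetic layer scans.

    Blue-channel means default to the centers of the two observed shade
    clouds (dark 180-210, light around 240); fractions are per-layer target
    area fractions of *all* pixels.
    """

    width: int = 256
    height: int = 256
    square_size: int = 24
    square_spacing: int = 64
    shade1_mu: float = 195.0
    shade2_mu: float = 240.0
    shade1_sigma: float = 8.0
    shade2_sigma: float = 6.0
    shade1_frac: tuple = (0.3,)
    shade2_frac: tuple = (0.2,)
    gray_noise_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        f1 = tuple(float(v) for v in np.atleast_1d(self.shade1_frac))
        f2 = tuple(float(v) for v in np.atleast_1d(self.shade2_frac))
        object.__setattr__(self, "shade1_frac", f1)
        object.__setattr__(self, "shade2_frac", f2)
        if len(f1) != len(f2) or not f1:
            raise ValueError("fraction vectors must be equal-length and nonempty")
        for a, b in zip(f1, f2):
            if a < 0 or b < 0 or a + b + self.gray_noise_frac > 1:
                raise ValueError("per-layer fractions must be nonnegative and "
                                 "sum (with noise) to at most 1")
        if not (0 < self.shade1_mu < 255 and 0 < self.shade2_mu < 255):
            raise ValueError("shade means must lie in (0, 255)")
        if self.shade1_sigma <= 0 or self.shade2_sigma <= 0:
            raise ValueError("shade sigmas must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("scan dimensions must be positive")
        if self.square_size < 0 or self.square_spacing < 1:
            raise ValueError("square grid must have positive spacing")

    @property
    def n_layers(self) -> int:
        return len(self.shade1_frac)


@dataclass(frozen=True)
class TraceRecipe:
    """Recipe for a two-wave diffusion trace.

    ``deff_true`` is the whole-membrane coefficient on the package's
    conventional scale; the first wave is the saturating rise
    c(t) = c0 (1 - exp(-k t)) with k = deff_true / thickness, whose initial
    slope deff_true * c0 / thickness inverts the quasi-steady relation.
    Defaults emulate an 8-layer membrane (per-layer coefficient 26e-9,
    inside the reported 25-28e-9 band) in a 0.04 g dm^-3 source cell.
    """

    deff_true: float = 26e-9 * 8
    thickness: float = 1e-3
    n_layers: int = 8
    plateau_start: float = 2400.0
    wave2_start: float = 7200.0
    wave2_slope: float = 2.9e-7
    noise_sd: float = 2e-4
    duration: float = 14400.0
    dt: float = 300.0
    source_c0: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.plateau_start < self.wave2_start < self.duration):
            raise ValueError("need 0 < plateau_start < wave2_start < duration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.deff_true <= 0 or self.thickness <= 0 or self.dt <= 0:
            raise ValueError("deff_true, thickness and dt must be positive")
        if self.wave2_slope < 0:
            raise ValueError("wave2_slope must be nonnegative")
        k = self.deff_true / self.thickness
        plateau_c = self.source_c0 * (1.0 - np.exp(-k * self.plateau_start))
        c_end = plateau_c + self.wave2_slope * (self.duration - self.wave2_start)
        if c_end > self.source_c0:
            raise ValueError("recipe drives the receiving cell above the "
                             "source concentration; lower wave2_slope or "
                             "shorten the trace")


def _square_mask(height: int, width: int, size: int, spacing: int) -> np.ndarray:
    mask = np.zeros((height, width), dtype=bool)
    if size == 0:
        return mask
    offset = max((spacing - size) // 2, 0)
    for top in range(offset, height, spacing):
        for left in range(offset, width, spacing):
            mask[top:top + size, left:left + size] = True
    return mask


def generate_scan(recipe: ScanRecipe, layer_index: int
                  ) -> tuple[LayerScan, np.ndarray]:
    """Generate one layer's scan and its exact per-pixel label grid.

    White squares sit on a regular grid; shade and achromatic-noise pixels
    are placed uniformly at random over the remaining area with counts
    rounded from the recipe fractions.  Shade pixels draw their blue channel
    from the recipe's Gaussian (clipped to the valid range) with red/green
    fixed ratios of blue, so every generated shade pixel is blue-dominant
    and chromatic by construction.
    """
    n_layers = recipe.n_layers
    if not (1 <= layer_index <= n_layers):
        raise ValueError(f"layer_index {layer_index} outside 1..{n_layers}")
    rng = np.random.default_rng([recipe.seed, layer_index])
    h, w = recipe.height, recipe.width
    total = h * w

    labels = np.full((h, w), LBL_BACKGROUND, dtype=np.uint8)
    squares = _square_mask(h, w, recipe.square_size, recipe.square_spacing)
    labels[squares] = LBL_SQUARE

    n1 = int(round(recipe.shade1_frac[layer_index - 1] * total))
    n2 = int(round(recipe.shade2_frac[layer_index - 1] * total))
    ng = int(round(recipe.gray_noise_frac * total))
    free = np.flatnonzero(~squares.ravel())
    if n1 + n2 + ng > free.size:
        raise CapacityError(
            f"layer {layer_index}: {n1 + n2 + ng} class pixels requested but "
            f"only {free.size} non-square pixels available")
    chosen = rng.choice(free, size=n1 + n2 + ng, replace=False)
    flat_labels = labels.ravel()
    flat_labels[chosen[:n1]] = LBL_SHADE1
    flat_labels[chosen[n1:n1 + n2]] = LBL_SHADE2
    flat_labels[chosen[n1 + n2:]] = LBL_GRAY

    pixels = np.full((total, 3), 255, dtype=np.uint8)
    for code, mu, sigma in ((LBL_SHADE1, recipe.shade1_mu, recipe.shade1_sigma),
                            (LBL_SHADE2, recipe.shade2_mu, recipe.shade2_sigma)):
        idx = np.flatnonzero(flat_labels == code)
        blue = np.clip(np.rint(rng.normal(mu, sigma, idx.size)),
                       _BLUE_MIN, 255).astype(np.uint8)
        pixels[idx, 0] = np.rint(RED_RATIO * blue).astype(np.uint8)
        pixels[idx, 1] = np.rint(GREEN_RATIO * blue).astype(np.uint8)
        pixels[idx, 2] = blue
    gray_idx = np.flatnonzero(flat_labels == LBL_GRAY)
    v = rng.integers(0, 256, gray_idx.size).astype(np.uint8)
    pixels[gray_idx] = v[:, None]

    pixels = pixels.reshape(h, w, 3)
    # Constructed invariants: shade pixels blue-dominant, noise achromatic.
    shade = (labels == LBL_SHADE1) | (labels == LBL_SHADE2)
    assert np.all(pixels[shade, 2] > pixels[shade, 0])
    assert np.all(pixels[shade, 2] > pixels[shade, 1])
    scan = LayerScan(pixels=pixels, layer_index=layer_index,
                     n_layers=n_layers, dpi=1200)
    return scan, labels


def generate_profile(n_layers: int, mode: str, **params) -> np.ndarray:
    """Per-layer fraction vector in one of the three observed regimes.

    uniform: constant ``level``; sigmoid: 4-parameter logistic over layer
    index (``lower``, ``upper``, ``midpoint``, ``steepness``); edge_peaked:
    symmetric parabola with ``high`` at both edges and ``low`` at the
    center.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    i = np.arange(1, n_layers + 1, dtype=float)
    if mode == "uniform":
        level = params.get("level", 0.3)
        return np.full(n_layers, float(level))
    if mode == "sigmoid":
        lower = params.get("lower", 0.1)
        upper = params.get("upper", 0.6)
        midpoint = params.get("midpoint", (n_layers + 1) / 2.0)
        steepness = params.get("steepness", 0.8)
        return lower + (upper - lower) / (1.0 + np.exp(-steepness * (i - midpoint)))
    if mode == "edge_peaked":
        low = params.get("low", 0.15)
        high = params.get("high", 0.4)
        center = (n_layers + 1) / 2.0
        return low + (high - low) * ((i - center) / (1.0 - center)) ** 2
    raise ValueError(f"unknown profile mode {mode!r}")


def generate_trace(recipe: TraceRecipe) -> tuple[DiffusionTrace, dict]:
    """Generate a two-wave trace plus its true change points.

    Returns the trace and a dict with the true segment boundaries (sample
    indices of plateau start and second-wave start), the rate constant, and
    the generating coefficients.
    """
    t = np.arange(0.0, recipe.duration + recipe.dt / 2, recipe.dt)
    k = recipe.deff_true / recipe.thickness
    c = recipe.source_c0 * (1.0 - np.exp(-k * np.minimum(t, recipe.plateau_start)))
    plateau_c = recipe.source_c0 * (1.0 - np.exp(-k * recipe.plateau_start))
    in_wave2 = t >= recipe.wave2_start
    c[in_wave2] = plateau_c + recipe.wave2_slope * (t[in_wave2] - recipe.wave2_start)
    rng = np.random.default_rng([recipe.seed, 0xD1FF])
    if recipe.noise_sd > 0:
        c = c + rng.normal(0.0, recipe.noise_sd, c.size)
    c = np.clip(c, 0.0, recipe.source_c0)
    trace = DiffusionTrace(times=t, concentrations=c,
                           source_c0=recipe.source_c0,
                           thickness=recipe.thickness,
                           n_layers=recipe.n_layers)
    truth = {
        "plateau_start_index": int(np.searchsorted(t, recipe.plateau_start)),
        "wave2_start_index": int(np.searchsorted(t, recipe.wave2_start)),
        "rate_constant": k,
        "deff_true": recipe.deff_true,
        "wave2_slope": recipe.wave2_slope,
        "plateau_concentration": float(plateau_c),
    }
    return trace, truth


def generate_gelatin_weights(fractions, coupling: float = 0.1,
                             noise_sd: float = 0.2, seed: int = 0) -> np.ndarray:
    """Gelatin weight per area coupled to the bound-dye fraction.

    weight = fraction / coupling + Gaussian noise, floored at zero; with the
    default coupling a fraction of 0.3 corresponds to 3 g m^-2.
    """
    if coupling <= 0:
        raise ValueError("coupling must be positive")
    f = np.asarray(fractions, dtype=float)
    rng = np.random.default_rng([seed, 0x6E1])
    w = f / coupling + rng.normal(0.0, noise_sd, f.shape)
    return np.maximum(w, 0.0)
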