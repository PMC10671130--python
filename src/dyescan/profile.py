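"""Membrane-thickness profiles of blue-pixel fractions.

The per-layer fraction of blue pixels is the scan-based surrogate for local
dye concentration.  Stacking the per-layer fractions in order (layer 1 faces
the source solution) gives a concentration profile across the membrane
thickness.  Thin membranes equilibrate and show a flat profile; thick ones
develop a sigmoidal diffusion interface in the *unbound* (light, shade-2)
dye, while the gelatin-*bound* (dark, shade-1) dye tracks the gelatin itself
and peaks at both edges.  This module assembles profiles from classified
scans, fits the sigmoid interface, correlates bound-dye fraction with
gelatin weight per area, and splits pooled (weight, fraction) pairs into the
main cloud and an outlier cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import expit

from .classify import PixelClassMap

__all__ = [
    "LayerProfile", "SigmoidFit", "CorrelationResult", "PairCluster",
    "UndefinedCorrelationError", "DegenerateClusterError",
    "build_profile", "fit_sigmoid", "correlate_gelatin", "cluster_pairs",
    "label_regime", "INTERFACE_THRESHOLD",
]

# Fitted (upper - lower) below this declares a uniform, interface-free
# profile: the thin-membrane regime where the dye has equilibrated.
INTERFACE_THRESHOLD = 0.05


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance in a series)."""


class DegenerateClusterError(ValueError):
    """All pooled points identical; no two-cluster split exists."""


@dataclass(frozen=True)
class LayerProfile:
    """Per-layer shade fractions (and optional gelatin weight per area).

    Fractions are blue pixels of a class divided by *all* pixels of the
    layer; gelatin weight is in g per m^2.
    """

    n_layers: int
    fractions_shade1: np.ndarray
    fractions_shade2: np.ndarray
    gelatin_weight: np.ndarray | None = None

    def __post_init__(self):
        f1 = np.asarray(self.fractions_shade1, dtype=float)
        f2 = np.asarray(self.fractions_shade2, dtype=float)
        object.__setattr__(self, "fractions_shade1", f1)
        object.__setattr__(self, "fractions_shade2", f2)
        if f1.shape != (self.n_layers,) or f2.shape != (self.n_layers,):
            raise ValueError("fraction vectors must have length n_layers")
        if np.any(f1 < 0) or np.any(f2 < 0) or np.any(f1 + f2 > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1] and sum to at most 1")
        if self.gelatin_weight is not None:
            w = np.asarray(self.gelatin_weight, dtype=float)
            object.__setattr__(self, "gelatin_weight", w)
            if w.shape != (self.n_layers,):
                raise ValueError("gelatin_weight must have length n_layers")

    @property
    def layer_index(self) -> np.ndarray:
        return np.arange(1, self.n_layers + 1)


@dataclass(frozen=True)
class SigmoidFit:
    """4-parameter logistic fit of a fraction profile over layer index.

    Model: f(i) = lower + (upper - lower) / (1 + exp(-steepness (i - midpoint)))
    with the convention lower <= upper (a decreasing interface has negative
    steepness).  ``interface_free`` marks the thin-membrane regime where the
    fitted range is below :data:`INTERFACE_THRESHOLD`.
    """

    lower: float
    upper: float
    midpoint: float
    steepness: float
    rss: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("requires lower <= upper")
        if not np.isfinite(self.steepness):
            raise ValueError("steepness must be finite")

    @property
    def interface_free(self) -> bool:
        return (self.upper - self.lower) < INTERFACE_THRESHOLD

    def predict(self, i) -> np.ndarray:
        i = np.asarray(i, dtype=float)
        return _logistic(i, self.lower, self.upper, self.midpoint,
                         self.steepness)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of bound-dye fraction with gelatin weight."""

    r: float
    n: int
    slope: float
    intercept: float

    def __post_init__(self):
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")
        if self.n < 3:
            raise ValueError("need at least 3 paired observations")


@dataclass(frozen=True)
class PairCluster:
    """Two-group split of pooled (gelatin weight, fraction) pairs."""

    labels: tuple               # 'main' / 'outlier' per pooled pair
    centroid_main: tuple        # (weight, fraction)
    centroid_outlier: tuple


def build_profile(classmaps: Sequence[PixelClassMap],
                  gelatin_weights: Sequence[float] | None = None) -> LayerProfile:
    """Assemble a thickness profile from per-layer classifications.

    ``classmaps`` must be ordered by layer index and cover 1..n_layers
    without gaps; fractions are class counts over total pixels per layer.
    """
    if not classmaps:
        raise ValueError("no classified layers supplied")
    n_layers = classmaps[0].n_layers
    indices = [cm.layer_index for cm in classmaps]
    if any(cm.n_layers != n_layers for cm in classmaps):
        raise ValueError("classified layers disagree on n_layers")
    if indices != list(range(1, n_layers + 1)):
        raise ValueError(
            f"layers must be ordered 1..{n_layers} without gaps; got {indices}")
    f1 = np.array([cm.fraction("shade1") for cm in classmaps])
    f2 = np.array([cm.fraction("shade2") for cm in classmaps])
    weights = None
    if gelatin_weights is not None:
        weights = np.asarray(gelatin_weights, dtype=float)
    return LayerProfile(n_layers=n_layers, fractions_shade1=f1,
                        fractions_shade2=f2, gelatin_weight=weights)


def _logistic(i, lower, upper, midpoint, steepness):
    return lower + (upper - lower) * expit(steepness * (i - midpoint))


def fit_sigmoid(profile: LayerProfile, which: str = "shade2") -> SigmoidFit:
    """Fit the 4-parameter logistic diffusion interface to a profile.

    Fitted by least squares over the layer index with deterministic
    initialization from the edge means, then canonicalized to lower <= upper
    (swapping asymptotes negates the steepness, leaving the curve itself
    unchanged).  Intended for the unbound (shade-2) dye, whose gradient is
    the diffusion interface; the bound shade peaks at both edges and is
    better summarized by :func:`label_regime`.
    """
    if which not in ("shade1", "shade2"):
        raise ValueError("which must be 'shade1' or 'shade2'")
    y = (profile.fractions_shade1 if which == "shade1"
         else profile.fractions_shade2)
    n = profile.n_layers
    if n < 4:
        raise ValueError("sigmoid fitting needs at least 4 layers")
    x = profile.layer_index.astype(float)

    if float(np.ptp(y)) < 1e-12:
        level = float(y[0])
        return SigmoidFit(lower=level, upper=level,
                          midpoint=(n + 1) / 2.0, steepness=0.0, rss=0.0)

    edge = max(1, n // 4)
    lo0, up0 = float(np.mean(y[:edge])), float(np.mean(y[-edge:]))
    k0 = 1.0 if up0 >= lo0 else -1.0
    p0 = [min(lo0, up0), max(lo0, up0), (n + 1) / 2.0, k0]

    def residuals(p):
        return _logistic(x, *p) - y

    # Bounds are symmetric under layer-order reversal, so a reversed profile
    # fits to the mirrored parameters; they also keep the steepness from
    # wandering on noisy flat profiles where it is unidentifiable.
    span = float(np.ptp(y))
    bounds = ([float(y.min()) - span, float(y.min()) - span, 1.0 - n, -25.0],
              [float(y.max()) + span, float(y.max()) + span, 2.0 * n, 25.0])
    result = least_squares(residuals, np.clip(p0, *bounds), method="trf",
                           bounds=bounds, xtol=1e-12, ftol=1e-12, gtol=1e-12,
                           max_nfev=20000)
    if result.status <= 0:
        # A noisy flat profile leaves the steepness unidentifiable and the
        # optimizer can exhaust its budget wandering a flat cost valley;
        # accept the fit if it is at least as good as the constant model
        # (the bounds already confine the asymptotes to the data range).
        flat_rss = float(np.sum((y - y.mean()) ** 2))
        if float(np.sum(result.fun ** 2)) > flat_rss:
            raise RuntimeError(
                f"sigmoid fit did not converge: {result.message}")
    lower, upper, mid, steep = (float(v) for v in result.x)
    if lower > upper:
        lower, upper, steep = upper, lower, -steep
    return SigmoidFit(lower=lower, upper=upper, midpoint=mid,
                      steepness=steep, rss=float(np.sum(result.fun ** 2)))


def correlate_gelatin(profile: LayerProfile) -> CorrelationResult:
    """Pearson correlation of bound-dye (shade-1) fraction with gelatin weight.

    Also returns the least-squares line of fraction on weight.
    """
    if profile.gelatin_weight is None:
        raise ValueError("profile carries no gelatin weights")
    if profile.n_layers < 3:
        raise ValueError("correlation needs at least 3 layers")
    w = profile.gelatin_weight
    f = profile.fractions_shade1
    if float(np.std(w)) == 0.0 or float(np.std(f)) == 0.0:
        raise UndefinedCorrelationError(
            "one of the series has zero variance; correlation undefined")
    r = float(stats.pearsonr(w, f).statistic)
    slope, intercept = np.polyfit(w, f, 1)
    return CorrelationResult(r=r, n=profile.n_layers,
                             slope=float(slope), intercept=float(intercept))


def _pool_pairs(profiles: Iterable[LayerProfile]) -> np.ndarray:
    pairs = []
    for p in profiles:
        if p.gelatin_weight is None:
            raise ValueError("all profiles must carry gelatin weights")
        pairs.extend(zip(p.gelatin_weight, p.fractions_shade1))
    return np.asarray(pairs, dtype=float)


def cluster_pairs(profiles: Sequence[LayerProfile]) -> PairCluster:
    """Split pooled (weight, fraction) pairs into main and outlier clusters.

    2-means on standardized pairs with deterministic farthest-pair
    initialization; the smaller group is labeled ``outlier`` (ties go to the
    group with the larger standardized centroid).  Deterministic and
    invariant to the order of the input profiles.
    """
    pts = _pool_pairs(profiles)
    if pts.shape[0] < 6:
        raise ValueError("need at least 6 pooled (weight, fraction) pairs")
    spread = np.ptp(pts, axis=0)
    if np.all(spread == 0.0):
        raise DegenerateClusterError("all pooled points are identical")
    scale = pts.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    z = (pts - pts.mean(axis=0)) / scale

    # Farthest pair as initial centroids; lexicographic tie-break keeps the
    # choice independent of input order.
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    best = None
    for i in range(len(z)):
        for j in range(i + 1, len(z)):
            a, b = sorted((tuple(z[i]), tuple(z[j])))
            key = (-d2[i, j], a, b)
            if best is None or key < best[0]:
                best = (key, np.array([a, b]))
    centroids = best[1]

    labels = None
    for _ in range(100):
        dist = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(dist, axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in (0, 1):
            if np.any(labels == c):
                centroids[c] = z[labels == c].mean(axis=0)

    sizes = np.bincount(labels, minlength=2)
    if sizes[0] == sizes[1]:
        outlier_id = int(np.argmax(np.abs(centroids).sum(axis=1)))
    else:
        outlier_id = int(np.argmin(sizes))
    orig_centroids = []
    for c in (0, 1):
        member = pts[labels == c]
        orig_centroids.append(tuple(member.mean(axis=0)) if member.size
                              else (float("nan"), float("nan")))
    names = tuple("outlier" if l == outlier_id else "main" for l in labels)
    return PairCluster(labels=names,
                       centroid_main=orig_centroids[1 - outlier_id],
                       centroid_outlier=orig_centroids[outlier_id])


def label_regime(fractions: Sequence[float],
                 interface_threshold: float = INTERFACE_THRESHOLD,
                 edge_threshold: float = 0.05) -> str:
    """Classify a fraction profile as uniform, sigmoid, or edge-peaked.

    Edge-peaked (both edges high, center low — the bound-dye/gelatin
    pattern) is declared when the mean of the two edge layers exceeds the
    central mean by ``edge_threshold`` and the two edges agree better than
    they differ from the center.  Otherwise a logistic fit decides between a
    diffusion interface (fitted range >= ``interface_threshold``) and a flat
    equilibrated profile.
    """
    y = np.asarray(fractions, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("regime labeling needs at least 4 layers")
    edge_mean = 0.5 * (y[0] + y[-1])
    mid = n // 2
    center = y[mid - 1: mid + 1].mean() if n % 2 == 0 else y[mid]
    u_depth = edge_mean - center
    if u_depth > edge_threshold and u_depth > abs(y[0] - y[-1]):
        return "edge_peaked"
    prof = LayerProfile(n_layers=n, fractions_shade1=np.zeros(n),
                        fractions_shade2=np.clip(y, 0, 1))
    fit = fit_sigmoid(prof, "shade2")
    return "uniform" if fit.interface_free else "sigmoid"
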