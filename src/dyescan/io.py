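"""File formats and run configuration.

Everything the workflow reads or writes is plain text or a standard bitmap:
two-column spectra, CSV weight tables and diffusion traces, PNG/BMP layer
scans, indexed-PNG classification maps, and a key=value run configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .color import Spectrum
from .classify import EXCLUDED, SHADE1, SHADE2, PixelClassMap
from .diffusion import DiffusionTrace
from .profile import LayerProfile

__all__ = [
    "read_spectrum", "read_gelatin_weights", "read_trace_csv",
    "write_trace_csv", "write_profile_csv", "write_classmap_png",
    "write_counts_csv", "RunConfig", "load_config", "config_hash",
    "scan_paths_in",
]

# Indexed-PNG palette for classification maps.
_CLASS_PALETTE = {
    EXCLUDED: (255, 255, 255),   # white
    SHADE1: (49, 54, 149),       # dark blue: gelatin-bound shade
    SHADE2: (116, 173, 209),     # light blue: free-dye shade
}


def read_spectrum(path, mode: str = "emission") -> Spectrum:
    """Read a two-column (wavelength_nm, value) delimited text file.

    The delimiter is sniffed (comma, semicolon, tab or whitespace); a
    single header line is skipped if present.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     header=None, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, value)")
    first = df.iloc[0]
    try:
        float(first.iloc[0]), float(first.iloc[1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    wl = df.iloc[:, 0].astype(float).to_numpy()
    vals = df.iloc[:, 1].astype(float).to_numpy()
    return Spectrum(wavelengths=wl, values=vals, mode=mode)


def read_gelatin_weights(path) -> np.ndarray:
    """Read a (layer_index, weight_g_per_m2) CSV, returned in layer order."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    idx_col = cols.get("layer_index", df.columns[0])
    w_col = cols.get("weight_g_per_m2", df.columns[1])
    df = df.sort_values(idx_col)
    idx = df[idx_col].astype(int).to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError(f"{path}: layer_index must cover 1..{len(idx)}")
    return df[w_col].astype(float).to_numpy()


def read_trace_csv(path, source_c0: float, thickness: float,
                   n_layers: int) -> DiffusionTrace:
    """Read a (time_s, concentration_g_per_dm3) CSV into a trace."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    t_col = cols.get("time_s", df.columns[0])
    c_col = cols.get("concentration_g_per_dm3", df.columns[1])
    return DiffusionTrace(times=df[t_col].astype(float).to_numpy(),
                          concentrations=df[c_col].astype(float).to_numpy(),
                          source_c0=source_c0, thickness=thickness,
                          n_layers=n_layers)


def write_trace_csv(trace: DiffusionTrace, path) -> None:
    pd.DataFrame({
        "time_s": trace.times,
        "concentration_g_per_dm3": trace.concentrations,
    }).to_csv(path, index=False)


def write_profile_csv(profile: LayerProfile, path) -> None:
    data = {
        "layer_index": profile.layer_index,
        "fraction_shade1": profile.fractions_shade1,
        "fraction_shade2": profile.fractions_shade2,
    }
    if profile.gelatin_weight is not None:
        data["gelatin_weight_g_per_m2"] = profile.gelatin_weight
    pd.DataFrame(data).to_csv(path, index=False)


def write_classmap_png(classmap: PixelClassMap, path) -> None:
    """Write a classification map as an indexed PNG.

    Palette: excluded = white, shade 1 = dark blue, shade 2 = light blue.
    """
    img = Image.fromarray(classmap.labels, mode="P")
    palette = [0] * 768
    for code, rgb in _CLASS_PALETTE.items():
        palette[3 * code: 3 * code + 3] = rgb
    img.putpalette(palette)
    img.save(Path(path))


def write_counts_csv(classmaps, path) -> None:
    rows = []
    for cm in classmaps:
        counts = cm.counts
        rows.append({
            "layer_index": cm.layer_index,
            "total_pixels": cm.total,
            "excluded": counts["excluded"],
            "shade1": counts["shade1"],
            "shade2": counts["shade2"],
            "fraction_shade1": counts["shade1"] / cm.total,
            "fraction_shade2": counts["shade2"] / cm.total,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def scan_paths_in(scan_dir) -> list[Path]:
    """Layer scans in a directory, sorted by filename (layer order)."""
    scan_dir = Path(scan_dir)
    paths = sorted(p for p in scan_dir.iterdir()
                   if p.suffix.lower() in (".png", ".bmp")
                   and not p.stem.endswith("_labels")
                   and not p.stem.endswith("_classes"))
    return paths


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    scan_dir: str
    out_dir: str
    weights_file: str | None = None
    trace_file: str | None = None
    gray_tol: int = 20
    white_floor: int = 245
    slope_tol: float = 0.15
    source_c0: float = 0.04
    thickness: float = 1e-3
    n_layers: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not Path(self.scan_dir).is_dir():
            raise FileNotFoundError(f"scan_dir does not exist: {self.scan_dir}")
        for name in ("weights_file", "trace_file"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if not (0 <= self.gray_tol <= 255 and 0 <= self.white_floor <= 255):
            raise ValueError("gray_tol and white_floor must lie in [0, 255]")
        if self.slope_tol <= 0 or self.source_c0 <= 0 or self.thickness <= 0:
            raise ValueError("slope_tol, source_c0 and thickness must be positive")


_CONFIG_FIELDS = {
    "scan_dir": str, "out_dir": str, "weights_file": str, "trace_file": str,
    "gray_tol": int, "white_floor": int, "slope_tol": float,
    "source_c0": float, "thickness": float, "n_layers": int, "seed": int,
}


def load_config(path, **overrides) -> RunConfig:
    """Parse a key=value configuration file; keyword overrides win."""
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in _CONFIG_FIELDS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = _CONFIG_FIELDS[key](val)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full configuration, embedded in run summaries."""
    canonical = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
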