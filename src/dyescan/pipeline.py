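"""End-to-end analysis pipeline: scans -> classification -> profile -> report.

``run_pipeline`` ties the modules into one reproducible run: it classifies
every layer scan, assembles the thickness profile, labels the concentration
regime, correlates bound dye with gelatin weight when weights are supplied,
estimates diffusion coefficients when a trace is supplied, and writes CSVs,
classified PNGs and a machine-readable JSON summary that embeds the full
configuration and its hash, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .classify import (blue_histogram, classify_pixels, fit_two_gaussians,
                       mask_pixels, read_scan)
from .diffusion import two_wave_report, detect_waves, estimate_deff
from .io import (RunConfig, config_hash, read_gelatin_weights, read_trace_csv,
                 scan_paths_in, write_classmap_png, write_counts_csv,
                 write_profile_csv)
from .profile import (build_profile, cluster_pairs, correlate_gelatin,
                      fit_sigmoid, label_regime)

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("dyescan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow described by ``config``.

    Returns the summary dict that is also written to ``out_dir/summary.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("dyescan %s: starting run, config hash %s",
             __version__, config_hash(config))
    for key, value in asdict(config).items():
        log.info("  %s = %r", key, value)

    paths = scan_paths_in(config.scan_dir)
    if not paths:
        raise PipelineError("discover-scans",
                            f"no PNG/BMP scans in {config.scan_dir}")
    n_layers = config.n_layers or len(paths)
    if len(paths) != n_layers:
        raise PipelineError("discover-scans",
                            f"found {len(paths)} scans but n_layers={n_layers}")

    classmaps = []
    mixture_fits = []
    for i, path in enumerate(paths, start=1):
        scan = _stage("read-scan", read_scan, path, i, n_layers)
        mask = _stage("mask-pixels", mask_pixels, scan,
                      config.gray_tol, config.white_floor)
        hist = _stage("blue-histogram", blue_histogram, scan, mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = _stage("deconvolve", fit_two_gaussians, hist)
        cm = _stage("classify", classify_pixels, scan, mask, fit)
        classmaps.append(cm)
        mixture_fits.append(fit)
        write_classmap_png(cm, out_dir / f"{path.stem}_classes.png")
        log.info("layer %d/%d: %s", i, n_layers, cm.counts)

    weights = None
    if config.weights_file:
        weights = _stage("read-weights", read_gelatin_weights,
                         config.weights_file)
    profile = _stage("build-profile", build_profile, classmaps, weights)
    write_counts_csv(classmaps, out_dir / "counts.csv")
    write_profile_csv(profile, out_dir / "profile.csv")

    summary: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config_hash(config),
        "n_layers": n_layers,
        "layers": [
            {"layer_index": cm.layer_index, **cm.counts,
             "mixture": {"mu1": f.mu1, "mu2": f.mu2, "sigma1": f.sigma1,
                         "sigma2": f.sigma2, "w1": f.w1,
                         "degenerate": f.degenerate}}
            for cm, f in zip(classmaps, mixture_fits)
        ],
    }

    if n_layers >= 4:
        regime2 = _stage("label-regime", label_regime, profile.fractions_shade2)
        summary["regime_shade2"] = regime2
        summary["regime_shade1"] = _stage("label-regime", label_regime,
                                          profile.fractions_shade1)
        fit2 = _stage("fit-sigmoid", fit_sigmoid, profile, "shade2")
        summary["sigmoid_shade2"] = {
            "lower": fit2.lower, "upper": fit2.upper,
            "midpoint": fit2.midpoint, "steepness": fit2.steepness,
            "rss": fit2.rss, "interface_free": fit2.interface_free,
        }

    if weights is not None:
        corr = _stage("correlate-gelatin", correlate_gelatin, profile)
        summary["gelatin_correlation"] = {
            "r": corr.r, "n": corr.n, "slope": corr.slope,
            "intercept": corr.intercept,
        }
        if n_layers >= 6:
            clusters = _stage("cluster-pairs", cluster_pairs, [profile])
            summary["clusters"] = {
                "labels": list(clusters.labels),
                "centroid_main": list(clusters.centroid_main),
                "centroid_outlier": list(clusters.centroid_outlier),
            }

    if config.trace_file:
        trace = _stage("read-trace", read_trace_csv, config.trace_file,
                       config.source_c0, config.thickness, n_layers)
        seg = _stage("detect-waves", detect_waves, trace, config.slope_tol)
        waves = {"wave1": list(seg.wave1),
                 "plateau": list(seg.plateau) if seg.plateau else None,
                 "wave2": list(seg.wave2) if seg.wave2 else None}
        if seg.wave2 is not None:
            rep = _stage("estimate-deff", two_wave_report, trace,
                         config.slope_tol)
            waves["first_wave"] = _deff_dict(rep.first)
            waves["second_wave"] = _deff_dict(rep.second)
        else:
            est = _stage("estimate-deff", estimate_deff, trace, seg.wave1)
            waves["first_wave"] = _deff_dict(est)
        summary["diffusion"] = waves

    out = out_dir / "summary.json"
    out.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("summary written to %s", out)
    return summary


def _deff_dict(est) -> dict:
    return {"deff": est.deff, "deff_per_layer": est.deff_per_layer,
            "dndt": est.dndt, "delta_c": est.delta_c, "wave": est.wave}
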