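# dyescan

Flatbed-scan colorimetry as a surrogate for UV-VIS spectroscopy: image
analysis of methylene-blue diffusion and gelatin binding in layered
polypropylene-nonwoven membranes.

## The problem

Methylene blue (MB) exists in two resonance states with distinct visible
spectra: the free, solvated form and a form hydrogen-bonded to a
macromolecule such as gelatin. In an 8-bit RGB scan of a dried membrane
layer the two states appear as two distinct blue shades, so an office
scanner can answer a question that normally needs a spectrometer: *where in
the membrane is the dye, and is it bound to the gelatin or not?*

`dyescan` implements the full workflow for membranes built from stacked
nonwoven-fabric layers glued with gelatin hydrogel and loaded with MB in a
side-by-side diffusion cell:

* **Color science** — spectra are integrated against the CIE 1931 2°
  color-matching functions; sRGB, CIELAB (L\*, a\*, b\*) and LCh (lightness,
  chroma C = √(a² + b²), hue h = atan2(b, a)) conversions identify the two
  resonance-state colors.
* **Pixel classification** — achromatic scanner noise (the diagonal of a
  two-channel histogram) is rejected, the blue-channel histogram of the
  remaining blue-dominant pixels is deconvolved as a two-Gaussian mixture
  (the two shades), and each pixel is assigned by maximum posterior.
* **Layer profiles** — per-layer blue-pixel area fractions form a profile
  across the membrane thickness; a 4-parameter logistic captures the
  diffusion interface of unbound dye, Pearson correlation ties the bound-dye
  fraction to gelatin weight per area, and 2-means clustering separates the
  main (weight, fraction) cloud from outliers.
* **Diffusion kinetics** — receiving-cell concentration traces rise in two
  waves (free dye, then dye released from the gelatin). Each wave's
  effective diffusion coefficient follows the quasi-steady relation

  *D*<sub>eff</sub> = (d*n*/d*t*) · *l* / Δ*c*

  with d*n*/d*t* the least-squares concentration slope over the wave,
  *l* the membrane thickness and Δ*c* the source–receiving difference at
  the segment midpoint; dividing by the layer count recalculates the
  coefficient per single layer.
* **Synthetic data** — seeded generators produce layer scans (two shade
  populations, white melted-polymer squares, achromatic noise) and two-wave
  traces with exact ground truth, so every step is testable without the
  original scans.

## Worked example

Convert the scanner color of freely solvated MB to CIELAB and LCh:

```sh
$ dyescan convert --from srgb8 --to lab -- 0 145 248
{"l": 58.99691332918417, "a": 5.673291127900715, "b": -60.16775958419127}
$ dyescan convert --from lab --to lch -- 59 5.6 -60
{"l": 59.0, "c": 60.260766672852746, "h": 275.33215888165955}
```

L\* ≈ 59 with b\* ≈ −60 (strongly blue); in cylindrical form chroma 60 at a
hue angle of 275° — a saturated blue. The gelatin-bound shade
([81, 91, 121]) converts to L\* ≈ 39: darker, as bound dye appears in scans.

Simulate a 16-layer membrane with a sigmoidal unbound-dye interface and
analyze it end to end:

```sh
$ dyescan simulate --out sim --n-layers 16 --mode sigmoid --seed 7
$ dyescan run --scans sim --weights sim/gelatin_weights.csv \
              --trace sim/trace.csv --out results
$ python -m json.tool results/summary.json | grep -E 'regime|"r"'
    "regime_shade1": "edge_peaked",
    "regime_shade2": "sigmoid",
        "r": 0.9057373830817111,
```

The run recovers the planted structure: the unbound (light) shade follows a
sigmoid across the stack (`regime_shade2`), the bound (dark) shade peaks at
both edges where the gelatin accumulates (`regime_shade1`), and the bound
fraction correlates with gelatin weight per area (r ≈ 0.91). From the
simulated trace the first-wave coefficient comes back as
27.0 × 10⁻⁹ m² s⁻¹ per layer against a generating value of 26 × 10⁻⁹,
and the slower second wave (release of gelatin-bound dye) yields
21.4 × 10⁻⁹ m² s⁻¹ for the whole membrane. `results/` also contains
`profile.csv` (per-layer fractions and weights), `counts.csv` and a
classified PNG per layer.

## Layout

| module | contents |
| --- | --- |
| `dyescan.color` | spectra, XYZ/sRGB/CIELAB/LCh conversions |
| `dyescan.classify` | scan I/O, masking, histograms, mixture deconvolution, shade assignment |
| `dyescan.profile` | thickness profiles, sigmoid interface, correlation, clustering |
| `dyescan.diffusion` | wave segmentation and D_eff estimation |
| `dyescan.synthetic` | seeded generators with ground truth |
| `dyescan.io` / `dyescan.pipeline` / `dyescan.cli` | formats, end-to-end runs, `dyescan` command |

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
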