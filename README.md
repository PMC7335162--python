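# foramxrf

Nano-XRF trace-metal analysis of planktic foraminifer chamber walls.

Planktic foraminifers build their calcite tests layer by layer — inner
calcitic layer (ICL), Ca-poor primary organic zone (POZ), outer
calcitic layer (OCL) and a final gametogenic crust (GC) — and trace
metals such as Mn and Zn taken up from seawater are imprinted on this
growth sequence at the sub-micrometre scale. Synchrotron X-ray
fluorescence maps of wall cross sections resolve these imprints as
layered contrasts and alternating nano-bands. `foramxrf` provides the
quantitative toolchain for such maps, for analysts working with fitted
XRF line-count images:

* **synthetic walls** — parametric ICL–POZ–OCL–GC models with
  element-specific layer contrasts and raised-cosine nano-banding,
  rendered into Poisson count maps through a Gaussian beam PSF;
* **profiles and ratios** — width-averaged cross-wall profiles with
  Poisson error bars, σ(S_X/S_Y) = (S_X/S_Y)·√((σ_X/S_X)² + (σ_Y/S_Y)²);
* **nano-band detection** — the finite-difference second derivative
  (S_X/S_Y)″ = [r(x+Δx) − 2r(x) + r(x−Δx)]/Δx² with exact (√6·σ/Δx²)
  or factor-of-two propagated thresholds, bands delimited by zero
  crossings and flagged when their extremum clears the threshold;
* **layer analysis** — Ca-profile segmentation of the four layers,
  per-layer enrichment statistics, Zn/Ca-vs-Mn/Ca regression and
  growth trajectories;
* **semi-quantification** — fundamental-parameter inversion
  c_i = S_i·A_i/(σ_i·ε_i) with Beer–Lambert self-absorption
  corrections for thick sections (A = 1 − e^(−χ) full path,
  A = 1 − (1 − e^(−χ′))/χ′ depth-averaged grazing exit), backed by an
  embedded mass-attenuation table for a porous calcite matrix.

## Worked example

Run the full pipeline on the default fossil-specimen preset (a 15 µm
wall mapped at 60 nm pixels, 3 s dwell):

```sh
$ foramxrf run-all --seed 42 --out demo
INFO foramxrf: rendered 7 element maps (250 x 41 px)
INFO foramxrf: detected 101 candidate bands (53 significant)
slope Zn/Ca vs Mn/Ca: 0.1902
bulk Mn enrichment: 7.48
summary: demo/summary.json
```

`demo/` then holds the rendered map stack (`maps.tif` + JSON sidecar),
the averaged profiles, the Mn/Ca band table, the segmentation, layer
statistics, correlation and quantification reports, and a summary.
From `demo/summary.json` for this seed:

* layer boundaries at 3000, 4260 and 10170 nm (generator truth 3000,
  4250, 10250) and a recovered POZ width of 1260 nm — the Ca-poor
  precursor zone is found to within ~1 pixel;
* Mn enrichment relative to the POZ: ICL 0.42, OCL 0.21, GC 0.05 —
  the outward Mn depletion of the calcitic layers;
* Zn/Ca vs Mn/Ca slope 0.1902 (95 % CI 0.1898–0.1906, Pearson
  ρ = 0.9999), recovering the proportionality encoded in the
  generator, with wall-mean Mn/Ca 5.26× wall-mean Zn/Ca;
* bulk Mn counts 7.48 ± 0.03 times higher in the fossil than in the
  modern preset;
* matrix-corrected bulk Mn/Ca of (7.62 ± 0.07)·10⁻⁴ over three
  synthetic specimens against the calibrated 7.66·10⁻⁴.

The absorption case study alone:

```sh
$ foramxrf quantify --thickness 10 --out demo
Ca K-alpha: 23.5% absorbed (normal full path)
Mn K-alpha: 32.4% absorbed (normal full path)
Zn K-alpha: 12.8% absorbed (normal full path)
```

The same calls are available as a library
(`foramxrf.run_pipeline(RunConfig(seed=42), "demo")`, or the
individual functions `render_element_maps`, `extract_profile`,
`second_derivative`, `segment_wall`, `quantify_ratio`, ...). Models,
acquisition and analysis settings are configurable through
`RunConfig`/YAML; see `docs/methods.md` for the model details and
defaults.

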