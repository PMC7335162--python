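# Methods

`foramxrf` analyses synchrotron X-ray fluorescence (XRF) count maps of
planktic foraminifer chamber walls: it simulates layered walls with
realistic counting noise, extracts averaged cross-wall profiles,
propagates Poisson uncertainties into elemental ratios, detects
sub-micrometre trace-metal bands with a second-derivative statistic,
segments the wall growth layers, and semi-quantifies elemental ratios
with a Beer–Lambert matrix correction. This note records the models,
the defaults and why, the numerical choices, and what the synthetic
generator does and does not emulate.

## The wall model

A chamber wall is an ordered stack of four growth layers crossed from
the inner to the outer surface: the inner calcitic layer (ICL), the
Ca-poor primary organic zone (POZ, hosting the thin primary organic
sheet), the outer calcitic layer (OCL, thicker than the ICL), and the
gametogenic crust (GC, a homogeneous final calcite layer). Each layer
carries a relative concentration per element, normalised so the POZ is
1 for every element; the absolute specimen-level abundance and the
instrument sensitivity are folded into one per-element count scale
(`bulk_scale`, counts·s⁻¹ per pixel at unit relative concentration).

Default relative levels (fossil "YTT" preset):

| element | ICL | POZ | OCL | GC |
|---|---|---|---|---|
| Ca | 1.2 | 1.0 | 1.5 | 1.5 |
| Sr | 1.2 | 1.0 | 1.05 | 1.05 |
| Mn, Zn | 0.4 | 1.0 | 0.2 | 0.05 |
| Mg, S | 1.0 | 1.0 | 1.0 | 0.8 |
| P | 0.5 | 1.0 | 0.3 | 0.1 |

These encode the observed contrasts: the POZ is Ca-poor and the most
Mn-, Zn-, P- and S-enriched zone; Ca rises ~20 % in the ICL and ~50 %
in the OCL and GC relative to the POZ; Mn falls to 40 % (ICL), 20 %
(OCL) and to a few per cent in the crust; Sr tracks Ca with Sr/Ca
reduced ~30 % in the OCL and GC. The GC Mn level (0.05) is a choice —
only "lowest contents" is reported. Layer thicknesses: YTT preset
ICL 3 µm, POZ 1.25 µm, OCL 6 µm, GC 4.75 µm (total 15 µm); modern
preset ICL 1.3 µm, POZ 0.7 µm, OCL 2.6 µm, GC 0.4 µm (total 5 µm).
Only the POZ width and the totals are reported quantities; the splits
are chosen to respect OCL > ICL and are fully configurable.

**Nano-banding.** Banding is a train of raised-cosine bands anchored
flush with each banded layer's distal edge (far from the POZ) and
repeating towards the POZ. All band trains share one centre grid per
layer: "in phase with Ca" means depletion at the centres (the thin
Ca-poor bands themselves, amplitude 0.15, width 300 nm, period 1 µm);
"anti-phase" means enrichment at the same centres, which is how the
Mn and Zn bands oppose the Ca pattern (amplitude 0.5 at the POZ,
decaying linearly to 0.2 at the wall surfaces — the decay law is a
package choice, only a decreasing trend is observed). Mg and S band
with equal amplitude everywhere (width 400 nm, period 2 µm: thin
high-Mg bands separated by ~2 µm low-Mg stretches). Anchoring the
outermost band at the OCL/GC boundary is a package choice (no band
registration is reported); it also makes that boundary recoverable by
the homogeneity rule below.

**Rendering.** Expected counts per pixel are
`bulk_scale × dwell × field`, convolved with an isotropic-separable
Gaussian PSF parameterised by the beam FWHM pair (55 × 60 nm), sampled
at pixel centres (60 nm pixels, 3 s dwell by default), and drawn
independently per pixel from a Poisson law — the correct noise model
for fitted line counts ("error bars are the square root of the raw
counts"). Each element uses an independent substream of the single
acquisition seed, so renders are exactly reproducible. `bulk_scale`
defaults put ~2500 Mn counts in a POZ pixel at 3 s dwell, i.e. a ~2 %
relative Mn and Mn/Ca uncertainty, matching the reported error scale;
Zn's scale is 0.19 × Mn's, which encodes the observed Zn/Ca ≈ 0.19
Mn/Ca proportionality exactly at the expectation level.

**Bulk counts.** Bulk analyses are average-spectrum comparisons: many
pixel spectra are compiled and the fitted counts compared per
spectrum. `render_bulk_counts` therefore draws Poisson totals around
`bulk_scale × dwell × wall-mean concentration × n_spectra`
(n_spectra = 1000 by default), not around the depth integral — walls
of different thickness are compared per spectrum. The modern preset's
Mn sensitivity is calibrated so the expected YTT/modern bulk Mn count
ratio is exactly 7.5, the centre of the reported 5–10× enrichment of
the fossil specimens.

## Profiles and ratio statistics

Profiles are extracted along grid-aligned axes, averaging an odd-width
rectangle (21 pixels by default, the field protocol): counts are the
across-width sum divided by the width (per-pixel units, comparable
across widths), and sigma is sqrt(summed raw counts)/width. A zero
summed count keeps a floor of one raw count so error bars never
vanish. Ratio traces X/Y carry the first-order propagated sigma
`(X/Y)·sqrt((σX/X)² + (σY/Y)²)`; zero-denominator positions are masked
to NaN and counted. Whether the field protocol averages or sums across
the rectangle is not stated; the mean is adopted.

## Band detection

The banding statistic is the three-point central-difference second
derivative of a ratio trace. Its uncertainty is available as

* `exact_sqrt6` (default): exact propagation of the stencil,
  `sqrt(σ²(x−Δx) + 4σ²(x) + σ²(x+Δx))/Δx²` → `sqrt(6)·σ/Δx²` for flat
  σ; verified against Monte-Carlo to 3 %;
* `paper_factor2`: the operational factor-of-two rule `2σ/Δx²`. The
  published relative-error statement equates the second derivative's
  relative uncertainty to twice the ratio's, which is dimensionally
  inconsistent with the stencil; its usual operational reading
  underestimates the exact propagation by 2/sqrt(6) ≈ 0.816. Both are
  selectable.

The detection threshold is a constant — a configurable multiplier
(default 1) of the profile-median sigma — reproducing the
horizontal-dashed-line convention; how the published threshold was
aggregated along the profile is not stated, the median is adopted, and
a pointwise variant sits behind a flag. Bands are the segments between
linearly interpolated zero crossings of the second derivative;
crossings closer than one pixel are merged (noise hysteresis) and
same-sign neighbours coalesced, so consecutive bands alternate sign.
A negative extremum marks a local ratio maximum (enrichment band). A
band is significant when |extremum| exceeds the threshold. Segments
touching the profile ends lack a delimiting crossing and are not
reported. Note two structural properties: (i) for a raised-cosine
band of width w the enriched curvature lobe spans w/2, so detected
widths are narrower than the generator's nominal band width; (ii) the
constant threshold controls the per-point false-positive rate, so the
probability that a pure-noise profile is entirely clean decays with
its length (≈96 % for 16-point profiles at a 3σ threshold, ≈77 % at
100 points). Optional moving-average pre-smoothing is off by default
(none is reported).

## Layer segmentation

Segmentation uses the Ca profile only, with the orientation (inner
surface first) declared by the caller — auto-detection is refused to
avoid silent flips. The POZ is the contiguous region around the global
Ca minimum below the midpoint between that minimum and each side's
flanking median, with the crossings linearly interpolated (robust to
PSF blur, lands at the half-height of the blurred step). The OCL/GC
boundary exploits the crust's homogeneity: the rolling SD (10-pixel
window) of the Ca profile is thresholded at half the ICL rolling-SD
median — the ICL is used because it is the region known to be banded
once the POZ is found — and the boundary is the outermost position
where the rolling SD rises above threshold, corrected by half a window
so it lands at the outermost banded feature. The published OCL/GC
criterion is qualitative (a sharp boundary visible in electron
micrographs); this rule is a parameter-light stand-in validated
against generator ground truth (boundaries recovered within 2 pixels).

Per-layer statistics are means, SDs and POZ-relative enrichments of
any set of count and ratio traces; empty layers are reported as NaN.
Cross-element relations use ordinary least squares with free intercept
(only "linear fit" is published) plus the Pearson correlation, with a
95 % CI on the slope from the t distribution. The "up to 20 %/50 %"
Ca increases are treated as layer means, and the Mn 40 %/20 % figures
as relative to the POZ mean (maxima vs means is not stated).

## Semi-quantification and matrix correction

Thin sections invert counts through the fundamental-parameter relation
c_i ∝ S_i·A_i/(σ_i·ε_i). Defaults are relative values: σ_i is the
photoionisation mass coefficient at the incident energy (17.4 keV)
times the K fluorescence yield, ε_i = 1; only ratios are claimed.

Self-absorption uses Beer–Lambert with χ = (μ/ρ)·ρ_eff·t for a porous
calcite matrix (CaCO₃, solid density 2.71 g·cm⁻³, porosity 0.15,
ρ_eff ≈ 2.30 g·cm⁻³). Two geometries are implemented:

* `normal_full_path`: A = 1 − e^(−χ). This reproduces the published
  10 µm-slab case study — Ca/Mn/Zn Kα absorbed fractions of
  23.5/32.4/12.8 % computed vs 24.8/33.3/13.2 % printed (−3 to −5 %
  relative, inside the attenuation-tabulation tolerance) — and is the
  geometry the case-study numbers are reported in.
* `grazing_depth_averaged`: A = 1 − (1 − e^(−χ'))/χ' with
  χ' = χ/sin(17°), i.e. emission uniformly distributed in depth
  exiting along the grazing path. This is the physically appropriate
  transmission for the detection geometry and is what `quantify_ratio`
  divides counts by before inverting; one fixed-point refinement folds
  the recovered trace fractions back into the matrix (negligible at
  trace level). Incident-beam attenuation at 17.4 keV (χ ≈ 0.04 at
  10 µm) is off by default, switchable on.

The round trip — forward-simulate slab counts at ≥10⁶ Ca counts, then
invert — recovers Mn/Ca and Mn/Zn to well under the published 4 %
validity bound. Secondary enhancement (e.g. Mn excited by Ca
fluorescence) is not modelled.

**Attenuation data.** Mass attenuation coefficients ship as a small
embedded CSV (C, O, Mg, P, S, Ca, Mn, Zn, Sr on a 1.5–20 keV log grid
with K edges bracketed, log-log interpolated), generated from
Cromer–Liberman anomalous scattering factors via
μ/ρ = 2 r_e λ f″ N_A/A (`scripts/make_attenuation_table.py`). These
are photoelectric coefficients; coherent/incoherent scattering (<2 %
of the total for calcite below 10 keV) is neglected. The table is an
input and can be replaced by any other tabulation.

**Bulk composition.** The default fossil specimen composition is
calibrated to the reference bulk conventions Mn/Ca = 7.66·10⁻⁴ and
Mn/Zn = 15.85 on the package's wt-ratio scale, with Ca at the calcite
stoichiometric mass fraction (0.4004). Three-specimen bulk
semi-quantification draws Poisson-only replicates around this
composition.

## What the generator does not emulate

Passing recovery tests show the pipeline is consistent with its own
forward model under Poisson noise; they do not validate against real
walls. Not emulated: pores (used only for orienting fragments),
diagenetic coatings and surface contamination, spectral-fitting
residuals and line interferences (Cu/Ni/Co pile-up), detector response
beyond a scalar efficiency, irregular band spacing and curvature of
real growth surfaces, specimen-to-specimen compositional scatter (the
reported ~40 % SD across fossil specimens; synthetic replicates vary
only by counting noise), and secondary fluorescence enhancement.
Published specimen-specific values (e.g. ρ = 0.975 between Zn/Ca and
Mn/Ca on real maps) enter only as generator parameters with recovery
tests.

## Problem sizes and determinism

Default analyses run on one 250 × 41 px map stack (a 15 µm wall at
60 nm pixels) with seven element channels; Monte-Carlo checks use
10⁵ replicates, renderer checks 200 seeds of a thin wall. A full
pipeline run takes well under a second. Every stochastic stage derives
its stream from the single run seed via spawned substreams; repeated
runs of one config are byte-identical, and all writers (TIFF + JSON
sidecar, CSV) are deterministic.
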