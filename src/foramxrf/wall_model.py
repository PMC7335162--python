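"""Parametric layered-wall models and synthetic nano-XRF map rendering.

The chamber wall of a planktic foraminifer test is modelled as an ordered
stack of four layers crossed from the inner to the outer surface:

* ICL  -- inner calcitic layer,
* POZ  -- primary organic zone, the Ca-poor precursor layer hosting the
          primary organic sheet (POS),
* OCL  -- outer calcitic layer (thicker than the ICL),
* GC   -- gametogenic crust, a homogeneous final calcite layer.

Each layer carries a relative concentration (dimensionless, POZ = 1 for
every element) and sub-micrometre banding is superposed on the calcitic
layers as trains of raised-cosine bands. Mn and Zn bands sit at the
positions of the thin Ca-poor bands (opposite phase to the Ca pattern)
with amplitudes that decay linearly away from the POZ; Mg and S band with
equal amplitude throughout the calcitic layers.

Rendering converts the continuous concentration field into expected
fluorescence counts per pixel (sensitivity x dwell time x PSF-convolved
field) and draws independent Poisson counts, the noise model appropriate
for fitted XRF line counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

LAYER_ORDER = ("ICL", "POZ", "OCL", "GC")

#: phase tags for banding relative to the Ca-poor band grid
IN_PHASE = "in_phase_with_Ca"
ANTI_PHASE = "anti_phase_with_Ca"

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Expected per-pixel counts above this are rejected as unphysical for a
# fitted-line map (and would degrade Poisson sampling accuracy).
_MAX_EXPECTED = 1e12


class WallModelError(ValueError):
    """Invalid wall-model or acquisition input."""


@dataclass(frozen=True)
class LayerSpec:
    """One wall layer: name, thickness (nm), per-element relative level."""

    name: str
    thickness: float
    concentration_scale: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.name not in LAYER_ORDER:
            raise WallModelError(f"unknown layer name {self.name!r}")
        if not self.thickness > 0:
            raise WallModelError(f"layer {self.name}: thickness must be > 0")
        for el, c in self.concentration_scale.items():
            if c < 0:
                raise WallModelError(f"layer {self.name}: {el} scale < 0")


@dataclass(frozen=True)
class BandingSpec:
    """A periodic train of raised-cosine bands for one element.

    Band centres are anchored flush with each banded layer's distal edge
    (the edge far from the POZ) and repeat with ``band_period`` towards
    the POZ. ``phase`` selects the sign of the modulation on the shared
    band grid: ``in_phase_with_Ca`` produces depletion bands (the Ca-poor
    pattern itself), ``anti_phase_with_Ca`` enrichment bands at the same
    positions. ``taper_distal`` is the relative amplitude remaining at
    the wall surface on each side of the POZ (1 = no decay).
    """

    element: str
    band_width: float
    band_period: float
    amplitude_profile: Mapping[str, float]
    phase: str = ANTI_PHASE
    taper_distal: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.band_width < self.band_period:
            raise WallModelError("need 0 < band_width < band_period")
        if self.phase not in (IN_PHASE, ANTI_PHASE):
            raise WallModelError(f"unknown banding phase {self.phase!r}")
        if any(a < 0 for a in self.amplitude_profile.values()):
            raise WallModelError("banding amplitudes must be >= 0")
        if not 0 <= self.taper_distal <= 1:
            raise WallModelError("taper_distal must be in [0, 1]")


@dataclass(frozen=True)
class WallModel:
    """Ordered ICL-POZ-OCL-GC layer stack with banding and count scales.

    ``bulk_scale`` maps element -> expected count rate (counts/s) per
    pixel at unit relative concentration; it carries both instrument
    sensitivity and the specimen's absolute element abundance.
    ``pos_position`` locates the primary organic sheet inside the POZ
    (nm from the POZ inner edge).
    """

    layers: Sequence[LayerSpec]
    bandings: Sequence[BandingSpec] = ()
    pos_position: float = 0.0
    bulk_scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(layer.name for layer in self.layers)
        if names != LAYER_ORDER:
            raise WallModelError(
                f"layer order must be {LAYER_ORDER}, got {names}"
            )
        icl, _, ocl, _ = self.layers
        if not ocl.thickness > icl.thickness:
            raise WallModelError("OCL must be thicker than the ICL")
        poz = self.layers[1]
        if not 0 <= self.pos_position <= poz.thickness:
            raise WallModelError("pos_position must lie inside the POZ")
        for el, s in self.bulk_scale.items():
            if s < 0:
                raise WallModelError(f"bulk_scale[{el!r}] must be >= 0")

    @property
    def total_thickness(self) -> float:
        return float(sum(layer.thickness for layer in self.layers))

    @property
    def layer_edges(self) -> np.ndarray:
        """Cumulative layer boundaries [0, e1, e2, e3, total] in nm."""
        return np.concatenate(
            ([0.0], np.cumsum([layer.thickness for layer in self.layers]))
        )

    def layer_interval(self, name: str) -> tuple[float, float]:
        i = LAYER_ORDER.index(name)
        edges = self.layer_edges
        return float(edges[i]), float(edges[i + 1])

    @property
    def elements(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for layer in self.layers:
            for el in layer.concentration_scale:
                seen.setdefault(el)
        return tuple(seen)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scan geometry and counting settings for map rendering."""

    pixel_size: float = 60.0          # nm
    dwell_time: float = 3.0           # s
    psf_fwhm: tuple[float, float] = (55.0, 60.0)  # (horizontal, vertical) nm
    excitation_energy: float = 17.4   # keV
    map_extent: tuple[int, int] = (250, 41)       # (width, height) px
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise WallModelError("pixel_size must be > 0")
        if not self.dwell_time > 0:
            raise WallModelError("dwell_time must be > 0")
        if not (self.psf_fwhm[0] > 0 and self.psf_fwhm[1] > 0):
            raise WallModelError("PSF FWHMs must be > 0")
        w, h = self.map_extent
        if w < 1 or h < 1:
            raise WallModelError("map_extent must be >= 1 px in each axis")


def default_acquisition(model: WallModel, height: int = 41, seed: int = 0,
                        pixel_size: float = 60.0,
                        dwell_time: float = 3.0) -> AcquisitionSpec:
    """Acquisition whose width spans the full wall at the given pixel size."""
    width = int(round(model.total_thickness / pixel_size))
    return AcquisitionSpec(pixel_size=pixel_size, dwell_time=dwell_time,
                           map_extent=(width, height), seed=seed)


# ---------------------------------------------------------------------------
# presets

def _mirror(d: Mapping[str, float]) -> dict[str, float]:
    return dict(d)


def _ytt_layers() -> list[LayerSpec]:
    scales = {
        "ICL": {"Ca": 1.2, "Sr": 1.2, "Mn": 0.4, "Zn": 0.4,
                "Mg": 1.0, "S": 1.0, "P": 0.5},
        "POZ": {"Ca": 1.0, "Sr": 1.0, "Mn": 1.0, "Zn": 1.0,
                "Mg": 1.0, "S": 1.0, "P": 1.0},
        "OCL": {"Ca": 1.5, "Sr": 1.05, "Mn": 0.2, "Zn": 0.2,
                "Mg": 1.0, "S": 1.0, "P": 0.3},
        "GC": {"Ca": 1.5, "Sr": 1.05, "Mn": 0.05, "Zn": 0.05,
               "Mg": 0.8, "S": 0.8, "P": 0.1},
    }
    thick = {"ICL": 3000.0, "POZ": 1250.0, "OCL": 6000.0, "GC": 4750.0}
    return [LayerSpec(n, thick[n], _mirror(scales[n])) for n in LAYER_ORDER]


def _modern_layers() -> list[LayerSpec]:
    ytt = {layer.name: layer for layer in _ytt_layers()}
    thick = {"ICL": 1300.0, "POZ": 700.0, "OCL": 2600.0, "GC": 400.0}
    return [
        LayerSpec(n, thick[n], _mirror(ytt[n].concentration_scale))
        for n in LAYER_ORDER
    ]


def _default_bandings() -> list[BandingSpec]:
    ca_amp = {"ICL": 0.15, "OCL": 0.15}
    mn_amp = {"ICL": 0.5, "OCL": 0.5}
    mg_amp = {"ICL": 1.0, "OCL": 1.0}
    return [
        BandingSpec("Ca", 300.0, 1000.0, dict(ca_amp), IN_PHASE),
        BandingSpec("Sr", 300.0, 1000.0, dict(ca_amp), IN_PHASE),
        BandingSpec("Mn", 300.0, 1000.0, dict(mn_amp), ANTI_PHASE,
                    taper_distal=0.2),
        BandingSpec("Zn", 300.0, 1000.0, dict(mn_amp), ANTI_PHASE,
                    taper_distal=0.2),
        BandingSpec("Mg", 400.0, 2000.0, dict(mg_amp), ANTI_PHASE),
        BandingSpec("S", 400.0, 2000.0, dict(mg_amp), ANTI_PHASE),
    ]


#: expected count rate per pixel at unit relative concentration (counts/s),
#: calibrated so a POZ Mn pixel at 3 s dwell collects ~2500 counts
#: (relative Mn and Mn/Ca uncertainty ~2%) and Zn/Ca = 0.19 * Mn/Ca.
_YTT_BULK_SCALE = {
    "Ca": 333333.3, "Sr": 33333.3, "Mn": 833.33, "Zn": 0.19 * 833.33,
    "Mg": 1000.0, "S": 800.0, "P": 600.0,
}

#: expected bulk Mn count enrichment of the YTT preset over the modern one
YTT_TO_MODERN_BULK_MN = 7.5


def default_wall_model(kind: str) -> WallModel:
    """Preset wall models for the fossil (YTT) and living (modern) cases.

    YTT: 15 um wall, 1250 nm POZ. modern: 5 um wall, 700 nm POZ, and a
    bulk Mn sensitivity calibrated so the expected bulk Mn count
    enrichment YTT/modern is exactly ``YTT_TO_MODERN_BULK_MN`` (the
    relative concentration fields are POZ-normalised, so the absolute
    specimen-level Mn difference lives in ``bulk_scale``).
    """
    if kind == "YTT":
        return WallModel(
            layers=_ytt_layers(),
            bandings=_default_bandings(),
            pos_position=600.0,
            bulk_scale=dict(_YTT_BULK_SCALE),
        )
    if kind == "modern":
        ytt = default_wall_model("YTT")
        modern = WallModel(
            layers=_modern_layers(),
            bandings=_default_bandings(),
            pos_position=350.0,
            bulk_scale=dict(_YTT_BULK_SCALE),
        )
        ratio = (_mean_concentration(ytt, "Mn")
                 / _mean_concentration(modern, "Mn"))
        mn_scale = (_YTT_BULK_SCALE["Mn"] * ratio / YTT_TO_MODERN_BULK_MN)
        scale = dict(_YTT_BULK_SCALE)
        scale["Mn"] = mn_scale
        scale["Zn"] = 0.19 * mn_scale
        return replace(modern, bulk_scale=scale)
    raise WallModelError(f"unknown preset kind {kind!r}; use 'YTT' or 'modern'")


# ---------------------------------------------------------------------------
# concentration fields

def _band_modulation(model: WallModel, element: str,
                     x: np.ndarray) -> np.ndarray:
    """Signed banding modulation (dimensionless) at positions x."""
    mod = np.zeros_like(x, dtype=float)
    edges = model.layer_edges
    poz_lo, poz_hi = model.layer_interval("POZ")
    total = model.total_thickness
    for spec in model.bandings:
        if spec.element != element:
            continue
        sign = -1.0 if spec.phase == IN_PHASE else 1.0
        w, period = spec.band_width, spec.band_period
        for i, name in enumerate(LAYER_ORDER):
            amp = spec.amplitude_profile.get(name, 0.0)
            if amp == 0.0:
                continue
            lo, hi = float(edges[i]), float(edges[i + 1])
            inner_side = hi <= poz_lo  # layer lies between x=0 and the POZ
            distal = lo if inner_side else hi
            # band centres flush with the distal edge, marching toward POZ
            n_bands = int((hi - lo - w) // period) + 1
            if n_bands < 1:
                continue
            ks = np.arange(n_bands)
            centres = (distal + (w / 2 + ks * period)) if inner_side \
                else (distal - (w / 2 + ks * period))
            in_layer = (x >= lo) & (x < hi)
            if not np.any(in_layer):
                continue
            xi = x[in_layer]
            bump = np.zeros_like(xi)
            for c in centres:
                u = xi - c
                sel = np.abs(u) < w / 2
                bump[sel] += 0.5 * (1.0 + np.cos(2.0 * np.pi * u[sel] / w))
            # linear amplitude decay with distance from the POZ
            if spec.taper_distal < 1.0:
                if inner_side:
                    d = poz_lo - xi
                    span = poz_lo
                else:
                    d = xi - poz_hi
                    span = total - poz_hi
                fac = 1.0 - (1.0 - spec.taper_distal) * d / span
            else:
                fac = 1.0
            mod[in_layer] += sign * amp * fac * bump
    return mod


def _field(model: WallModel, element: str, x: np.ndarray) -> np.ndarray:
    """Relative concentration at positions x; 0 outside the wall."""
    x = np.asarray(x, dtype=float)
    edges = model.layer_edges
    out = np.zeros_like(x)
    inside = (x >= 0) & (x <= edges[-1])
    idx = np.clip(np.searchsorted(edges, x[inside], side="right") - 1, 0,
                  len(LAYER_ORDER) - 1)
    base = np.array([
        model.layers[i].concentration_scale.get(element, 0.0) for i in idx
    ])
    out[inside] = base * (1.0 + _band_modulation(model, element, x[inside]))
    return np.clip(out, 0.0, None)


def concentration_profile(model: WallModel, element: str,
                          positions: np.ndarray) -> np.ndarray:
    """Deterministic relative concentration of ``element`` at ``positions``.

    Positions are nm from the inner wall surface and must lie inside
    [0, total thickness].
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size and (positions.min() < 0
                           or positions.max() > model.total_thickness):
        raise WallModelError("positions outside [0, total thickness]")
    return _field(model, element, positions)


def _pixel_centers(acq: AcquisitionSpec) -> np.ndarray:
    width = acq.map_extent[0]
    return (np.arange(width) + 0.5) * acq.pixel_size


def _mean_concentration(model: WallModel, element: str,
                        n: int = 30001) -> float:
    x = np.linspace(0.0, model.total_thickness, n)
    return float(np.trapezoid(_field(model, element, x), x)
                 / model.total_thickness)


# ---------------------------------------------------------------------------
# rendering

def expected_element_maps(model: WallModel,
                          acq: AcquisitionSpec) -> dict[str, np.ndarray]:
    """Noise-free expected counts per pixel, PSF-convolved, per element."""
    width, height = acq.map_extent
    x = _pixel_centers(acq)
    sig_h = acq.psf_fwhm[0] * _FWHM_TO_SIGMA / acq.pixel_size
    sig_v = acq.psf_fwhm[1] * _FWHM_TO_SIGMA / acq.pixel_size
    out = {}
    for el in sorted(model.bulk_scale):
        scale = model.bulk_scale[el]
        if scale < 0:
            raise WallModelError(f"negative bulk_scale for {el}")
        row = scale * acq.dwell_time * _field(model, el, x)
        img = np.tile(row, (height, 1))
        img = gaussian_filter(img, sigma=(sig_v, sig_h), mode="nearest")
        if img.max(initial=0.0) > _MAX_EXPECTED:
            raise WallModelError(f"expected counts overflow for {el}")
        out[el] = img
    return out


def render_element_maps(model: WallModel, acq: AcquisitionSpec):
    """Poisson-sampled integer count maps for every element of the model.

    Identical model + acquisition (including ``acq.seed``) give identical
    maps; each element draws from an independent substream.

    Returns a ``map_io.MapStack``.
    """
    from .map_io import ElementMap, MapStack

    expected = expected_element_maps(model, acq)
    maps = {}
    for i, el in enumerate(sorted(expected)):
        rng = np.random.default_rng(np.random.SeedSequence([acq.seed, i]))
        counts = rng.poisson(expected[el]).astype(np.int64)
        maps[el] = ElementMap(
            line=el, counts=counts, pixel_size=acq.pixel_size,
            dwell_time=acq.dwell_time,
            excitation_energy=acq.excitation_energy,
            provenance=f"synthetic render seed={acq.seed}",
        )
    return MapStack(maps=maps, metadata={"seed": acq.seed,
                                         "psf_fwhm": list(acq.psf_fwhm)})


def expected_bulk_counts(model: WallModel, acq: AcquisitionSpec,
                         n_spectra: int = 1000) -> dict[str, float]:
    """Expected bulk-spectrum counts per element.

    Bulk analyses compile the fitted counts of many pixel spectra spread
    over the mapped wall, so the expectation per element is the
    wall-mean concentration times sensitivity, dwell and the number of
    compiled spectra -- not the depth integral (walls of different
    thickness are compared per spectrum, as in an average-spectrum
    comparison).
    """
    if n_spectra < 1:
        raise WallModelError("n_spectra must be >= 1")
    return {
        el: model.bulk_scale[el] * acq.dwell_time * n_spectra
        * _mean_concentration(model, el)
        for el in sorted(model.bulk_scale)
    }


def render_bulk_counts(model: WallModel, acq: AcquisitionSpec,
                       n_spectra: int = 1000) -> dict[str, int]:
    """Poisson-sampled bulk-spectrum counts per element."""
    expected = expected_bulk_counts(model, acq, n_spectra)
    out = {}
    for i, el in enumerate(sorted(expected)):
        rng = np.random.default_rng(
            np.random.SeedSequence([acq.seed, 100000 + i]))
        out[el] = int(rng.poisson(expected[el]))
    return out
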