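"""Averaged 1D profiles across the wall and Poisson-propagated ratios.

A profile is extracted from a count map by averaging over an
axis-aligned rectangle (the field protocol averages a 21-pixel-wide
box), keeping per-pixel count units: for each position the raw counts
are summed across the averaging width and divided by the width, and the
uncertainty is the square root of the summed raw counts divided by the
width (Poisson statistics of fitted line counts).

Elemental ratio traces carry the standard first-order propagated
uncertainty

    sigma(X/Y) = (X/Y) * sqrt((sigma_X/X)^2 + (sigma_Y/Y)^2),

which for a trace element over the dominant Ca line is close to the
trace element's own relative uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .map_io import ElementMap


class ProfileError(ValueError):
    """Invalid profile-extraction or ratio input."""


@dataclass(frozen=True)
class Profile:
    """Averaged count trace for one emission line along one axis."""

    line: str
    position: np.ndarray        # nm, pixel centers, strictly increasing
    counts: np.ndarray          # mean counts per pixel column
    sigma: np.ndarray           # propagated uncertainty, same units
    averaging_width: int = 1    # pixels averaged across

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.size > 1:
            dx = np.diff(pos)
            if not np.all(dx > 0):
                raise ProfileError("positions must be strictly increasing")
            if not np.allclose(dx, dx[0], rtol=1e-9, atol=0.0):
                raise ProfileError("positions must be uniformly spaced")
        if np.any(np.asarray(self.sigma, dtype=float) < 0):
            raise ProfileError("sigma must be >= 0")
        for name in ("position", "counts", "sigma"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))

    @property
    def spacing(self) -> float:
        return float(self.position[1] - self.position[0])


@dataclass(frozen=True)
class RatioProfile:
    """Elemental ratio trace with propagated uncertainty.

    Positions where the denominator had zero counts are masked to NaN in
    both ``ratio`` and ``sigma`` and counted in ``n_masked``.
    """

    numerator: str
    denominator: str
    position: np.ndarray
    ratio: np.ndarray
    sigma: np.ndarray
    n_masked: int = 0

    def __post_init__(self) -> None:
        for name in ("position", "ratio", "sigma"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))

    @property
    def spacing(self) -> float:
        return float(self.position[1] - self.position[0])

    @property
    def label(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def extract_profile(emap: ElementMap, axis_start: tuple[int, int],
                    axis_end: tuple[int, int], width: int = 21) -> Profile:
    """Average an axis-aligned rectangle of ``emap`` into a 1D profile.

    ``axis_start`` and ``axis_end`` are (row, col) pixel coordinates of
    the profile axis endpoints (inclusive); the axis must be aligned
    with a grid direction and the rectangle of ``width`` pixels centred
    on it must lie inside the map. ``width`` must be odd.
    """
    if width < 1 or width % 2 == 0:
        raise ProfileError("width must be odd and >= 1")
    r0, c0 = axis_start
    r1, c1 = axis_end
    nrow, ncol = emap.shape
    if r0 != r1 and c0 != c1:
        raise ProfileError("profile axis must be row- or column-aligned")
    half = width // 2
    counts = np.asarray(emap.counts)
    if r0 == r1:                              # along columns
        lo, hi = sorted((c0, c1))
        if not (0 <= lo and hi < ncol and 0 <= r0 - half
                and r0 + half < nrow):
            raise ProfileError("averaging rectangle out of bounds")
        block = counts[r0 - half:r0 + half + 1, lo:hi + 1]
        summed = block.sum(axis=0, dtype=np.int64)
        index = np.arange(lo, hi + 1)
    else:                                     # along rows
        lo, hi = sorted((r0, r1))
        if not (0 <= lo and hi < nrow and 0 <= c0 - half
                and c0 + half < ncol):
            raise ProfileError("averaging rectangle out of bounds")
        block = counts[lo:hi + 1, c0 - half:c0 + half + 1]
        summed = block.sum(axis=1, dtype=np.int64)
        index = np.arange(lo, hi + 1)
    # Poisson unit floor: a zero summed count still gets sigma of 1 raw count
    sigma = np.sqrt(np.maximum(summed, 1)) / width
    position = (index + 0.5) * emap.pixel_size
    return Profile(line=emap.line, position=position,
                   counts=summed / width, sigma=sigma,
                   averaging_width=width)


def ratio_profile(num: Profile, den: Profile) -> RatioProfile:
    """Form the ratio trace num/den with propagated Poisson uncertainty.

    The two profiles must share their position grid exactly. Positions
    with zero denominator counts are masked to NaN.
    """
    if num.position.shape != den.position.shape \
            or not np.array_equal(num.position, den.position):
        raise ProfileError("profiles do not share one position grid")
    good = den.counts > 0
    ratio = np.full(num.counts.shape, np.nan)
    sigma = np.full(num.counts.shape, np.nan)
    n, d = num.counts[good], den.counts[good]
    ratio[good] = n / d
    # where numerator counts are zero, the unit-floor sigma alone applies
    zero_n = n == 0
    r = np.empty_like(ratio[good])
    nz = ~zero_n
    r[nz] = ratio[good][nz] * np.sqrt((num.sigma[good][nz] / n[nz])**2
                                      + (den.sigma[good][nz] / d[nz])**2)
    r[zero_n] = num.sigma[good][zero_n] / d[zero_n]
    sigma[good] = r
    return RatioProfile(numerator=num.line, denominator=den.line,
                        position=num.position.copy(), ratio=ratio,
                        sigma=sigma, n_masked=int((~good).sum()))
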