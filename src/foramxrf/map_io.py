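"""Containers and lossless I/O for element maps, profiles and results.

A :class:`MapStack` is written as one multi-page 32-bit integer TIFF
(one page per emission line, lines in sorted order) plus a JSON sidecar
holding all metadata with fixed key ordering, so identical inputs
produce identical bytes. Profiles go to CSV with full ``repr`` float
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile


class MapIOError(ValueError):
    """Malformed container, metadata or table."""


@dataclass(frozen=True)
class ElementMap:
    """One emission line's 2D integer count image plus acquisition metadata."""

    line: str
    counts: np.ndarray
    pixel_size: float            # nm
    dwell_time: float            # s
    excitation_energy: float = 17.4  # keV
    provenance: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise MapIOError(f"{self.line}: counts must be 2D")
        if not np.issubdtype(counts.dtype, np.integer):
            raise MapIOError(f"{self.line}: counts must be integer-valued")
        if counts.size and counts.min() < 0:
            raise MapIOError(f"{self.line}: negative counts")
        if not self.pixel_size > 0 or not self.dwell_time > 0:
            raise MapIOError(f"{self.line}: pixel_size and dwell_time > 0")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class MapStack:
    """A set of co-registered element maps sharing one grid."""

    maps: Mapping[str, ElementMap]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.maps:
            raise MapIOError("empty map stack")
        ref = next(iter(self.maps.values()))
        for line, emap in self.maps.items():
            if emap.shape != ref.shape:
                raise MapIOError(
                    f"shape mismatch: {line} {emap.shape} vs {ref.shape}")
            if emap.pixel_size != ref.pixel_size \
                    or emap.dwell_time != ref.dwell_time:
                raise MapIOError(f"{line}: pixel size / dwell mismatch")

    @property
    def lines(self) -> list[str]:
        return sorted(self.maps)

    def __getitem__(self, line: str) -> ElementMap:
        return self.maps[line]

    def __eq__(self, other) -> bool:
        if not isinstance(other, MapStack):
            return NotImplemented
        if self.lines != other.lines or self.metadata != other.metadata:
            return False
        for line in self.lines:
            a, b = self[line], other[line]
            if (a.pixel_size, a.dwell_time, a.excitation_energy,
                    a.provenance) != (b.pixel_size, b.dwell_time,
                                      b.excitation_energy, b.provenance):
                return False
            if not np.array_equal(a.counts, b.counts):
                return False
        return True


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_map_stack(stack: MapStack, path: str | Path) -> None:
    """Write a stack as multi-page int32 TIFF + JSON sidecar (deterministic)."""
    path = Path(path)
    lines = stack.lines
    data = np.stack([stack[line].counts.astype(np.int32) for line in lines])
    for line in lines:
        if stack[line].counts.max(initial=0) > np.iinfo(np.int32).max:
            raise MapIOError(f"{line}: counts exceed int32 range")
    ref = stack[lines[0]]
    meta = {
        "lines": lines,
        "pixel_size_nm": ref.pixel_size,
        "dwell_time_s": ref.dwell_time,
        "excitation_energy_keV": {
            line: stack[line].excitation_energy for line in lines},
        "provenance": {line: stack[line].provenance for line in lines},
        "metadata": stack.metadata,
    }
    tifffile.imwrite(path, data, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n")


def read_map_stack(path: str | Path) -> MapStack:
    """Read a stack written by :func:`write_map_stack` (lossless)."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise MapIOError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise MapIOError(f"malformed sidecar {sidecar}: {exc}") from exc
    for key in ("lines", "pixel_size_nm", "dwell_time_s"):
        if key not in meta:
            raise MapIOError(f"sidecar missing key {key!r}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    lines = meta["lines"]
    if data.shape[0] != len(lines):
        raise MapIOError(
            f"page count {data.shape[0]} != line count {len(lines)}")
    maps = {
        line: ElementMap(
            line=line,
            counts=np.asarray(data[i], dtype=np.int64),
            pixel_size=meta["pixel_size_nm"],
            dwell_time=meta["dwell_time_s"],
            excitation_energy=meta.get("excitation_energy_keV", {}).get(
                line, 17.4),
            provenance=meta.get("provenance", {}).get(line, ""),
        )
        for i, line in enumerate(lines)
    }
    return MapStack(maps=maps, metadata=meta.get("metadata", {}))


# ---------------------------------------------------------------------------
# profile tables

def write_profile_table(profiles: Sequence, path: str | Path) -> None:
    """Write profiles sharing one position grid to a delimited table.

    Columns: ``position_nm`` then ``<line>_counts``, ``<line>_sigma``
    per profile. An empty profile list yields a header-only file.
    """
    path = Path(path)
    if not profiles:
        path.write_text("position_nm\n")
        return
    pos = np.asarray(profiles[0].position, dtype=float)
    cols: dict[str, np.ndarray] = {"position_nm": pos}
    for prof in profiles:
        if not np.array_equal(np.asarray(prof.position, dtype=float), pos):
            raise MapIOError("profiles do not share one position grid")
        cols[f"{prof.line}_counts"] = np.asarray(prof.counts, dtype=float)
        cols[f"{prof.line}_sigma"] = np.asarray(prof.sigma, dtype=float)
    frame = pd.DataFrame(cols)
    # no float_format: the shortest-repr default round-trips float64 exactly
    frame.to_csv(path, index=False, lineterminator="\n")


def read_profile_table(path: str | Path) -> list:
    """Read a profile table back into :class:`foramxrf.profiles.Profile`."""
    from .profiles import Profile

    frame = pd.read_csv(path)
    if "position_nm" not in frame.columns:
        raise MapIOError("profile table missing 'position_nm' column")
    pos = frame["position_nm"].to_numpy(dtype=float)
    lines = [c[:-len("_counts")] for c in frame.columns
             if c.endswith("_counts")]
    out = []
    for line in lines:
        sig_col = f"{line}_sigma"
        if sig_col not in frame.columns:
            raise MapIOError(f"profile table missing column {sig_col!r}")
        counts = frame[f"{line}_counts"].to_numpy(dtype=float)
        sigma = frame[sig_col].to_numpy(dtype=float)
        if counts.size and counts.min() < 0:
            raise MapIOError(f"{line}: negative counts in table")
        out.append(Profile(line=line, position=pos, counts=counts,
                           sigma=sigma, averaging_width=0))
    return out


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer used for all result exports."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1,
                                     allow_nan=True) + "\n")
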