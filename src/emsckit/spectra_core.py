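"""Core spectral containers and delimited-text I/O.

A :class:`SpectraSet` holds a set of apparent-absorbance spectra on a shared
wavenumber axis. The axis is always stored ascending; files written by
instruments with descending axes are reordered on read. Region selection and
interpolation never happen implicitly — models reject axis mismatches and the
caller resamples explicitly with :func:`interpolate_to_axis`.

File dialect
------------
Spectra matrices are UTF-8 delimited text (comma or tab, autodetected) with a
header row ``wavenumber,<id1>,<id2>,...`` and one row per channel. Values are
written with 12 significant digits. Hyperspectral images use a long format
with header ``x,y,wavenumber,absorbance`` and 0-based integer pixel
coordinates.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AxisError,
    ExtrapolationError,
    ParseError,
    RegionError,
    ValidationError,
)

__all__ = [
    "WavenumberAxis",
    "SpectraSet",
    "HyperspectralImage",
    "read_spectra",
    "write_spectra",
    "read_image",
    "write_image",
    "select_region",
    "interpolate_to_axis",
]


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly ascending wavenumber grid in cm^-1 (length >= 3)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise AxisError("wavenumber axis must be one-dimensional")
        if values.size < 3:
            raise AxisError(f"axis needs at least 3 channels, got {values.size}")
        if not np.all(np.isfinite(values)):
            raise AxisError("axis contains non-finite wavenumbers")
        diffs = np.diff(values)
        if np.any(diffs == 0):
            dup = values[np.where(diffs == 0)[0][0]]
            raise AxisError(f"duplicate wavenumber {dup:g} cm^-1 in axis")
        if np.any(diffs < 0):
            raise AxisError("axis must be strictly ascending (reorder on read)")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the channel nearest ``wavenumber``; ties -> lower cm^-1."""
        if not (self.lo <= wavenumber <= self.hi):
            raise RegionError(
                f"wavenumber {wavenumber:g} outside axis range "
                f"[{self.lo:g}, {self.hi:g}] cm^-1"
            )
        dist = np.abs(self.values - wavenumber)
        # argmin returns the first (lowest-wavenumber) channel on exact ties
        return int(np.argmin(dist))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )


@dataclass
class SpectraSet:
    """Apparent absorbance spectra Zapp on a shared axis.

    ``absorbance`` has shape ``(n_spectra, n_channels)``; ``ids`` are unique
    spectrum identifiers aligned with rows.
    """

    axis: WavenumberAxis
    absorbance: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        ab = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if ab.shape[1] != len(self.axis):
            raise ValidationError(
                f"absorbance has {ab.shape[1]} channels but axis has {len(self.axis)}"
            )
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != ab.shape[0]:
            raise ValidationError(
                f"{len(self.ids)} ids for {ab.shape[0]} spectra"
            )
        if not self.ids:
            raise ValidationError("SpectraSet needs at least one spectrum id")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("spectrum ids must be unique")
        if not np.all(np.isfinite(ab)):
            raise ValidationError("absorbance values must be finite")
        self.absorbance = ab

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def spectrum(self, id_: str) -> np.ndarray:
        return self.absorbance[self.ids.index(id_)]

    def mean_spectrum(self) -> np.ndarray:
        return self.absorbance.mean(axis=0)

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.axis, self.absorbance.copy(), list(self.ids))


@dataclass
class HyperspectralImage:
    """Per-pixel spectra on a rectangular grid, row-major pixel order.

    Pixel ``(x, y)`` maps to cube row ``y * width + x``.
    """

    width: int
    height: int
    axis: WavenumberAxis
    cube: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cube = np.atleast_2d(np.asarray(self.cube, dtype=float))
        if cube.shape[0] != self.width * self.height:
            raise ValidationError(
                f"cube has {cube.shape[0]} spectra but image is "
                f"{self.width}x{self.height}"
            )
        if cube.shape[1] != len(self.axis):
            raise ValidationError("cube channel count does not match axis")
        self.cube = cube
        if not self.ids:
            self.ids = [
                f"px_{i % self.width}_{i // self.width}"
                for i in range(cube.shape[0])
            ]

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def to_spectra(self) -> SpectraSet:
        """Flatten to a SpectraSet (lossless; see :meth:`from_spectra`)."""
        return SpectraSet(self.axis, self.cube, list(self.ids))

    @classmethod
    def from_spectra(cls, spectra: SpectraSet, width: int, height: int) -> "HyperspectralImage":
        return cls(width, height, spectra.axis, spectra.absorbance, list(spectra.ids))

    def plane(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-pixel vector to a (height, width) raster."""
        return np.asarray(values).reshape(self.height, self.width)


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_spectra(path: str | Path, delimiter: str | None = None) -> SpectraSet:
    """Read a spectra matrix file into a :class:`SpectraSet`.

    The first column must parse as numeric wavenumbers; the header row gives
    the spectrum ids. A descending axis is reordered to ascending.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    header = next(reader)
    if len(header) < 2:
        raise ParseError(f"{path}: header must list wavenumber plus >=1 spectrum id")
    ids = [h.strip() for h in header[1:]]
    wavenumbers: list[float] = []
    rows: list[list[float]] = []
    for irow, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise ParseError(
                f"{path}: row {irow} has {len(row)} fields, expected {len(header)}"
            )
        parsed = []
        for icol, cell in enumerate(row, start=1):
            try:
                parsed.append(float(cell))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at row {irow}, "
                    f"column {icol}"
                ) from exc
        wavenumbers.append(parsed[0])
        rows.append(parsed[1:])
    if len(wavenumbers) < 3:
        raise ParseError(f"{path}: needs at least 3 channel rows")
    wn = np.array(wavenumbers)
    data = np.array(rows)  # (n_channels, n_spectra)
    if np.unique(wn).size != wn.size:
        raise AxisError(f"{path}: duplicate wavenumbers in first column")
    order = np.argsort(wn)
    return SpectraSet(WavenumberAxis(wn[order]), data[order].T, ids)


def write_spectra(
    spectra: SpectraSet,
    path: str | Path,
    delimiter: str = ",",
    descending: bool = False,
) -> None:
    """Write a :class:`SpectraSet` in the standard matrix dialect.

    ``descending=True`` writes the axis high-to-low (common instrument
    convention); reading it back restores the ascending orientation.
    """
    path = Path(path)
    wn = spectra.axis.values
    data = spectra.absorbance.T  # (n_channels, n_spectra)
    if descending:
        wn = wn[::-1]
        data = data[::-1]
    lines = [delimiter.join(["wavenumber", *spectra.ids])]
    for w, row in zip(wn, data):
        lines.append(delimiter.join(f"{v:.12g}" for v in (w, *row)))
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"could not write spectra file {path}: {exc}") from exc


def read_image(path: str | Path, delimiter: str | None = None) -> HyperspectralImage:
    """Read a long-format hyperspectral image (x,y,wavenumber,absorbance)."""
    path = Path(path)
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            delimiter = _sniff_delimiter(fh.readline())
    try:
        df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # pandas raises several parse error types
        raise ParseError(f"{path}: {exc}") from exc
    required = ["x", "y", "wavenumber", "absorbance"]
    if list(df.columns[:4]) != required:
        raise ParseError(
            f"{path}: header must be {','.join(required)}, got {list(df.columns)}"
        )
    wn = np.sort(df["wavenumber"].unique())
    width = int(df["x"].max()) + 1
    height = int(df["y"].max()) + 1
    n_px = width * height
    if len(df) != n_px * wn.size:
        raise ParseError(
            f"{path}: {len(df)} rows cannot tile a {width}x{height} image "
            f"with {wn.size} channels"
        )
    pivot = df.pivot_table(
        index=["y", "x"], columns="wavenumber", values="absorbance", sort=True
    )
    cube = pivot.to_numpy()
    return HyperspectralImage(width, height, WavenumberAxis(wn), cube)


def write_image(image: HyperspectralImage, path: str | Path, delimiter: str = ",") -> None:
    """Write a hyperspectral image in the long-format dialect."""
    path = Path(path)
    wn = image.axis.values
    # row-major pixel order: y outer, x inner, wavenumber innermost
    px_x = np.arange(image.n_pixels) % image.width
    px_y = np.arange(image.n_pixels) // image.width
    x_col = np.repeat(px_x, wn.size)
    y_col = np.repeat(px_y, wn.size)
    wn_col = np.tile(wn, image.n_pixels)
    ab_col = image.cube.reshape(-1)
    df = pd.DataFrame(
        {"x": x_col, "y": y_col, "wavenumber": wn_col, "absorbance": ab_col}
    )
    df.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def _normalize_intervals(intervals: Iterable[Sequence[float]]) -> list[tuple[float, float]]:
    out = []
    for pair in intervals:
        lo, hi = float(pair[0]), float(pair[1])
        if lo > hi:
            lo, hi = hi, lo
        if lo == hi:
            raise RegionError(f"degenerate interval [{lo:g}, {hi:g}]")
        out.append((lo, hi))
    if not out:
        raise RegionError("no intervals given")
    return out


def select_region(
    spectra: SpectraSet, intervals: Iterable[Sequence[float]]
) -> SpectraSet:
    """Keep the channels whose wavenumber falls in the closed union of intervals.

    Endpoints are inclusive, so the conventional "3050-2800 cm^-1" phrasing
    keeps both named channels. Endpoint order within a pair is normalized.
    """
    pairs = _normalize_intervals(intervals)
    wn = spectra.axis.values
    mask = np.zeros(wn.size, dtype=bool)
    for lo, hi in pairs:
        mask |= (wn >= lo) & (wn <= hi)
    if mask.sum() < 3:
        raise RegionError(
            f"selection {pairs} keeps {int(mask.sum())} channels; need >= 3"
        )
    return SpectraSet(
        WavenumberAxis(wn[mask]), spectra.absorbance[:, mask], list(spectra.ids)
    )


def interpolate_to_axis(spectra: SpectraSet, target: WavenumberAxis) -> SpectraSet:
    """Linearly interpolate every spectrum onto ``target`` (no extrapolation)."""
    src = spectra.axis
    if target == src:
        return spectra.copy()
    if target.lo < src.lo or target.hi > src.hi:
        raise ExtrapolationError(
            f"target range [{target.lo:g}, {target.hi:g}] exceeds source "
            f"[{src.lo:g}, {src.hi:g}] cm^-1"
        )
    out = np.empty((spectra.n_spectra, len(target)))
    for i, row in enumerate(spectra.absorbance):
        out[i] = np.interp(target.values, src.values, row)
    return SpectraSet(target, out, list(spectra.ids))
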