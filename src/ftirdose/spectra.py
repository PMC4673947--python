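"""Spectrum containers, delimited-text I/O, windowing, and resampling.

Absorbance traces live on a shared, uniformly spaced wavenumber grid in
cm⁻¹ (mid-infrared; the instrument range is 400–4000 cm⁻¹). Two
delimited-text dialects are supported:

* ``wide`` — first column is the wavenumber, each remaining column one
  spectrum, with header ``dose:replicate`` (e.g. ``0.25:3``), so a single
  file carries the full dose design;
* ``long`` — columns ``(wavenumber, absorbance, dose, replicate)``.

Files are UTF-8 CSV with ``.`` as the decimal separator; absorbances are
serialized with 17 significant digits so a write→read round trip is
lossless to well below 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    ExtrapolationError,
    FormatError,
    GridError,
    WindowError,
)

INSTRUMENT_RANGE = (400.0, 4000.0)
_GRID_RTOL = 1e-9


@dataclass(frozen=True, eq=False)
class WavenumberGrid:
    """A strictly increasing, uniformly spaced wavenumber axis (cm⁻¹)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise GridError("grid needs at least two wavenumber points")
        if not np.all(np.isfinite(v)):
            raise GridError("grid contains non-finite wavenumbers")
        d = np.diff(v)
        if np.any(d <= 0):
            raise GridError("wavenumbers must be strictly increasing")
        step = d[0]
        if np.any(np.abs(d - step) > _GRID_RTOL * max(abs(step), 1.0)):
            raise GridError(f"grid spacing is not uniform (first step {step:g})")
        lo, hi = INSTRUMENT_RANGE
        if v[0] < lo - 1e-9 or v[-1] > hi + 1e-9:
            raise GridError(
                f"grid [{v[0]:g}, {v[-1]:g}] outside instrument range {lo:g}-{hi:g} cm^-1"
            )

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.size == other.values.size and np.allclose(
            self.values, other.values, rtol=_GRID_RTOL, atol=0.0
        )

    def __hash__(self):  # frozen dataclass with eq=False would supply id-hash
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


def default_grid(lo: float = 1000.0, hi: float = 3000.0, spacing: float = 1.0) -> WavenumberGrid:
    """The package's working grid: 1000–3000 cm⁻¹ at 1 cm⁻¹ (2001 points).

    Every band centre used by the simulator lies on this grid, which makes
    peak worked-examples exact.
    """
    n = int(round((hi - lo) / spacing)) + 1
    return WavenumberGrid(lo + spacing * np.arange(n))


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace with its dose/replicate metadata.

    ``dose`` is the cisplatin concentration in µg/mL (≥ 0); ``replicate_id``
    is 1-based within a dose group. Absorbance values may be slightly
    negative after baseline correction; as generated they are non-negative.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    dose: float = 0.0
    replicate_id: int = 1
    label: str = ""

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", a)
        if a.ndim != 1 or a.size != len(self.grid):
            raise DataError(
                f"absorbance length {a.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(a)):
            raise DataError("absorbance contains non-finite values")
        if self.dose < 0:
            raise DataError(f"dose must be >= 0, got {self.dose}")
        if int(self.replicate_id) < 1:
            raise DataError(f"replicate_id must be >= 1, got {self.replicate_id}")


@dataclass
class SpectrumCollection:
    """A list of spectra sharing one grid, replicate ids unique per dose."""

    spectra: list = field(default_factory=list)

    def __post_init__(self):
        if not self.spectra:
            return
        g0 = self.spectra[0].grid
        seen = set()
        for s in self.spectra:
            if s.grid != g0:
                raise GridError("all spectra in a collection must share one grid")
            key = (s.dose, s.replicate_id)
            if key in seen:
                raise DataError(f"duplicate (dose, replicate) pair {key}")
            seen.add(key)

    @property
    def grid(self) -> WavenumberGrid:
        if not self.spectra:
            raise DataError("empty collection has no grid")
        return self.spectra[0].grid

    @property
    def doses(self) -> np.ndarray:
        """Sorted unique doses present in the collection."""
        return np.unique([s.dose for s in self.spectra])

    def at_dose(self, dose: float) -> list:
        return [s for s in self.spectra if s.dose == dose]

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]


# ---------------------------------------------------------------------------
# I/O


def _column_name(s: Spectrum) -> str:
    return f"{s.dose:g}:{s.replicate_id:d}"


def _parse_column_name(name: str) -> tuple[float, int]:
    parts = str(name).split(":")
    if len(parts) != 2:
        raise FormatError(f"wide-dialect column header {name!r} is not 'dose:replicate'")
    try:
        return float(parts[0]), int(parts[1])
    except ValueError as exc:
        raise FormatError(f"cannot parse column header {name!r}") from exc


def write_spectra(collection: SpectrumCollection, path, dialect: str = "wide") -> None:
    """Serialize a collection as CSV in the ``wide`` or ``long`` dialect."""
    if len(collection) == 0:
        raise DataError("refusing to write an empty collection")
    if dialect == "wide":
        data = {"wavenumber": collection.grid.values}
        for s in collection:
            data[_column_name(s)] = s.absorbance
        frame = pd.DataFrame(data)
    elif dialect == "long":
        frames = [
            pd.DataFrame(
                {
                    "wavenumber": s.grid.values,
                    "absorbance": s.absorbance,
                    "dose": s.dose,
                    "replicate": s.replicate_id,
                }
            )
            for s in collection
        ]
        frame = pd.concat(frames, ignore_index=True)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    frame.to_csv(path, index=False, float_format="%.17g")


def read_spectra(path, dialect: str = "wide") -> SpectrumCollection:
    """Parse a CSV written by :func:`write_spectra` (or shaped like it)."""
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if dialect == "wide":
        if frame.shape[1] < 2:
            raise FormatError("wide file needs a wavenumber column plus >=1 spectrum")
        grid = WavenumberGrid(frame.iloc[:, 0].to_numpy(dtype=float))
        spectra = []
        for col in frame.columns[1:]:
            dose, rep = _parse_column_name(col)
            spectra.append(
                Spectrum(grid, frame[col].to_numpy(dtype=float), dose=dose, replicate_id=rep)
            )
        return SpectrumCollection(spectra)
    if dialect == "long":
        required = {"wavenumber", "absorbance", "dose", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"long file missing columns: {sorted(missing)}")
        spectra = []
        grid = None
        for (dose, rep), sub in frame.groupby(["dose", "replicate"], sort=True):
            g = WavenumberGrid(sub["wavenumber"].to_numpy(dtype=float))
            if grid is None:
                grid = g
            elif g != grid:
                raise GridError("long file contains spectra on differing grids")
            spectra.append(
                Spectrum(
                    grid,
                    sub["absorbance"].to_numpy(dtype=float),
                    dose=float(dose),
                    replicate_id=int(rep),
                )
            )
        if not spectra:
            raise FormatError("long file contains no spectra")
        return SpectrumCollection(spectra)
    raise FormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Windowing / resampling

_WINDOW_ATOL = 1e-6


def window_mask(grid: WavenumberGrid, lo: float, hi: float) -> np.ndarray:
    """Boolean mask of grid points inside the closed interval [lo, hi]."""
    if not lo < hi:
        raise WindowError(f"window bounds must satisfy lo < hi, got [{lo}, {hi}]")
    v = grid.values
    mask = (v >= lo - _WINDOW_ATOL) & (v <= hi + _WINDOW_ATOL)
    if not mask.any():
        raise WindowError(f"window [{lo}, {hi}] does not overlap grid "
                          f"[{v[0]:g}, {v[-1]:g}]")
    return mask


def extract_window(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict a spectrum to the closed interval [lo, hi] cm⁻¹.

    A grid point g is kept iff lo ≤ g ≤ hi; metadata is preserved.
    Idempotent: windowing twice with the same bounds equals once.
    """
    mask = window_mask(spectrum.grid, lo, hi)
    sub = spectrum.grid.values[mask]
    if sub.size < 2:
        raise WindowError(f"window [{lo}, {hi}] keeps fewer than two grid points")
    return replace(spectrum, grid=WavenumberGrid(sub), absorbance=spectrum.absorbance[mask])


def resample(spectrum: Spectrum, grid: WavenumberGrid) -> Spectrum:
    """Linear interpolation of a spectrum onto a new grid (no extrapolation).

    Exact at grid points shared between source and target.
    """
    src = spectrum.grid.values
    tgt = grid.values
    if tgt[0] < src[0] - _WINDOW_ATOL or tgt[-1] > src[-1] + _WINDOW_ATOL:
        raise ExtrapolationError(
            f"target grid [{tgt[0]:g}, {tgt[-1]:g}] extends beyond source "
            f"[{src[0]:g}, {src[-1]:g}]"
        )
    values = np.interp(tgt, src, spectrum.absorbance)
    return replace(spectrum, grid=grid, absorbance=values)
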