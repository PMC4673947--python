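"""Biochemical index spectra (BIS) and peak location.

A BIS row is an exposed-cell spectrum minus the pointwise mean of all
control-dose spectra, computed after preprocessing. The stack of BIS rows
(X) with the corresponding dose vector (y) is the data the regression
consumes: under the default design of nine concentrations × seven
replicates the control group is consumed as reference and 8 × 7 = 56
rows remain.

Peak location uses local-extremum detection with a prominence filter and
a three-point parabolic apex refinement; reported centres are rounded to
the nearest integer cm⁻¹, matching how band positions are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ControlReferenceError, DataError, WindowError
from .spectra import SpectrumCollection, WavenumberGrid, window_mask


@dataclass
class BISMatrix:
    """Difference-spectrum design matrix: rows = exposed replicates."""

    X: np.ndarray
    y: np.ndarray
    grid: WavenumberGrid
    row_labels: list  # (dose, replicate_id) per row

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise DataError("X rows and y length disagree")
        if self.X.shape[1] != len(self.grid):
            raise DataError("X columns and grid length disagree")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def restrict(self, lo: float, hi: float) -> "BISMatrix":
        """The same matrix restricted to the closed window [lo, hi] cm⁻¹."""
        mask = window_mask(self.grid, lo, hi)
        return BISMatrix(self.X[:, mask], self.y,
                         WavenumberGrid(self.grid.values[mask]), list(self.row_labels))

    def to_frame(self) -> pd.DataFrame:
        index = [f"{d:g}:{r:d}" for d, r in self.row_labels]
        cols = [f"{w:g}" for w in self.grid.values]
        return pd.DataFrame(self.X, index=index, columns=cols)


def write_bis(bis: BISMatrix, path) -> None:
    bis.to_frame().to_csv(path, index_label="dose:replicate", float_format="%.17g")


def read_bis(path) -> BISMatrix:
    frame = pd.read_csv(path, index_col=0)
    grid = WavenumberGrid(np.array([float(c) for c in frame.columns]))
    labels = []
    for idx in frame.index:
        d, r = str(idx).split(":")
        labels.append((float(d), int(r)))
    y = np.array([d for d, _ in labels])
    return BISMatrix(frame.to_numpy(dtype=float), y, grid, labels)


def compute_bis(collection: SpectrumCollection, control_dose: float = 0.0) -> BISMatrix:
    """Exposed spectra minus the mean control spectrum.

    Control-dose replicates are averaged into one reference trace and
    never appear as rows. Linear by construction: a collection whose
    exposed spectra equal (control mean + delta) yields exactly delta.
    """
    controls = [s for s in collection if s.dose == control_dose]
    if not controls:
        raise ControlReferenceError(f"no spectra at control dose {control_dose:g}")
    exposed = [s for s in collection if s.dose != control_dose]
    if not exposed:
        raise ControlReferenceError("no exposed spectra to difference against control")
    reference = np.mean([s.absorbance for s in controls], axis=0)
    X = np.stack([s.absorbance - reference for s in exposed])
    y = np.array([s.dose for s in exposed])
    labels = [(s.dose, s.replicate_id) for s in exposed]
    return BISMatrix(X, y, collection.grid, labels)


@dataclass(frozen=True)
class Peak:
    """A located band apex: integer-rounded centre plus refined estimate."""

    center: int  # cm^-1, rounded
    center_interp: float  # parabolic apex estimate
    height: float  # signed intensity at the apex
    sign: str  # "positive" | "negative"
    prominence: float

    def __post_init__(self):
        if self.sign == "positive" and self.height <= 0:
            raise DataError("positive peak must have height > 0")
        if self.sign == "negative" and self.height >= 0:
            raise DataError("negative peak must have height < 0")


def detect_peaks(values, grid: WavenumberGrid, lo: float, hi: float,
                 sign: str = "positive", min_prominence: float = 0.0) -> list[Peak]:
    """Local extrema of one sign inside [lo, hi], ordered by |height| desc.

    Negative peaks are found as maxima of the negated trace. Each apex is
    refined by fitting a parabola through the three samples around the
    discrete extremum; the reported ``center`` is that estimate rounded
    to the nearest integer cm⁻¹.
    """
    if sign not in ("positive", "negative"):
        raise DataError(f"sign must be 'positive' or 'negative', got {sign!r}")
    mask = window_mask(grid, lo, hi)
    x = grid.values[mask]
    v = np.asarray(values, dtype=float)
    if v.size != len(grid):
        raise DataError("trace length does not match grid")
    trace = v[mask]
    flipped = trace if sign == "positive" else -trace
    idx, props = find_peaks(flipped, prominence=min_prominence)
    spacing = x[1] - x[0] if x.size > 1 else 1.0
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        ym, y0, yp = flipped[i - 1], flipped[i], flipped[i + 1]
        denom = ym - 2.0 * y0 + yp
        delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
        apex = y0 - 0.25 * (ym - yp) * delta
        center = x[i] + delta * spacing
        height = apex if sign == "positive" else -apex
        if sign == "positive" and height <= 0:
            continue  # extremum of the wrong sign (e.g. a dip between troughs)
        if sign == "negative" and height >= 0:
            continue
        peaks.append(Peak(center=int(round(center)), center_interp=float(center),
                          height=float(height), sign=sign, prominence=float(prom)))
    peaks.sort(key=lambda p: abs(p.height), reverse=True)
    return peaks


def peak_trajectory(collection: SpectrumCollection, band_window: tuple,
                    sign: str = "positive", min_prominence: float = 0.0) -> pd.DataFrame:
    """Per-dose top-peak centre/height averages across replicates.

    Doses where no replicate shows a peak of the requested sign are
    reported with ``n_detected == 0`` and NaN summaries, never
    interpolated.
    """
    lo, hi = band_window
    rows = []
    for dose in collection.doses:
        centers, heights = [], []
        for s in collection.at_dose(dose):
            hits = detect_peaks(s.absorbance, s.grid, lo, hi, sign, min_prominence)
            if hits:
                centers.append(hits[0].center_interp)
                heights.append(hits[0].height)
        rows.append({
            "dose": dose,
            "n_detected": len(centers),
            "mean_center": float(np.mean(centers)) if centers else np.nan,
            "mean_height": float(np.mean(heights)) if heights else np.nan,
        })
    return pd.DataFrame(rows)


def bis_peak_trajectory(bis: BISMatrix, band_window: tuple, sign: str = "positive",
                        min_prominence: float = 0.0) -> pd.DataFrame:
    """Per-dose top-peak trajectory over the rows of a BIS matrix."""
    lo, hi = band_window
    rows = []
    for dose in np.unique(bis.y):
        centers, heights = [], []
        for row in bis.X[bis.y == dose]:
            hits = detect_peaks(row, bis.grid, lo, hi, sign, min_prominence)
            if hits:
                centers.append(hits[0].center_interp)
                heights.append(hits[0].height)
        rows.append({
            "dose": dose,
            "n_detected": len(centers),
            "mean_center": float(np.mean(centers)) if centers else np.nan,
            "mean_height": float(np.mean(heights)) if heights else np.nan,
        })
    return pd.DataFrame(rows)
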