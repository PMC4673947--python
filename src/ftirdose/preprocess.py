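"""Baseline correction and 0–1 normalization.

Each spectrum is baseline-corrected with asymmetric least squares (ALS)
and then min-max normalized to span [0, 1], in that fixed order, before
any difference-spectrum or regression step. ALS estimates a smooth
baseline z minimizing

    sum_i w_i (y_i - z_i)^2 + lambda * sum_i (Delta^2 z_i)^2

with asymmetric weights w_i = p for points above the baseline and 1 - p
below, iterated to convergence; lambda controls stiffness and p pushes
the baseline toward the lower envelope. Normalization is applied over
the full recorded range, not per window, so that segmentation afterwards
does not rescale band heights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded

from .errors import DataError, NormalizationError, ParameterError
from .spectra import Spectrum, SpectrumCollection


@dataclass(frozen=True)
class PreprocessParams:
    """ALS baseline parameters plus the normalization switch.

    ``baseline_lambda`` (>0) is the smoothness weight — larger is
    stiffer; ``baseline_p`` in (0,1) is the asymmetry weight given to
    points above the baseline; ``baseline_iters`` reweighting passes.
    """

    baseline_lambda: float = 1e8
    baseline_p: float = 0.01
    baseline_iters: int = 10
    normalize: bool = True

    def __post_init__(self):
        if self.baseline_lambda <= 0:
            raise ParameterError("baseline_lambda must be > 0")
        if not 0 < self.baseline_p < 1:
            raise ParameterError("baseline_p must lie in (0, 1)")
        if self.baseline_iters < 1:
            raise ParameterError("baseline_iters must be >= 1")


def als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                 iters: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline of a 1-D signal.

    Solves (W + lam * D2'D2) z = W y with D2 the second-difference
    operator, iterating the asymmetric weights. The banded symmetric
    system is solved directly (bandwidth 2), so the estimate is
    deterministic.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise DataError("need at least 10 points for baseline estimation")
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = (lam * (d2.T @ d2)).todia()
    # upper-banded storage for solveh_banded: rows are offsets 2, 1, 0
    ab_template = np.zeros((3, n))
    for row, offset in zip(range(3), (2, 1, 0)):
        diag = penalty.diagonal(offset)
        ab_template[row, offset:] = diag if offset else diag
    w = np.ones(n)
    z = y
    for _ in range(iters):
        ab = ab_template.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(spectrum: Spectrum, params: PreprocessParams | None = None) -> Spectrum:
    """Subtract the ALS baseline estimate from a spectrum.

    The output may contain small negatives; values in (−1e-6, 0) are
    snapped to exactly 0.
    """
    params = params or PreprocessParams()
    a = spectrum.absorbance
    if not np.all(np.isfinite(a)):
        raise DataError("spectrum contains non-finite absorbance")
    z = als_baseline(a, params.baseline_lambda, params.baseline_p, params.baseline_iters)
    corrected = a - z
    corrected[(corrected < 0) & (corrected > -1e-6)] = 0.0
    return replace(spectrum, absorbance=corrected)


def normalize_01(spectrum: Spectrum) -> Spectrum:
    """Min-max normalize so the trace spans exactly [0, 1]."""
    a = spectrum.absorbance
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        raise NormalizationError("constant spectrum cannot be normalized to [0, 1]")
    return replace(spectrum, absorbance=(a - lo) / (hi - lo))


def preprocess_spectrum(spectrum: Spectrum, params: PreprocessParams | None = None) -> Spectrum:
    params = params or PreprocessParams()
    out = baseline_correct(spectrum, params)
    if params.normalize:
        out = normalize_01(out)
    return out


def preprocess_collection(collection: SpectrumCollection,
                          params: PreprocessParams | None = None) -> SpectrumCollection:
    """Baseline-correct then normalize every member, preserving order."""
    params = params or PreprocessParams()
    out = []
    for s in collection:
        try:
            out.append(preprocess_spectrum(s, params))
        except Exception as exc:
            raise type(exc)(
                f"spectrum dose={s.dose:g} replicate={s.replicate_id}: {exc}"
            ) from exc
    return SpectrumCollection(out)
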