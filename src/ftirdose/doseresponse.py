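"""Clonogenic survival-curve fitting: two-parameter Hill model and LC50.

Mortality is modelled as mortality% = 100 · cʰ / (EC50ʰ + cʰ) with the
asymptotes fixed at 0 and 100 — the designed assay reaches both 0 % and
100 % mortality, so only the midpoint (EC50/LC50, µg/mL) and the Hill
slope h are free. The fit is least squares on the linear concentration
axis (the design includes dose 0, which a log-dose fit cannot hold),
multi-started over a grid of slopes with a deterministic local
optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ControlReferenceError, DataError, DegeneracyError
from .evaluate import r_squared

SLOPE_STARTS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class MortalityTable:
    """Rows of (concentration µg/mL, mortality %)."""

    concentration: np.ndarray
    mortality_pct: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.concentration, dtype=float)
        m = np.asarray(self.mortality_pct, dtype=float)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "mortality_pct", m)
        if c.size != m.size or c.size == 0:
            raise DataError("concentration and mortality must be equal-length, non-empty")
        if np.unique(c).size != c.size:
            raise DataError("concentrations must be distinct")
        if np.any(c < 0) or np.any((m < 0) | (m > 100)):
            raise DataError("concentrations >= 0 and mortality within [0, 100] required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose": self.concentration, "mortality_pct": self.mortality_pct})


def cisplatin_hepg2_mortality() -> MortalityTable:
    """Reference clonogenic mortality of HepG2 cells, 24 h cisplatin exposure.

    Nine concentrations spanning 0–4 µg/mL with mortality from 0 to
    100 %; the curve crosses 50 % between 0.25 and 0.5 µg/mL.
    """
    return MortalityTable(
        concentration=np.array([0.0, 0.125, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0]),
        mortality_pct=np.array([0.0, 24.0, 40.0, 67.0, 88.0, 92.0, 95.0, 98.0, 100.0]),
    )


@dataclass(frozen=True)
class HillFit:
    """Fitted dose-response parameters; check ``converged`` before use."""

    ec50: float
    slope: float
    residual_ss: float
    converged: bool


def _hill(c, ec50, slope):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        return 100.0 * c ** slope / (ec50 ** slope + c ** slope)


def fit_hill(table: MortalityTable) -> HillFit:
    """Least-squares Hill fit over the non-zero concentrations.

    Multi-start over slopes {0.5, 1, 2, 4}; EC50 starts at the linear
    interpolation of the 50 % crossing (falling back to the median
    dose). A fit that explains no variance (R² ≤ 0, e.g. mortality
    decreasing in dose) is flagged ``converged=False`` rather than
    returned silently.
    """
    mask = table.concentration > 0
    c = table.concentration[mask]
    m = table.mortality_pct[mask]
    if c.size < 3:
        raise DataError("need at least three non-zero concentrations")
    if np.all(m == 0) or np.all(m == 100):
        raise DegeneracyError("mortality pinned at an asymptote; Hill midpoint undefined")
    if not np.any((m > 0) & (m < 100)):
        raise DegeneracyError("no mortality strictly between 0 and 100 %")

    order = np.argsort(c)
    cs, ms = c[order], m[order]
    crossing = np.nonzero(np.diff((ms >= 50.0).astype(int)))[0]
    if crossing.size:
        i = crossing[0]
        frac = (50.0 - ms[i]) / (ms[i + 1] - ms[i])
        ec50_start = cs[i] + frac * (cs[i + 1] - cs[i])
        ec50_start = float(np.clip(ec50_start, cs[0] / 10, cs[-1] * 10))
    else:
        ec50_start = float(np.median(cs))

    def residuals(theta):
        return _hill(c, theta[0], theta[1]) - m

    best = None
    for h0 in SLOPE_STARTS:
        sol = least_squares(residuals, x0=[ec50_start, h0],
                            bounds=([1e-6, 1e-3], [1e4, 50.0]))
        ss = float(2.0 * sol.cost)
        if best is None or ss < best[0]:
            best = (ss, sol)
    ss, sol = best
    ec50, slope = float(sol.x[0]), float(sol.x[1])
    fitted = _hill(c, ec50, slope)
    ok = bool(sol.success) and slope > 0 and r_squared(m, fitted) > 0
    return HillFit(ec50=ec50, slope=slope, residual_ss=ss, converged=ok)


def predict_mortality(fit: HillFit, dose) -> np.ndarray | float:
    """Hill-curve mortality (%): 0 at dose 0, → 100 as dose → ∞."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise DataError("dose must be >= 0")
    out = _hill(d, fit.ec50, fit.slope)
    return float(out) if np.isscalar(dose) else out


def survival_from_colonies(counts: pd.DataFrame, control_dose: float = 0.0) -> MortalityTable:
    """Convert colony counts to mortality relative to the control well.

    ``counts`` needs columns ``dose`` and ``colonies``; mortality% =
    100 · (1 − colonies/colonies_control), clipped to [0, 100].
    """
    if not {"dose", "colonies"} <= set(counts.columns):
        raise DataError("counts needs 'dose' and 'colonies' columns")
    control = counts.loc[counts["dose"] == control_dose, "colonies"]
    if control.empty:
        raise ControlReferenceError(f"no control row at dose {control_dose:g}")
    c0 = float(control.iloc[0])
    if c0 <= 0:
        raise ControlReferenceError("control colony count must be > 0")
    mortality = 100.0 * (1.0 - counts["colonies"].to_numpy(dtype=float) / c0)
    return MortalityTable(
        concentration=counts["dose"].to_numpy(dtype=float),
        mortality_pct=np.clip(mortality, 0.0, 100.0),
    )
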