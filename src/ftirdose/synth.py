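"""Synthetic dose-structured cell FTIR spectra and clonogenic assay data.

The generator emulates the statistical structure that the downstream
analysis assumes for cisplatin-exposed HepG2 cells:

* each spectrum is a sum of Gaussian vibrational bands on the working
  1000–3000 cm⁻¹ grid;
* DNA-binding band shifts (guanine 1725→1713, thymine 1665→1657 cm⁻¹)
  switch on above ~1.5 µg/mL and the protein amide β-sheet shift
  (1639→1624 cm⁻¹) above ~2 µg/mL, modelled as logistic transitions of
  the band centre (and amplitude) in dose;
* two difference-spectrum marker features — a positive excess at
  1648 cm⁻¹ and a negative deficit at 1490 cm⁻¹ in exposed relative to
  control cells — whose magnitudes decay linearly with dose to 20 % of
  their 0.125 µg/mL value at 4 µg/mL;
* replicate-level nuisance: additive Gaussian noise, a random linear
  baseline, and multiplicative scale jitter;
* a clonogenic mortality curve following a two-parameter Hill law with
  binomially distributed colony counts.

The default design is nine concentrations (0, 0.125, 0.25, 0.5, 1, 1.5,
2, 3, 4 µg/mL) with seven replicates each. Setting every noise term to
zero yields the deterministic noise-free spectrum used by worked
examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ControlReferenceError, ParameterError
from .spectra import Spectrum, SpectrumCollection, WavenumberGrid, default_grid

DEFAULT_CONCENTRATIONS = (0.0, 0.125, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0)

# Dose range over which the difference-spectrum marker amplitudes decay.
_BIS_REF_DOSE = 0.125
_BIS_MAX_DOSE = 4.0
_BIS_FLOOR = 0.2


def logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian vibrational band and its dose behaviour.

    The centre moves from ``center_low`` (unexposed) to ``center_high``
    (saturating dose) along a logistic transition with midpoint
    ``threshold`` (µg/mL) and steepness in (µg/mL)⁻¹; the base amplitude
    is interpolated identically between ``amp_low`` and ``amp_high``.
    ``bis_excess`` is a signed exposure-only amplitude increment (its
    value at the 0.125 µg/mL reference dose) that decays linearly to 20 %
    at 4 µg/mL — this is what creates the difference-spectrum markers.
    Bands with no reported shift have center_low == center_high.
    """

    name: str
    center_low: float
    center_high: float
    amp_low: float
    amp_high: float
    sigma: float = 4.0
    threshold: float = 1.5
    steepness: float = 8.0
    bis_excess: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError(f"band {self.name}: sigma must be > 0")
        if self.amp_low < 0 or self.amp_high < 0:
            raise ParameterError(f"band {self.name}: amplitudes must be >= 0")
        if self.threshold < 0:
            raise ParameterError(f"band {self.name}: threshold must be >= 0")


def _band(name, center, amp, **kw):
    """Helper for an unshifted band (center_low == center_high)."""
    return BandSpec(name, center, center, amp, amp, **kw)


def default_band_table() -> list[BandSpec]:
    """The band table anchoring the simulator to reported HepG2 spectroscopy.

    DNA base ring vibrations: guanine 1725 cm⁻¹ (shifting to 1713 above
    ~1.5 µg/mL, platinum binding at N7), thymine 1665→1657 (O2 binding),
    adenine 1613 and cytosine 1499 (no shift). Protein amide β-sheet at
    1639 shifting to 1624 above ~2 µg/mL. Phosphate asymmetric/symmetric
    stretches at 1228/1087 with no major shift. Marker components at 1648
    (exposure excess, positive in difference spectra) and 1490 (exposure
    deficit, negative). C–H stretch bands near 2852/2923/2958 cm⁻¹
    populate the upper window; 2000–2500 cm⁻¹ is left silent.
    """
    return [
        BandSpec("guanine", 1725.0, 1713.0, 0.30, 0.30, threshold=1.5),
        BandSpec("thymine", 1665.0, 1657.0, 0.65, 0.65, threshold=1.5),
        _band("adenine", 1613.0, 0.35),
        _band("cytosine", 1499.0, 0.25),
        BandSpec("amide_beta_sheet", 1639.0, 1624.0, 0.70, 0.70, threshold=2.0),
        _band("phosphate_asym", 1228.0, 0.55),
        _band("phosphate_sym", 1087.0, 0.65),
        _band("bis_marker_1648", 1648.0, 0.10, bis_excess=+0.10),
        _band("bis_marker_1490", 1490.0, 0.15, bis_excess=-0.08),
        _band("ch2_sym_stretch", 2852.0, 0.35),
        _band("ch2_asym_stretch", 2923.0, 0.50),
        _band("ch3_asym_stretch", 2958.0, 0.30),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to generate a reproducible spectral design."""

    bands: tuple = field(default_factory=lambda: tuple(default_band_table()))
    grid: WavenumberGrid = field(default_factory=default_grid)
    noise_sd: float = 0.0035  # ~0.5 % of the ~0.71 peak absorbance
    baseline_offset_sd: float = 0.02
    baseline_slope_sd: float = 1e-5  # per cm^-1
    scale_jitter_sd: float = 0.02
    concentrations: tuple = DEFAULT_CONCENTRATIONS
    n_replicates: int = 7
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "concentrations", tuple(float(c) for c in self.concentrations))
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        for sd in (self.noise_sd, self.baseline_offset_sd, self.baseline_slope_sd,
                   self.scale_jitter_sd):
            if sd < 0:
                raise ParameterError("noise standard deviations must be >= 0")

    @property
    def is_noise_free(self) -> bool:
        return (self.noise_sd == 0 and self.baseline_offset_sd == 0
                and self.baseline_slope_sd == 0 and self.scale_jitter_sd == 0)


def noise_free(config: GeneratorConfig) -> GeneratorConfig:
    """A copy of ``config`` with every stochastic term switched off."""
    return replace(config, noise_sd=0.0, baseline_offset_sd=0.0,
                   baseline_slope_sd=0.0, scale_jitter_sd=0.0)


def _bis_excess_fraction(dose: float) -> float:
    """Linear decay from 1 at the 0.125 µg/mL reference to 0.2 at 4 µg/mL."""
    frac = 1.0 - (1.0 - _BIS_FLOOR) * (dose - _BIS_REF_DOSE) / (_BIS_MAX_DOSE - _BIS_REF_DOSE)
    return max(frac, _BIS_FLOOR)


def band_center_at_dose(band: BandSpec, dose: float) -> float:
    """Band centre (cm⁻¹) at a given dose via the logistic transition."""
    if dose < 0:
        raise ParameterError(f"dose must be >= 0, got {dose}")
    f = float(logistic(band.steepness * (dose - band.threshold)))
    return band.center_low + (band.center_high - band.center_low) * f


def band_amplitude_at_dose(band: BandSpec, dose: float) -> float:
    """Band amplitude at a given dose (logistic base + marker excess)."""
    if dose < 0:
        raise ParameterError(f"dose must be >= 0, got {dose}")
    f = float(logistic(band.steepness * (dose - band.threshold)))
    amp = band.amp_low + (band.amp_high - band.amp_low) * f
    if band.bis_excess != 0.0 and dose > 0:
        amp += band.bis_excess * _bis_excess_fraction(dose)
    return max(amp, 0.0)


def ideal_spectrum_values(dose: float, config: GeneratorConfig) -> np.ndarray:
    """Deterministic noise-free absorbance trace at ``dose``."""
    x = config.grid.values
    total = np.zeros_like(x)
    for band in config.bands:
        c = band_center_at_dose(band, dose)
        a = band_amplitude_at_dose(band, dose)
        if a == 0.0:
            continue
        total += a * np.exp(-0.5 * ((x - c) / band.sigma) ** 2)
    return total


def generate_spectrum(dose: float, config: GeneratorConfig, rng=None,
                      replicate_id: int = 1) -> Spectrum:
    """One replicate spectrum: bands + baseline + scale jitter + noise.

    With all noise terms zero the result is deterministic and ``rng`` is
    ignored; otherwise ``rng`` (a numpy Generator) is required.
    """
    values = ideal_spectrum_values(dose, config)
    if not config.is_noise_free:
        if rng is None:
            raise ParameterError("rng is required when noise terms are non-zero")
        x = config.grid.values
        if config.scale_jitter_sd > 0:
            values = values * (1.0 + rng.normal(0.0, config.scale_jitter_sd))
        offset = rng.normal(0.0, config.baseline_offset_sd) if config.baseline_offset_sd > 0 else 0.0
        slope = rng.normal(0.0, config.baseline_slope_sd) if config.baseline_slope_sd > 0 else 0.0
        values = values + offset + slope * (x - x.mean())
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, size=x.size)
        values = np.maximum(values, 0.0)  # absorbance floor
    return Spectrum(config.grid, values, dose=dose, replicate_id=replicate_id,
                    label=f"dose={dose:g}")


def generate_design(config: GeneratorConfig) -> SpectrumCollection:
    """The full replicated design, deterministic given ``config.seed``.

    Defaults give 9 concentrations × 7 replicates = 63 raw spectra; the
    56 rows the regression sees arise downstream when the control group
    is consumed as the difference-spectrum reference.
    """
    rng = np.random.default_rng(config.seed)
    spectra = []
    for dose in config.concentrations:
        for rep in range(1, config.n_replicates + 1):
            spectra.append(generate_spectrum(dose, config, rng=rng, replicate_id=rep))
    return SpectrumCollection(spectra)


# ---------------------------------------------------------------------------
# Clonogenic assay


@dataclass(frozen=True)
class HillParams:
    """Ground-truth mortality curve: mortality% = 100·cʰ/(ec50ʰ + cʰ)."""

    ec50: float = 0.3
    slope: float = 1.6
    upper: float = 100.0
    lower: float = 0.0

    def __post_init__(self):
        if self.ec50 <= 0 or self.slope <= 0:
            raise ParameterError("ec50 and slope must be > 0")


def hill_mortality(dose, params: HillParams):
    """Expected mortality (%) under the Hill law; 0 at dose 0."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        m = params.upper * d ** params.slope / (
            params.ec50 ** params.slope + d ** params.slope
        )
    return m + params.lower


def simulate_clonogenic(doses, n_cells: int, params: HillParams, rng) -> pd.DataFrame:
    """Colony counts and mortality for a clonogenic survival assay.

    ``n_cells`` cells are seeded per well; colonies ~ Binomial(n_cells,
    survival(dose)) with survival = 1 − Hill(dose)/100. Mortality is
    expressed relative to the colonies counted in the unexposed control
    well, as in the assay's standard readout.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    doses = [float(d) for d in doses]
    if not any(d == 0.0 for d in doses):
        raise ControlReferenceError("clonogenic design must include a 0-dose control")
    survival = 1.0 - hill_mortality(np.array(doses), params) / 100.0
    colonies = np.array([rng.binomial(n_cells, max(min(s, 1.0), 0.0)) for s in survival])
    control = colonies[doses.index(0.0)]
    if control == 0:
        raise ControlReferenceError("control well produced zero colonies")
    mortality = 100.0 * (1.0 - colonies / control)
    mortality = np.clip(mortality, 0.0, 100.0)
    return pd.DataFrame({"dose": doses, "colonies": colonies, "mortality_pct": mortality})
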