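"""Bee photoreceptor sensitivities, illuminants and quantum catches.

Trichromatic bees sample the 300–700 nm window with three receptor classes
whose peak sensitivities sit near 347 nm (UV), 424 nm (blue) and 539 nm
(green).  Only those peak positions are fixed by measurement; the full
sensitivity curves S_i(λ) are reconstructed here with the standard A1
visual-pigment template of Govardovskii et al. (2000), which parameterises
an opsin's α-band (and optionally its β-band) as a function of the peak
wavelength alone.

The photon capture of receptor class i viewing a surface with reflectance
R(λ) under an illuminant with relative photon flux I(λ) is the quantum catch

    Q_i = ∫ I(λ) S_i(λ) R(λ) dλ   over 300–700 nm.

Receptors adapt to the prevailing background (green foliage for a foraging
bee): the von Kries step divides each catch by the catch for the adaptation
background, and a hyperbolic (Michaelis–Menten) transduction maps the ratio
into a bounded excitation E = q/(q+1) with E = 0.5 at the background itself.
Any rescaling of the illuminant cancels in the ratio, which is what makes
the downstream colour coordinates intensity-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import ReflectanceSpectrum, WavelengthGrid

__all__ = [
    "SensitivityCurve",
    "ReceptorSet",
    "Illuminant",
    "QuantumCatchVector",
    "BEE_PEAKS_NM",
    "pigment_template",
    "default_bee_receptors",
    "d65_illuminant",
    "equal_energy_illuminant",
    "make_illuminant",
    "quantum_catch",
    "catch_vector",
    "adapted_excitation",
]

#: Peak sensitivities (nm) of the generic trichromatic bee receptor set.
BEE_PEAKS_NM: tuple[float, float, float] = (347.0, 424.0, 539.0)

#: Integration window (nm) for quantum catches.
INTEGRATION_SPAN: tuple[float, float] = (300.0, 700.0)


@dataclass(frozen=True)
class SensitivityCurve:
    """One receptor class sensitivity S(λ), normalised to peak 1."""

    grid: WavelengthGrid
    sensitivity: np.ndarray
    lambda_max: float

    def __post_init__(self) -> None:
        sens = np.asarray(self.sensitivity, dtype=float)
        object.__setattr__(self, "sensitivity", sens)
        if sens.shape != self.grid.values.shape:
            raise ValueError("sensitivity and grid lengths differ")
        if sens.min() < 0:
            raise ValueError("sensitivity must be non-negative")
        nearest = int(np.argmin(np.abs(self.grid.values - self.lambda_max)))
        # curves are normalised to the continuous peak, so on a coarse grid
        # the discrete maximum may fall a whisker short of exactly 1
        if abs(sens[nearest] - sens.max()) > 1e-3 or abs(sens.max() - 1.0) > 1e-3:
            raise ValueError("curve must peak at 1 at the grid point nearest lambda_max")


@dataclass(frozen=True)
class ReceptorSet:
    """UV, blue and green sensitivity curves on one shared grid."""

    uv: SensitivityCurve
    blue: SensitivityCurve
    green: SensitivityCurve

    def __post_init__(self) -> None:
        if not (self.uv.grid == self.blue.grid == self.green.grid):
            raise ValueError("receptor curves must share a grid")
        if not (self.uv.lambda_max < self.blue.lambda_max < self.green.lambda_max):
            raise ValueError("peaks must be ordered uv < blue < green")

    @property
    def grid(self) -> WavelengthGrid:
        return self.uv.grid

    @property
    def curves(self) -> tuple[SensitivityCurve, SensitivityCurve, SensitivityCurve]:
        return (self.uv, self.blue, self.green)


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral photon flux I(λ), unitless and non-negative."""

    grid: WavelengthGrid
    irradiance: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        irr = np.asarray(self.irradiance, dtype=float)
        object.__setattr__(self, "irradiance", irr)
        if irr.shape != self.grid.values.shape:
            raise ValueError("irradiance and grid lengths differ")
        if irr.min() < 0 or not np.all(np.isfinite(irr)):
            raise ValueError("irradiance must be finite and non-negative")
        lo, hi = self.grid.span
        if lo > INTEGRATION_SPAN[0] or hi < INTEGRATION_SPAN[1]:
            raise ValueError("illuminant must span at least 300-700 nm")

    def scaled(self, factor: float) -> "Illuminant":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, irradiance=self.irradiance * factor)


@dataclass(frozen=True)
class QuantumCatchVector:
    """Per-class photon captures (q_uv, q_blue, q_green)."""

    q_uv: float
    q_blue: float
    q_green: float

    def __post_init__(self) -> None:
        for q in (self.q_uv, self.q_blue, self.q_green):
            if not np.isfinite(q) or q < 0:
                raise ValueError("quantum catches must be finite and non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.q_uv, self.q_blue, self.q_green])


# Govardovskii et al. (2000) A1 alpha-band constants.
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


def _alpha_band(wl: np.ndarray, lambda_max: float) -> np.ndarray:
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )


def _beta_band(wl: np.ndarray, lambda_max: float) -> np.ndarray:
    lam_beta = 189.0 + 0.315 * lambda_max
    bandwidth = -40.5 + 0.195 * lambda_max
    return 0.26 * np.exp(-(((wl - lam_beta) / bandwidth) ** 2))


def pigment_template(
    lambda_max: float, grid: WavelengthGrid, *, beta_band: bool = False
) -> SensitivityCurve:
    """A1 visual-pigment sensitivity template, peak-normalised to 1.

    Parameters
    ----------
    lambda_max:
        Peak wavelength in nm; must lie in 300–650 and inside the grid span.
    grid:
        Wavelengths at which to evaluate the template.
    beta_band:
        Include the secondary (β) absorption band.  Off by default: for a UV
        receptor the β-band sits below the sampled window, and for the blue
        and green receptors its contribution is small against the α-band.
    """
    if not 300.0 <= lambda_max <= 650.0:
        raise ValueError("lambda_max must lie in 300-650 nm")
    lo, hi = grid.span
    if not lo <= lambda_max <= hi:
        raise ValueError(f"grid [{lo}, {hi}] does not cover lambda_max {lambda_max}")
    wl = grid.values

    def raw(w: np.ndarray) -> np.ndarray:
        s = _alpha_band(w, lambda_max)
        if beta_band:
            s = s + _beta_band(w, lambda_max)
        return s

    # normalise by the continuous peak (dense window around lambda_max) so
    # the curve is independent of the evaluation grid
    dense = np.arange(lambda_max - 15.0, lambda_max + 15.0, 0.01)
    sens = np.minimum(raw(wl) / raw(dense).max(), 1.0)
    return SensitivityCurve(grid=grid, sensitivity=sens, lambda_max=lambda_max)


def default_bee_receptors(
    grid: WavelengthGrid | None = None, *, beta_band: bool = False
) -> ReceptorSet:
    """Generic trichromatic bee receptor set with peaks at 347/424/539 nm."""
    if grid is None:
        grid = WavelengthGrid.regular(300.0, 700.0, 1.0)
    uv, blue, green = (
        pigment_template(peak, grid, beta_band=beta_band) for peak in BEE_PEAKS_NM
    )
    return ReceptorSet(uv=uv, blue=blue, green=green)


# CIE standard illuminant D65 relative spectral power, 300-700 nm at 10 nm.
_D65_WL = np.arange(300.0, 701.0, 10.0)
_D65_SPD = np.array([
    0.034, 3.294, 20.236, 37.054, 39.949, 44.912, 46.638, 52.089, 49.975,
    54.648, 82.755, 91.486, 93.432, 86.682, 104.865, 117.008, 117.812,
    114.861, 115.923, 108.811, 109.354, 107.802, 104.790, 107.689, 104.405,
    104.046, 100.000, 96.334, 95.788, 88.685, 90.006, 89.599, 87.698,
    83.288, 83.699, 80.026, 80.120, 82.277, 78.284, 69.721, 71.609,
])


def d65_illuminant(grid: WavelengthGrid | None = None) -> Illuminant:
    """Standard daylight (D65) as relative photon flux on the given grid.

    The tabulated D65 curve is an energy spectrum; photon flux is obtained by
    weighting with λ (a photon's energy is hc/λ), then renormalising to 1 at
    the maximum.  Absolute level is irrelevant downstream thanks to the
    von Kries step.
    """
    if grid is None:
        grid = WavelengthGrid.regular(300.0, 700.0, 1.0)
    energy = np.interp(grid.values, _D65_WL, _D65_SPD)
    photons = energy * grid.values
    return Illuminant(grid=grid, irradiance=photons / photons.max(), name="d65_300_700")


def equal_energy_illuminant(grid: WavelengthGrid | None = None) -> Illuminant:
    """Flat equal-energy illuminant (I ≡ 1)."""
    if grid is None:
        grid = WavelengthGrid.regular(300.0, 700.0, 1.0)
    return Illuminant(grid=grid, irradiance=np.ones(len(grid)), name="equal_energy")


def make_illuminant(kind: str, grid: WavelengthGrid | None = None) -> Illuminant:
    factories = {"d65_300_700": d65_illuminant, "equal_energy": equal_energy_illuminant}
    if kind not in factories:
        raise ValueError(f"unknown illuminant {kind!r}; choose from {sorted(factories)}")
    return factories[kind](grid)


def quantum_catch(
    s: ReflectanceSpectrum, sens: SensitivityCurve, ill: Illuminant
) -> float:
    """Trapezoid integral of I(λ)·S(λ)·R(λ) over 300–700 nm.

    All three inputs must already live on one common grid (resample first);
    a grid mismatch is an error rather than a silent interpolation.
    """
    if not (s.grid == sens.grid == ill.grid):
        raise ValueError("spectrum, sensitivity and illuminant must share a grid")
    wl = s.grid.values
    mask = (wl >= INTEGRATION_SPAN[0]) & (wl <= INTEGRATION_SPAN[1])
    if wl[mask].size < 2 or wl[mask][0] > INTEGRATION_SPAN[0] or wl[mask][-1] < INTEGRATION_SPAN[1]:
        raise ValueError("common grid must cover 300-700 nm")
    integrand = ill.irradiance[mask] * sens.sensitivity[mask] * s.reflectance[mask]
    return float(np.trapezoid(integrand, wl[mask]))


def catch_vector(
    s: ReflectanceSpectrum, receptors: ReceptorSet, ill: Illuminant
) -> QuantumCatchVector:
    qs = [quantum_catch(s, curve, ill) for curve in receptors.curves]
    return QuantumCatchVector(*qs)


def adapted_excitation(q: float, q_background: float) -> float:
    """Von Kries adapted, hyperbolically transduced excitation.

    E = (q/q_b) / (q/q_b + 1), so E ∈ [0, 1), E = 0 for a black surface and
    E = 0.5 exactly when the stimulus matches the adaptation background.
    """
    if q_background <= 0:
        raise ValueError("background quantum catch must be positive")
    if q < 0:
        raise ValueError("quantum catch must be non-negative")
    ratio = q / q_background
    return ratio / (ratio + 1.0)
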