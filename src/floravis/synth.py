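"""Synthetic floral reflectance archetypes with measurement noise.

Five spectral shapes recur in strawberry flower/leaf measurements and are
emulated here as parametric idealisations (sums of a baseline plus logistic
edges, Gaussian bumps and a compact-support near-UV feature, clipped to
[0, 1]):

* ``white_petal`` — high broadband plateau above ~410 nm, low near-UV;
* ``green_leaf`` — low baseline with a chlorophyll-window bump near 550 nm;
* ``red_petal`` — reflectance only beyond a ~585 nm edge (a red invisible to bees);
* ``anther_yellow`` — plateau from ~505 nm (yellow anther/stamen disk);
* ``uv_bullseye_center`` / ``uv_bullseye_periphery`` — a pair identical
  outside 300–380 nm, differing only in a raised-cosine UV feature
  (absorbing centre, reflecting periphery).

Scenario builders assemble whole labelled cultivars from these archetypes so
the full contrast pipeline can run without any downloaded data.  Noise is
independent zero-mean Gaussian per wavelength — real spectrophotometer noise
is wavelength-correlated, a simplification noted in the methods note.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .pipeline import CultivarDataset
from .spectra import FloralPart, ReflectanceSpectrum, WavelengthGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumArchetype",
    "NoiseModel",
    "ARCHETYPE_DEFAULTS",
    "SCENARIOS",
    "make_archetype",
    "add_measurement_noise",
    "make_synthetic_cultivar",
    "write_demo",
]


def _logistic(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - center) / width))


def _gaussian(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _uv_feature(wl: np.ndarray, lo: float = 304.0, hi: float = 378.0) -> np.ndarray:
    """Raised-cosine bump exactly zero outside [lo, hi] (compact support)."""
    t = (wl - lo) / (hi - lo)
    bump = np.where((t >= 0) & (t <= 1), np.sin(np.pi * np.clip(t, 0, 1)) ** 2, 0.0)
    return bump


# Component amplitudes/centres/widths, all in reflectance fraction and nm.
ARCHETYPE_DEFAULTS: dict[str, dict[str, float]] = {
    "white_petal": {"baseline": 0.04, "amp": 0.82, "edge": 412.0, "width": 10.0},
    "green_leaf": {"baseline": 0.05, "amp": 0.18, "center": 550.0, "sigma": 40.0},
    "red_petal": {"baseline": 0.06, "amp": 0.60, "edge": 585.0, "width": 10.0},
    "anther_yellow": {"baseline": 0.05, "amp": 0.55, "edge": 505.0, "width": 16.0},
    "uv_bullseye_center": {
        "baseline": 0.04, "amp": 0.78, "edge": 412.0, "width": 10.0, "uv_amp": 0.02,
    },
    "uv_bullseye_periphery": {
        "baseline": 0.04, "amp": 0.78, "edge": 412.0, "width": 10.0, "uv_amp": 0.30,
    },
}


@dataclass(frozen=True)
class SpectrumArchetype:
    """A named spectral shape plus its component parameters."""

    kind: str
    parameters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPE_DEFAULTS:
            raise ValueError(
                f"unknown archetype {self.kind!r}; choose from {sorted(ARCHETYPE_DEFAULTS)}"
            )

    def resolved(self) -> dict[str, float]:
        params = dict(ARCHETYPE_DEFAULTS[self.kind])
        params.update(self.parameters)
        return params


@dataclass(frozen=True)
class NoiseModel:
    """Seeded Gaussian measurement noise (reflectance-fraction sd)."""

    sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")


def make_archetype(
    kind: str | SpectrumArchetype,
    grid: WavelengthGrid | None = None,
    parameters: dict[str, float] | None = None,
) -> ReflectanceSpectrum:
    """Evaluate a spectral archetype on a grid (defaults: 300–700 nm, 1 nm)."""
    arch = kind if isinstance(kind, SpectrumArchetype) else SpectrumArchetype(kind, parameters or {})
    if grid is None:
        grid = WavelengthGrid.regular(300.0, 700.0, 1.0)
    p = arch.resolved()
    wl = grid.values
    if arch.kind in ("white_petal", "red_petal", "anther_yellow"):
        values = p["baseline"] + p["amp"] * _logistic(wl, p["edge"], p["width"])
    elif arch.kind == "green_leaf":
        values = p["baseline"] + p["amp"] * _gaussian(wl, p["center"], p["sigma"])
    elif arch.kind in ("uv_bullseye_center", "uv_bullseye_periphery"):
        values = (
            p["baseline"]
            + p["amp"] * _logistic(wl, p["edge"], p["width"])
            + p["uv_amp"] * _uv_feature(wl)
        )
    else:  # pragma: no cover - guarded by SpectrumArchetype
        raise ValueError(arch.kind)
    if values.min() < 0 or values.max() > 1:
        logger.warning(
            "archetype %s produced values outside [0, 1] (min %.3f, max %.3f); clipping",
            arch.kind, values.min(), values.max(),
        )
        values = np.clip(values, 0.0, 1.0)
    return ReflectanceSpectrum(grid=grid, reflectance=values, label=arch.kind)


def add_measurement_noise(s: ReflectanceSpectrum, noise: NoiseModel) -> ReflectanceSpectrum:
    """Add independent zero-mean Gaussian noise, clipped to [0, 1].

    The realisation is fully determined by the noise model's seed.
    """
    if noise.sd >= 0.1:
        raise ValueError("noise sd must stay below 0.1 reflectance fraction")
    if noise.sd == 0:
        return s
    rng = np.random.default_rng(noise.seed)
    noisy = np.clip(s.reflectance + rng.normal(0.0, noise.sd, s.reflectance.size), 0.0, 1.0)
    return s.with_values(noisy)


# Scenario part recipes: (part, archetype kind, parameter overrides).
# Amplitudes step down from the strongly reflective commercial white petals
# through the dimmer wild-type petal to the bee-dark red cultivar; sepals are
# foliage-like but slightly offset from the leaf proper.
_SEPAL = ("green_leaf", {"baseline": 0.065, "amp": 0.22, "center": 552.0})

SCENARIOS: dict[str, list[tuple[FloralPart, str, dict[str, float]]]] = {
    "wild_type": [
        (FloralPart.PETAL, "white_petal", {"amp": 0.45}),
        (FloralPart.ANTHER_SEPAL_DISK, "anther_yellow", {"amp": 0.50}),
        (FloralPart.LEAF_UPPER, "green_leaf", {}),
    ],
    "white_high_contrast": [
        (FloralPart.PETAL, "white_petal", {"amp": 0.90}),
        (FloralPart.ANTHER, "anther_yellow", {}),
        (FloralPart.SEPAL, _SEPAL[0], _SEPAL[1]),
        (FloralPart.LEAF_UPPER, "green_leaf", {}),
    ],
    "white_medium_contrast": [
        (FloralPart.PETAL, "white_petal", {"amp": 0.62}),
        (FloralPart.ANTHER, "anther_yellow", {}),
        (FloralPart.SEPAL, _SEPAL[0], _SEPAL[1]),
        (FloralPart.LEAF_UPPER, "green_leaf", {}),
    ],
    "red_blind": [
        (FloralPart.PETAL, "red_petal", {}),
        (FloralPart.ANTHER, "red_petal", {"amp": 0.56, "edge": 586.0}),
        # dull foliage-like sepal: every structure of this cultivar sits close
        # to the leaf background in bee colour space
        (FloralPart.SEPAL, "green_leaf", {"baseline": 0.055, "amp": 0.19, "center": 551.0}),
        (FloralPart.LEAF_UPPER, "green_leaf", {}),
    ],
    "bullseye": [
        (FloralPart.PETAL, "uv_bullseye_periphery", {}),
        (FloralPart.ANTHER, "uv_bullseye_center", {}),
        (FloralPart.SEPAL, _SEPAL[0], _SEPAL[1]),
        (FloralPart.LEAF_UPPER, "green_leaf", {}),
    ],
}


def make_synthetic_cultivar(
    scenario: str,
    seed: int = 0,
    *,
    grid: WavelengthGrid | None = None,
    noise_sd: float = 0.005,
) -> CultivarDataset:
    """Build a labelled synthetic cultivar dataset for one scenario.

    Scenarios mirror the qualitative structure of measured strawberry
    cultivars: a wild type (petal, joint anther+sepal disk, leaf), two white
    cultivars of differing petal brightness, a bee-dark red cultivar, and a
    UV-bullseye pattern.  Identical (scenario, seed) pairs produce identical
    datasets.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    if grid is None:
        grid = WavelengthGrid.regular(300.0, 700.0, 1.0)
    scenario_tag = zlib.crc32(scenario.encode())  # stable across processes
    root = np.random.SeedSequence([scenario_tag, seed])
    part_seeds = root.generate_state(len(SCENARIOS[scenario]))
    spectra: dict[FloralPart, ReflectanceSpectrum] = {}
    for (part, kind, params), pseed in zip(SCENARIOS[scenario], part_seeds):
        clean = make_archetype(kind, grid, params)
        noisy = add_measurement_noise(clean, NoiseModel(sd=noise_sd, seed=int(pseed)))
        spectra[part] = ReflectanceSpectrum(
            grid=grid,
            reflectance=noisy.reflectance,
            label=f"{scenario}:{part.code}",
            part=part,
            specimen_id=scenario,
        )
    return CultivarDataset(
        cultivar=scenario,
        spectra=spectra,
        replicate_counts={part: 1 for part in spectra},
    )


def write_demo(out_dir, seed: int = 0, scenarios: list[str] | None = None) -> str:
    """Write per-scenario spectrum CSVs plus a manifest consumable by the
    cultivar pipeline; returns the manifest path."""
    import yaml
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, list[str]]] = {}
    for scenario in scenarios or sorted(SCENARIOS):
        ds = make_synthetic_cultivar(scenario, seed)
        entry: dict[str, list[str]] = {}
        for part, spectrum in ds.spectra.items():
            path = out / f"{scenario}_{part.value}.csv"
            import pandas as pd

            pd.DataFrame(
                {"wavelength_nm": spectrum.grid.values, part.code: 100.0 * spectrum.reflectance}
            ).to_csv(path, index=False)
            entry[part.value] = [path.name]
        manifest[scenario] = entry
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump({"cultivars": manifest}, sort_keys=False))
    return str(manifest_path)
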