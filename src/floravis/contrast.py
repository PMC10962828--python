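"""Normalised-segment colour coordinates and pairwise contrast ΔS.

A stimulus is reduced to a point with three adapted receptor excitations
(e_uv, e_blue, e_green) plus an achromatic brightness term, the mean of the
three.  Contrast between two stimuli is the Euclidean distance between their
points, scaled onto the behavioural ΔS axis on which honeybees have been
shown to detect flowers against foliage at values as low as 2.3:

    ΔS = scale · sqrt( w_c Σ_i (e_i1 − e_i2)² + w_b (B1 − B2)² )

With the default unit weights this is a metric (non-negative, symmetric,
triangle inequality), zero exactly for identical points.  The single scale
factor is the model's only calibrated constant; see the methods note for how
the default was anchored.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

from .receptors import (
    BEE_PEAKS_NM,
    Illuminant,
    ReceptorSet,
    adapted_excitation,
    catch_vector,
)
from .spectra import FloralPart, ReflectanceSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "NSCPoint",
    "ContrastRecord",
    "DetectionThreshold",
    "ModelConfig",
    "DEFAULT_SCALE",
    "TABLE_PAIR_ORDER",
    "nsc_coordinates",
    "delta_s",
    "classify_detectable",
    "pairwise_contrast_table",
]

#: Default ΔS scale factor; calibrated once so that the synthetic
#: wild-strawberry leaf/petal contrast lands at the magnitude reported for
#: that pair in behavioural-model studies (ΔS ≈ 8.9).  See docs/methods.md.
DEFAULT_SCALE = 18.6

#: Canonical report order for floral-part pairs.
TABLE_PAIR_ORDER: tuple[tuple[FloralPart, FloralPart], ...] = (
    (FloralPart.ANTHER, FloralPart.SEPAL),
    (FloralPart.ANTHER, FloralPart.PETAL),
    (FloralPart.SEPAL, FloralPart.PETAL),
    (FloralPart.LEAF_UPPER, FloralPart.PETAL),
    (FloralPart.ANTHER_SEPAL_DISK, FloralPart.PETAL),
)


@dataclass(frozen=True)
class DetectionThreshold:
    """Behavioural detection threshold on the ΔS axis (default 2.3)."""

    value: float = 2.3
    provenance: str = "honeybee 75%-detection threshold against foliage"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("detection threshold must be positive")


@dataclass(frozen=True)
class ModelConfig:
    """Complete vision-model configuration; hashable into a config id."""

    receptor_peaks: tuple[float, float, float] = BEE_PEAKS_NM
    illuminant: str = "d65_300_700"
    background: str = "own_leaf"
    span: tuple[float, float] = (300.0, 700.0)
    scale: float = DEFAULT_SCALE
    w_chroma: float = 1.0
    w_bright: float = 1.0
    threshold: DetectionThreshold = field(default_factory=DetectionThreshold)
    beta_band: bool = False

    @property
    def config_id(self) -> str:
        payload = (
            f"peaks={self.receptor_peaks};ill={self.illuminant};bg={self.background};"
            f"span={self.span};scale={self.scale};wc={self.w_chroma};wb={self.w_bright};"
            f"thr={self.threshold.value};beta={self.beta_band}"
        )
        return "nsc-" + hashlib.sha1(payload.encode()).hexdigest()[:8]

    def snapshot(self) -> dict:
        return {
            "config_id": self.config_id,
            "receptor_peaks_nm": list(self.receptor_peaks),
            "illuminant": self.illuminant,
            "background": self.background,
            "integration_span_nm": list(self.span),
            "scale": self.scale,
            "w_chroma": self.w_chroma,
            "w_bright": self.w_bright,
            "threshold": self.threshold.value,
            "beta_band": self.beta_band,
        }


@dataclass(frozen=True)
class NSCPoint:
    """Chromatic coordinates plus brightness for one stimulus."""

    e_uv: float
    e_blue: float
    e_green: float
    model_config_id: str = "default"

    def __post_init__(self) -> None:
        for e in (self.e_uv, self.e_blue, self.e_green):
            if not math.isfinite(e) or not 0.0 <= e < 1.0:
                raise ValueError("excitations must be finite and in [0, 1)")

    @property
    def brightness(self) -> float:
        """Achromatic term: mean adapted excitation across the three classes."""
        return (self.e_uv + self.e_blue + self.e_green) / 3.0


@dataclass(frozen=True)
class ContrastRecord:
    """A pairwise ΔS with part labels and a detectability flag."""

    label_a: str
    label_b: str
    delta_s: float
    detectable: bool
    model_config_id: str

    def __post_init__(self) -> None:
        if self.delta_s < 0:
            raise ValueError("delta_s must be non-negative")

    @property
    def pair(self) -> str:
        return f"{self.label_a}/{self.label_b}"


def nsc_coordinates(
    s: ReflectanceSpectrum,
    receptors: ReceptorSet,
    ill: Illuminant,
    background: ReflectanceSpectrum,
    config_id: str = "default",
) -> NSCPoint:
    """Quantum catches → background-adapted excitations for one spectrum.

    The background (green foliage by convention) must yield a strictly
    positive catch in every receptor class, otherwise adaptation is
    undefined and the input is rejected as degenerate.
    """
    q = catch_vector(s, receptors, ill)
    q_bg = catch_vector(background, receptors, ill)
    if min(q_bg.as_array()) <= 0:
        raise ValueError("adaptation background has a zero quantum catch")
    e = [
        adapted_excitation(qi, qb)
        for qi, qb in zip(q.as_array(), q_bg.as_array())
    ]
    return NSCPoint(e_uv=e[0], e_blue=e[1], e_green=e[2], model_config_id=config_id)


def delta_s(
    p1: NSCPoint,
    p2: NSCPoint,
    *,
    w_chroma: float = 1.0,
    w_bright: float = 1.0,
    scale: float = DEFAULT_SCALE,
) -> float:
    """Scaled Euclidean contrast between two colour points."""
    if p1.model_config_id != p2.model_config_id:
        raise ValueError(
            f"points computed under different model configs: "
            f"{p1.model_config_id} vs {p2.model_config_id}"
        )
    chroma = (
        (p1.e_uv - p2.e_uv) ** 2
        + (p1.e_blue - p2.e_blue) ** 2
        + (p1.e_green - p2.e_green) ** 2
    )
    bright = (p1.brightness - p2.brightness) ** 2
    return scale * math.sqrt(w_chroma * chroma + w_bright * bright)


def classify_detectable(d: float, thr: DetectionThreshold | float = DetectionThreshold()) -> bool:
    """True iff the contrast reaches the detection threshold (inclusive)."""
    if d < 0:
        raise ValueError("contrast must be non-negative")
    value = thr.value if isinstance(thr, DetectionThreshold) else float(thr)
    return d >= value


def pairwise_contrast_table(
    parts: dict[FloralPart, ReflectanceSpectrum],
    config: ModelConfig,
    receptors: ReceptorSet,
    ill: Illuminant,
    background: ReflectanceSpectrum,
) -> list[ContrastRecord]:
    """ΔS for every canonical floral-part pair available in ``parts``.

    Pairs follow the canonical order (A/S, A/P, S/P, L/P, A+S/P); a pair
    whose parts are missing is skipped with a warning, never fabricated.
    With fewer than two parts the result is an empty list.
    """
    if len(parts) < 2:
        logger.warning("fewer than two parts supplied; no contrasts computed")
        return []
    cid = config.config_id
    points = {
        part: nsc_coordinates(spectrum, receptors, ill, background, config_id=cid)
        for part, spectrum in parts.items()
    }
    records: list[ContrastRecord] = []
    for a, b in TABLE_PAIR_ORDER:
        if a not in points or b not in points:
            logger.warning("pair %s/%s skipped: part missing", a.code, b.code)
            continue
        d = delta_s(
            points[a],
            points[b],
            w_chroma=config.w_chroma,
            w_bright=config.w_bright,
            scale=config.scale,
        )
        records.append(
            ContrastRecord(
                label_a=a.code,
                label_b=b.code,
                delta_s=d,
                detectable=classify_detectable(d, config.threshold),
                model_config_id=cid,
            )
        )
    return records
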