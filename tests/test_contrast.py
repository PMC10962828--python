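"""Colour coordinates, ΔS metric behaviour and detectability calls."""

import numpy as np
import pytest

from floravis.contrast import (
    DetectionThreshold,
    ModelConfig,
    NSCPoint,
    classify_detectable,
    delta_s,
    nsc_coordinates,
    pairwise_contrast_table,
)
from floravis.receptors import adapted_excitation, catch_vector
from floravis.spectra import FloralPart, ReflectanceSpectrum
from floravis.synth import make_archetype


def random_points(n, rng, config_id="default"):
    e = rng.uniform(0.0, 0.999, size=(n, 3))
    return [NSCPoint(*row, model_config_id=config_id) for row in e]


class TestNSCCoordinates:
    def test_background_is_the_fixed_point(self, receptors, d65, leaf):
        p = nsc_coordinates(leaf, receptors, d65, leaf)
        assert (p.e_uv, p.e_blue, p.e_green) == pytest.approx((0.5, 0.5, 0.5))
        assert p.brightness == pytest.approx(0.5)

    def test_black_stimulus_maps_to_origin(self, grid, receptors, d65, leaf):
        black = ReflectanceSpectrum(grid=grid, reflectance=np.zeros(len(grid)))
        p = nsc_coordinates(black, receptors, d65, leaf)
        assert (p.e_uv, p.e_blue, p.e_green, p.brightness) == (0, 0, 0, 0)

    def test_matches_hand_computed_chain(self, grid, receptors, flat, leaf, white_petal):
        # straight-line recomputation: trapezoid catches, ratio transduction
        p = nsc_coordinates(white_petal, receptors, flat, leaf)
        wl = grid.values
        for got, curve in zip((p.e_uv, p.e_blue, p.e_green), receptors.curves):
            q = np.trapezoid(curve.sensitivity * white_petal.reflectance, wl)
            qb = np.trapezoid(curve.sensitivity * leaf.reflectance, wl)
            ratio = q / qb
            assert got == pytest.approx(ratio / (ratio + 1.0), abs=1e-9)
        assert p.brightness == pytest.approx((p.e_uv + p.e_blue + p.e_green) / 3, abs=1e-12)

    def test_degenerate_background_rejected(self, grid, receptors, d65, leaf):
        black = ReflectanceSpectrum(grid=grid, reflectance=np.zeros(len(grid)))
        with pytest.raises(ValueError, match="background"):
            nsc_coordinates(leaf, receptors, d65, background=black)


class TestDeltaS:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        p1, p2 = random_points(2, rng)
        assert delta_s(p1, p1) == 0.0
        assert delta_s(p1, p2) == pytest.approx(delta_s(p2, p1))

    def test_metric_axioms_on_random_point_pairs(self):
        rng = np.random.default_rng(123)
        pts = random_points(3000, rng)
        for i in range(1000):
            a, b, c = pts[3 * i], pts[3 * i + 1], pts[3 * i + 2]
            dab, dba = delta_s(a, b), delta_s(b, a)
            assert dab >= 0.0
            assert dab == pytest.approx(dba, rel=1e-12)
            assert delta_s(a, c) <= dab + delta_s(b, c) + 1e-9
        same = pts[0]
        assert delta_s(same, same) == 0.0

    def test_config_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        (p1,) = random_points(1, rng, config_id="a")
        (p2,) = random_points(1, rng, config_id="b")
        with pytest.raises(ValueError, match="config"):
            delta_s(p1, p2)

    def test_scale_and_weights_enter_linearly_under_sqrt(self):
        p1 = NSCPoint(0.2, 0.4, 0.6)
        p2 = NSCPoint(0.3, 0.5, 0.7)
        assert delta_s(p1, p2, scale=2.0) == pytest.approx(2 * delta_s(p1, p2, scale=1.0))
        d_chroma_only = delta_s(p1, p2, w_bright=0.0, scale=1.0)
        assert d_chroma_only == pytest.approx(np.sqrt(3 * 0.1**2), abs=1e-12)


class TestDetectability:
    @pytest.mark.parametrize(
        "d,expected", [(1.335, False), (2.3, True), (5.261, True), (0.0, False)]
    )
    def test_threshold_rule_inclusive(self, d, expected):
        assert classify_detectable(d, DetectionThreshold()) is expected

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            DetectionThreshold(value=0.0)


class TestPairwiseTable:
    def _parts(self, grid, codes):
        kinds = {
            FloralPart.PETAL: ("white_petal", {}),
            FloralPart.ANTHER: ("anther_yellow", {}),
            FloralPart.SEPAL: ("green_leaf", {"amp": 0.16}),
            FloralPart.LEAF_UPPER: ("green_leaf", {}),
            FloralPart.ANTHER_SEPAL_DISK: ("anther_yellow", {"amp": 0.5}),
        }
        return {
            part: make_archetype(kinds[part][0], grid, kinds[part][1]) for part in codes
        }

    def test_four_part_cultivar_yields_canonical_four_pairs(self, grid, receptors, d65, leaf):
        parts = self._parts(
            grid, [FloralPart.PETAL, FloralPart.ANTHER, FloralPart.SEPAL, FloralPart.LEAF_UPPER]
        )
        records = pairwise_contrast_table(parts, ModelConfig(), receptors, d65, leaf)
        assert [r.pair for r in records] == ["A/S", "A/P", "S/P", "L/P"]

    def test_wild_type_layout_yields_disk_and_leaf_pairs(self, grid, receptors, d65, leaf):
        parts = self._parts(
            grid, [FloralPart.PETAL, FloralPart.ANTHER_SEPAL_DISK, FloralPart.LEAF_UPPER]
        )
        records = pairwise_contrast_table(parts, ModelConfig(), receptors, d65, leaf)
        assert [r.pair for r in records] == ["L/P", "A+S/P"]

    def test_single_part_warns_and_returns_empty(self, grid, receptors, d65, leaf, caplog):
        parts = self._parts(grid, [FloralPart.PETAL])
        with caplog.at_level("WARNING"):
            records = pairwise_contrast_table(parts, ModelConfig(), receptors, d65, leaf)
        assert records == []
        assert any("fewer than two parts" in m for m in caplog.messages)


class TestModelInvariances:
    def test_self_contrast_is_zero_and_undetectable(self, receptors, d65, leaf, white_petal):
        p = nsc_coordinates(white_petal, receptors, d65, leaf)
        assert delta_s(p, p) == 0.0
        assert classify_detectable(delta_s(p, p)) is False

    def test_illuminant_rescaling_leaves_delta_s_unchanged(
        self, receptors, d65, leaf, white_petal
    ):
        def pair_contrast(ill):
            pp = nsc_coordinates(white_petal, receptors, ill, leaf)
            pl = nsc_coordinates(leaf, receptors, ill, leaf)
            return delta_s(pp, pl)

        assert pair_contrast(d65.scaled(37.5)) == pytest.approx(pair_contrast(d65), abs=1e-9)

    def test_contrast_monotone_along_leaf_to_white_segment(
        self, grid, receptors, d65, leaf, white_petal
    ):
        pl = nsc_coordinates(leaf, receptors, d65, leaf)
        values = []
        for c in np.linspace(0.0, 1.0, 11):
            blend = ReflectanceSpectrum(
                grid=grid,
                reflectance=leaf.reflectance + c * (white_petal.reflectance - leaf.reflectance),
            )
            values.append(delta_s(nsc_coordinates(blend, receptors, d65, leaf), pl))
        assert np.all(np.diff(values) >= -1e-12)

    def test_larger_uv_bullseye_gap_raises_center_periphery_contrast(
        self, grid, receptors, d65, leaf
    ):
        from scipy.stats import spearmanr

        gaps = [0.05, 0.15, 0.25, 0.35, 0.45]
        contrasts = []
        for gap in gaps:
            center = make_archetype("uv_bullseye_center", grid, {"uv_amp": 0.02})
            periph = make_archetype("uv_bullseye_periphery", grid, {"uv_amp": 0.02 + gap})
            pc = nsc_coordinates(center, receptors, d65, leaf)
            pp = nsc_coordinates(periph, receptors, d65, leaf)
            contrasts.append(delta_s(pc, pp))
        rho, _ = spearmanr(gaps, contrasts)
        assert rho == pytest.approx(1.0)
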