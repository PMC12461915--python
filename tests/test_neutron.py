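"""NDIS first-order differences, r↔Q transforms, cation differences."""

import numpy as np
import pytest

from eccforge.neutron import (
    COHERENT_B_FM,
    DifferenceFunction,
    NeutronError,
    ScatteringSpec,
    cation_difference,
    first_order_difference,
    null_water_adjust,
    to_q_space,
    to_r_space,
)
from eccforge.structure import RDFCurve
from eccforge.toysim import GaussianPeak, analytic_rdf


def _curve(edges, g):
    return RDFCurve(("A", "B"), edges, g, 10.0, 10.0)


def _edges(r_max=2.0, dr=0.005):
    return np.arange(0.0, r_max + dr / 2, dr)


@pytest.fixture
def kcl_spec():
    """4 m KCl-like composition per water molecule (concentrations arbitrary units)."""
    return [
        ScatteringSpec("K", COHERENT_B_FM["K"], 0.072),
        ScatteringSpec("Cl", COHERENT_B_FM["Cl"], 0.072),
        ScatteringSpec("O", COHERENT_B_FM["O"], 1.0),
        ScatteringSpec("H", 0.0, 2.0),  # null water: effective b_H = 0
    ]


class TestFirstOrderDifference:
    def test_featureless_fluid_gives_zero(self, kcl_spec):
        edges = _edges()
        ones = np.ones(edges.size - 1)
        partials = {
            ("K", "Cl"): _curve(edges, ones),
            ("K", "O"): _curve(edges, ones),
            ("K", "K"): _curve(edges, ones),
        }
        dG = first_order_difference(partials, kcl_spec, "K")
        np.testing.assert_allclose(dG.values, 0.0, atol=1e-14)

    def test_single_partial_linearity(self, kcl_spec):
        """One structured partial of peak height h: output peak is w·(h−1)."""
        edges = _edges()
        r = 0.5 * (edges[:-1] + edges[1:])
        ones = np.ones_like(r)
        peak = 1.0 + 1.5 * np.exp(-((r - 0.28) ** 2) / (2 * 0.02**2))
        partials = {
            ("K", "Cl"): _curve(edges, ones),
            ("K", "O"): _curve(edges, peak),
            ("K", "K"): _curve(edges, ones),
        }
        dG = first_order_difference(partials, kcl_spec, "K")
        w = dG.component_weights["K-O"]
        assert dG.values.max() == pytest.approx(w * (peak.max() - 1.0), rel=1e-9)

    def test_hand_computed_two_component_weights(self):
        """Weights match the spreadsheet evaluation of 2·c_M·Δb·c_α·b_α."""
        spec = [
            ScatteringSpec("M", 5.0, 0.5),
            ScatteringSpec("O", 6.0, 2.0),
        ]
        edges = _edges(1.0)
        g = np.ones(edges.size - 1)
        partials = {("M", "O"): _curve(edges, g), ("M", "M"): _curve(edges, g)}
        dG = first_order_difference(partials, spec, "M", contrast_b=3.0,
                                    normalization="raw")
        # cross: 2 * 0.5 * 3.0 * 2.0 * 6.0 = 36; self: 0.25 * (25 - 4) = 5.25
        assert dG.component_weights["M-O"] == pytest.approx(36.0)
        assert dG.component_weights["M-M"] == pytest.approx(0.5**2 * (25.0 - 4.0))

    def test_missing_partial_named_in_error(self, kcl_spec):
        edges = _edges()
        ones = np.ones(edges.size - 1)
        partials = {("K", "Cl"): _curve(edges, ones), ("K", "K"): _curve(edges, ones)}
        with pytest.raises(NeutronError, match="'K', 'O'"):
            first_order_difference(partials, kcl_spec, "K")

    def test_linearity_in_partials(self, kcl_spec):
        """ΔG of a convex combination equals the combination of ΔGs."""
        edges = _edges()
        r = 0.5 * (edges[:-1] + edges[1:])
        ones = np.ones_like(r)
        bump = 1.0 + np.exp(-((r - 0.3) ** 2) / (2 * 0.03**2))

        def build(g_ko):
            return {
                ("K", "Cl"): _curve(edges, ones),
                ("K", "O"): _curve(edges, g_ko),
                ("K", "K"): _curve(edges, ones),
            }

        lam = 0.3
        mix = lam * bump + (1 - lam) * ones
        d_mix = first_order_difference(build(mix), kcl_spec, "K")
        d_a = first_order_difference(build(bump), kcl_spec, "K")
        d_b = first_order_difference(build(ones), kcl_spec, "K")
        np.testing.assert_allclose(
            d_mix.values, lam * d_a.values + (1 - lam) * d_b.values, atol=1e-12
        )


class TestQSpaceTransforms:
    def test_zero_map(self):
        edges = _edges()
        r = 0.5 * (edges[:-1] + edges[1:])
        dG = DifferenceFunction(r, np.zeros_like(r), "r")
        dS = to_q_space(dG, 33.0, np.linspace(0, 100, 200))
        np.testing.assert_allclose(dS.values, 0.0)

    def test_gaussian_transform_matches_closed_form(self):
        """ΔG = exp(−r²/2s²) has ΔS(Q) = ρ(2πs²)^{3/2}·exp(−Q²s²/2)."""
        s, rho = 0.08, 30.0
        r = np.arange(0.0, 2.0, 0.002)
        dG = DifferenceFunction(r, np.exp(-(r**2) / (2 * s**2)), "r")
        q = np.linspace(0.0, 60.0, 121)
        dS = to_q_space(dG, rho, q)
        expected = rho * (2 * np.pi * s**2) ** 1.5 * np.exp(-(q**2) * s**2 / 2)
        np.testing.assert_allclose(dS.values, expected, atol=1e-4 * expected.max())

    def test_round_trip_recovers_input(self):
        """r → Q → r without window: <1% RMS on the grid interior."""
        r = np.arange(0.0, 3.0, 0.005)
        vals = np.exp(-((r - 0.4) ** 2) / (2 * 0.05**2)) - 0.5 * np.exp(
            -((r - 0.7) ** 2) / (2 * 0.08**2)
        )
        dG = DifferenceFunction(r, vals, "r")
        rho = 30.0
        q = np.arange(0.0, 400.0, 0.5)
        back = to_r_space(to_q_space(dG, rho, q), rho, r)
        interior = slice(10, -10)
        rms = np.sqrt(np.mean((back.values[interior] - vals[interior]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(vals[interior] ** 2))

    def test_lorch_window_reduces_truncation_ripple(self):
        """On a truncated r-grid the Lorch window damps ripple beyond the peaks."""
        s, rho = 0.03, 30.0
        r = np.arange(0.0, 0.6, 0.002)  # hard truncation
        vals = np.exp(-((r - 0.3) ** 2) / (2 * s**2))
        dG = DifferenceFunction(r, vals, "r")
        q = np.linspace(40.0, 150.0, 400)  # tail region
        plain = to_q_space(dG, rho, q, window="none")
        lorch = to_q_space(dG, rho, q, window="lorch")
        assert np.abs(lorch.values).max() < np.abs(plain.values).max()

    def test_non_uniform_grid_rejected(self):
        r = np.array([0.0, 0.1, 0.3, 0.35])
        dG = DifferenceFunction(r, np.zeros_like(r), "r")
        with pytest.raises(NeutronError, match="non-uniform"):
            to_q_space(dG, 30.0, np.linspace(0, 10, 5))


class TestCationDifference:
    def _dg(self, center, height):
        r = np.arange(0.0, 1.0, 0.002)
        return DifferenceFunction(
            r, height * np.exp(-((r - center) ** 2) / (2 * 0.015**2)), "r",
            metadata={"substituted": f"M{center}"},
        )

    def test_self_difference_is_zero(self):
        a = self._dg(0.28, 1.0)
        d = cation_difference(a, a)
        np.testing.assert_allclose(d.values, 0.0)

    def test_features_carry_sign_and_position(self):
        gk = self._dg(0.30, 1.0)
        gna = self._dg(0.24, 0.6)
        d = cation_difference(gk, gna)
        r = d.grid
        assert d.values[np.argmin(np.abs(r - 0.30))] == pytest.approx(1.0, abs=0.05)
        assert d.values[np.argmin(np.abs(r - 0.24))] == pytest.approx(-0.6, abs=0.05)

    def test_order_swap_negates(self):
        gk, gna = self._dg(0.30, 1.0), self._dg(0.24, 0.6)
        np.testing.assert_allclose(
            cation_difference(gk, gna).values,
            -cation_difference(gna, gk).values,
        )

    def test_grid_mismatch_rejected(self):
        a = self._dg(0.28, 1.0)
        r = np.arange(0.0, 0.5, 0.002)
        b = DifferenceFunction(r, np.zeros_like(r), "r")
        with pytest.raises(NeutronError, match="grid"):
            cation_difference(a, b)


class TestNullWaterAdjust:
    def _setup(self):
        edges = _edges(1.0, 0.002)
        r = 0.5 * (edges[:-1] + edges[1:])
        dG = DifferenceFunction(r, np.sin(r), "r")
        oo, _ = analytic_rdf(
            "gaussian-peaks", edges, 30.0,
            peaks=[GaussianPeak(1.2, 0.28, 0.02)], baseline=1.0,
        )
        return dG, oo

    def test_zero_weight_is_identity(self):
        dG, oo = self._setup()
        out = null_water_adjust(dG, oo, 0.0)
        np.testing.assert_allclose(out.values, dG.values)

    def test_flat_partial_is_identity(self):
        dG, _ = self._setup()
        edges = _edges(1.0, 0.002)
        flat, _ = analytic_rdf("gaussian-peaks", edges, 30.0, peaks=[], baseline=1.0)
        out = null_water_adjust(dG, flat, 0.7)
        np.testing.assert_allclose(out.values, dG.values)

    def test_peak_subtracted_exactly(self):
        dG, oo = self._setup()
        w = 0.4
        out = null_water_adjust(dG, oo, w)
        np.testing.assert_allclose(out.values, dG.values - w * (oo.g - 1.0))
        assert out.component_weights["OO-adjustment"] == -w
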