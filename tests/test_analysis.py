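"""Diagonal pairs, orderings, correlations, polarizing power, Born-Lande."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionocov import (
    born_lande,
    correlate,
    diagonal_table,
    load_table,
    ordering_check,
    polarizing_power_compare,
)


class TestDiagonalTable:
    def test_carbon_phosphorus_pair_on_canonical_data(self, rows):
        [pair] = diagonal_table(rows, [("C4+", "P5+")])
        assert pair.quantities["ic"][:2] == (4.320, 4.355)
        assert pair.delta("ic") < 0.05

    def test_boron_silicon_ionicity_pair(self, rows):
        [pair] = diagonal_table(rows, [("B3+", "Si4+")])
        assert pair.quantities["i_av"][:2] == (23.800, 25.763)

    def test_self_pair_has_zero_differences(self, rows):
        [pair] = diagonal_table(rows, [("Fe2+", "Fe2+")])
        assert all(d == 0 for *_, d in pair.quantities.values())

    def test_unresolvable_label_raises(self, rows):
        with pytest.raises(KeyError):
            diagonal_table(rows, [("Xx9+", "C4+")])

    def test_diagonal_deltas_smaller_than_horizontal_differences(self, rows):
        # with the chart parameterization, each diagonal |dIC| is smaller than
        # the step to the next element of the same (upper) period
        overlay = load_table("alt_chart_values")
        pairs = diagonal_table(rows, overlay=overlay)
        uppers = [p.quantities["ic"][0] for p in pairs]
        horizontal = [abs(a - b) for a, b in zip(uppers, uppers[1:])]
        # the last upper (N5+) steps to O6+ from the chart overlay
        o6 = float(overlay.query("symbol == 'O'")["ic"].iloc[0])
        horizontal.append(abs(uppers[-1] - o6))
        for pair, h in zip(pairs, horizontal):
            assert pair.delta("ic") < h, (pair.upper, pair.lower)


class TestCorrelate:
    def test_moessbauer_shift_anticorrelates_perfectly_with_ic(self):
        df = load_table("moessbauer_iron")
        result = correlate(df["ic"], df["delta_mm_s"], method="rank")
        assert result.coefficient == pytest.approx(-1.0)

    def test_identical_series_correlate_perfectly(self):
        series = [1.0, 2.0, 5.0]
        for method in ("rank", "linear"):
            assert correlate(series, series, method).coefficient == pytest.approx(1.0)

    def test_mcl2_lattice_energy_rank_matches_brute_force_oracle(self):
        df = load_table("mcl2_lattice")
        result = correlate(df["ic"], df["u_kj_mol"], method="rank")
        # frozen from an independent average-rank computation on the printed rows
        assert result.coefficient == pytest.approx(0.9422535927041, abs=1e-9)
        assert result.coefficient > 0

    @pytest.mark.parametrize(
        "x, y", [([1, 2], [1, 2]), ([1, 2, 3], [1, 2])]
    )
    def test_rejects_short_or_mismatched_series(self, x, y):
        with pytest.raises(ValueError):
            correlate(x, y)

    @settings(derandomize=True, max_examples=100)
    @given(
        xy=st.lists(
            st.tuples(
                st.floats(min_value=-100, max_value=100),
                st.floats(min_value=-100, max_value=100),
            ),
            min_size=3,
            max_size=12,
            unique_by=lambda t: t[0],
        )
    )
    def test_symmetry_and_monotone_invariance(self, xy):
        x, y = zip(*xy)
        if len(set(y)) < 2:
            return
        a = correlate(x, y, "rank").coefficient
        assert correlate(y, x, "rank").coefficient == pytest.approx(a, abs=1e-9)
        transformed = [v**3 + 2 * v for v in x]  # strictly monotone map
        assert correlate(transformed, y, "rank").coefficient == pytest.approx(a, abs=1e-9)


class TestOrderingCheck:
    def test_chalcogen_acidity_chain_descends_on_ic(self, rows):
        chain = ["Se2+", "S2+", "C2+", "Te2+", "I1+", "H1+"]
        assert ordering_check(rows, chain, "ic", "decreasing").ok

    def test_irving_williams_series_ascends_on_ic(self, rows):
        chain = ["Mn2+", "Fe2+", "Co2+", "Ni2+", "Cu2+"]
        assert ordering_check(rows, chain, "ic", "increasing").ok

    def test_halogen_softness_ascends_on_n_star_and_radius(self, rows):
        chain = ["F7+", "Cl5+", "Br7+", "I7+"]
        assert ordering_check(rows, chain, "n_star", "increasing").ok
        assert ordering_check(rows, chain, "r_c", "increasing").ok

    def test_single_label_vacuously_true(self, rows):
        assert ordering_check(rows, ["H1+"], "ic").ok

    def test_violations_list_adjacent_pairs(self, rows):
        result = ordering_check(rows, ["H1+", "K1+", "C4+"], "ic", "increasing")
        assert not result.ok
        assert result.violations == (("H1+", "K1+"),)

    @settings(derandomize=True, max_examples=100)
    @given(
        labels=st.lists(
            st.sampled_from(["H1+", "K1+", "Ca2+", "Fe2+", "Fe3+", "C4+", "Ta5+"]),
            min_size=1,
            max_size=6,
            unique=True,
        )
    )
    def test_agrees_with_pairwise_comparison_oracle(self, rows, labels):
        result = ordering_check(rows, labels, "ic", "decreasing")
        values = result.values
        oracle = all(a > b for a, b in zip(values, values[1:]))
        assert result.ok == oracle


class TestBornLande:
    def test_rock_salt_oracle_value(self):
        # frozen from a hand evaluation of the closed form with CODATA constants
        assert born_lande(1, 1.748, 2.82, 8) == pytest.approx(-753.552, abs=0.01)

    def test_infinite_born_exponent_limit_is_pure_coulomb(self):
        u_large = born_lande(1, 1.748, 2.82, 1e12)
        coulomb = born_lande(1, 1.748, 2.82, 2) * 2
        assert u_large == pytest.approx(coulomb, rel=1e-6)

    def test_charge_squared_scaling(self):
        assert born_lande(2, 1.748, 2.82, 8) == pytest.approx(
            4 * born_lande(1, 1.748, 2.82, 8)
        )

    def test_rejects_born_exponent_at_or_below_one(self):
        with pytest.raises(ValueError, match="born_exponent"):
            born_lande(1, 1.748, 2.82, 1.0)


class TestPolarizingPower:
    def test_mercury_outpolarizes_calcium(self, rows):
        cmp = polarizing_power_compare(rows, "Hg2+", "Ca2+")
        assert cmp.quantities["z_star"] == (4.490, 2.807)
        assert cmp.quantities["ic"] == (3.118, 1.617)
        assert cmp.dominant["z_star"] == cmp.dominant["ic"] == "Hg2+"

    def test_copper_has_higher_spatial_covalency_than_silver(self, rows):
        cmp = polarizing_power_compare(rows, "Cu3+", "Ag3+")
        assert cmp.quantities["n_star_rc_inv"] == (3.108, 2.875)
        assert cmp.dominant["n_star_rc_inv"] == "Cu3+"

    def test_self_comparison_ties_everywhere(self, rows):
        cmp = polarizing_power_compare(rows, "Fe2+", "Fe2+")
        assert all(v is None for v in cmp.dominant.values())
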