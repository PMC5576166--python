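"""Lorenz construction and the three Gini routes, checked against closed
forms and a brute-force mean-absolute-difference oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthequity.lorenz_gini import (
    DegenerateCurveError,
    GiniGroupedInputs,
    LorenzCurve,
    build_lorenz,
    gini_from_table,
    gini_grouped,
    gini_oracle,
    gini_trapezoid,
    grouped_inputs,
)
from healthequity.region_data import RegionRecord, RegionTable, ResourceKind


def table_from(weights, counts, areas=None):
    """Tiny helper: region i holds weights[i] persons and counts[i] physicians."""
    areas = areas if areas is not None else weights
    return RegionTable(
        regions=tuple(
            RegionRecord(f"R{i:02d}", int(w), float(a), int(c), 0, 0)
            for i, (w, a, c) in enumerate(zip(weights, areas, counts))
        )
    )


# weight/count instance strategy: 2-8 regions, at least one positive count
instances = st.lists(
    st.tuples(st.integers(1, 500), st.integers(0, 400)),
    min_size=2,
    max_size=8,
).filter(lambda rows: sum(c for _, c in rows) > 0)


class TestLorenzCurve:
    def test_uniform_density_lies_on_diagonal(self):
        t = table_from([10, 20, 40, 30], [1, 2, 4, 3])
        curve = build_lorenz(t, ResourceKind.PHYSICIANS, "population")
        assert curve.p == pytest.approx(curve.q)

    def test_extreme_concentration_two_regions(self):
        t = table_from([9, 1], [0, 10])
        curve = build_lorenz(t, ResourceKind.PHYSICIANS, "population")
        assert curve.points == pytest.approx(np.array([[0, 0], [0.9, 0], [1, 1]]))

    def test_fixture_capital_is_last_on_population_basis(self, mongolia):
        curve = build_lorenz(mongolia, ResourceKind.PHYSICIANS, "population")
        assert curve.order[-1] == "Ulaanbaatar"
        # pre-terminal point: everything except the capital
        assert curve.p[-2] == pytest.approx(0.545, abs=5e-4)
        assert curve.q[-2] == pytest.approx(0.383, abs=5e-4)

    def test_all_zero_resource_is_degenerate(self):
        t = table_from([5, 5], [0, 0])
        with pytest.raises(DegenerateCurveError):
            build_lorenz(t, ResourceKind.PHYSICIANS, "population")

    def test_invalid_endpoints_rejected(self):
        with pytest.raises(ValueError):
            LorenzCurve(p=np.array([0.0, 0.5]), q=np.array([0.0, 0.9]), basis="population")


class TestGroupedFormula:
    def test_perfect_equality_is_zero(self):
        # one group of n identical units
        inputs = GiniGroupedInputs(f=np.array([50.0]), x=np.array([3.0]))
        assert gini_grouped(inputs).coefficient == pytest.approx(0.0, abs=1e-12)

    def test_perfect_inequality_is_exactly_one(self):
        # n-1 empty units plus one holding everything
        inputs = GiniGroupedInputs(f=np.array([99.0, 1.0]), x=np.array([0.0, 7.0]))
        assert gini_grouped(inputs).coefficient == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_amount_rejected(self):
        with pytest.raises(DegenerateCurveError):
            gini_grouped(GiniGroupedInputs(f=np.array([3.0, 2.0]), x=np.array([0.0, 0.0])))

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError, match="n="):
            gini_grouped(GiniGroupedInputs(f=np.array([1.0]), x=np.array([5.0])))

    def test_unsorted_densities_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            GiniGroupedInputs(f=np.array([1.0, 1.0]), x=np.array([2.0, 1.0]))


class TestTrapezoid:
    def test_diagonal_curve_gives_zero(self):
        curve = LorenzCurve(p=np.linspace(0, 1, 5), q=np.linspace(0, 1, 5), basis="population")
        assert gini_trapezoid(curve).coefficient == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("eps", [0.1, 0.01, 0.001])
    def test_concentrated_curve_approaches_one(self, eps):
        curve = LorenzCurve(
            p=np.array([0.0, 1 - eps, 1.0]), q=np.array([0.0, 0.0, 1.0]), basis="area"
        )
        assert gini_trapezoid(curve).coefficient == pytest.approx(1 - eps, abs=1e-12)


class TestOracle:
    def test_identical_units_give_zero(self):
        assert gini_oracle([1, 1, 1], [5, 5, 5]).coefficient == pytest.approx(0.0)

    def test_single_holder_of_four_units(self):
        # units {0,0,0,T}: direct double loop gives 0.75 (n-denominator)
        assert gini_oracle([1, 1, 1, 1], [0, 0, 0, 9]).coefficient == pytest.approx(0.75)

    def test_refuses_oversized_instance(self):
        with pytest.raises(ValueError, match="rescale"):
            gini_oracle([20_000], [1.0])

    @given(instances)
    @settings(max_examples=30)
    def test_trapezoid_matches_oracle(self, rows):
        """The trapezoid route equals the brute-force MAD Gini (n-denominator)."""
        w = [1 + r[0] % 50 for r in rows]  # keep the oracle expansion small
        c = [r[1] for r in rows]
        t = table_from(w, c)
        trap = gini_from_table(t, ResourceKind.PHYSICIANS, "population").coefficient
        oracle = gini_oracle(w, c).coefficient
        assert trap == pytest.approx(oracle, abs=1e-9)


class TestInvariants:
    @given(instances, st.randoms(use_true_random=False))
    @settings(max_examples=30)
    def test_permutation_invariance(self, rows, rnd):
        w = [r[0] for r in rows]
        c = [r[1] for r in rows]
        g1 = gini_from_table(table_from(w, c), ResourceKind.PHYSICIANS, "population")
        order = list(range(len(rows)))
        rnd.shuffle(order)
        g2 = gini_from_table(
            table_from([w[i] for i in order], [c[i] for i in order]),
            ResourceKind.PHYSICIANS,
            "population",
        )
        assert g1.coefficient == pytest.approx(g2.coefficient, abs=1e-12)

    @given(instances, st.integers(2, 20))
    @settings(max_examples=30)
    def test_scale_invariance(self, rows, factor):
        w = [r[0] for r in rows]
        c = [r[1] for r in rows]
        base = gini_from_table(table_from(w, c), ResourceKind.PHYSICIANS, "population")
        counts_scaled = gini_from_table(
            table_from(w, [x * factor for x in c]), ResourceKind.PHYSICIANS, "population"
        )
        weights_scaled = gini_from_table(
            table_from([x * factor for x in w], c), ResourceKind.PHYSICIANS, "population"
        )
        assert counts_scaled.coefficient == pytest.approx(base.coefficient, abs=1e-12)
        assert weights_scaled.coefficient == pytest.approx(base.coefficient, abs=1e-12)

    @given(instances)
    @settings(max_examples=50)
    def test_range_and_method_agreement(self, rows):
        """Coefficients lie in [0,1]; grouped vs trapezoid differ by ≤ 1/n."""
        w = [r[0] for r in rows]
        c = [r[1] for r in rows]
        t = table_from(w, c)
        trap = gini_from_table(t, ResourceKind.PHYSICIANS, "population").coefficient
        grp = gini_from_table(
            t, ResourceKind.PHYSICIANS, "population", method="grouped_formula"
        ).coefficient
        n = sum(w)
        assert -1e-12 <= trap <= 1 + 1e-12
        assert -1e-12 <= grp <= 1 + 1e-12
        assert abs(grp - trap) <= 1 / n + 1e-12

    def test_tie_order_invariance(self):
        """Regions with tied densities can be listed either way round."""
        t1 = table_from([10, 30, 60], [1, 3, 12])  # first two tied at 0.1
        t2 = table_from([30, 10, 60], [3, 1, 12])
        g1 = gini_from_table(t1, ResourceKind.PHYSICIANS, "population")
        g2 = gini_from_table(t2, ResourceKind.PHYSICIANS, "population")
        assert g1.coefficient == pytest.approx(g2.coefficient, abs=1e-15)

    @given(instances)
    @settings(max_examples=30)
    def test_transfer_to_richest_never_decreases(self, rows):
        """Moving resource from the poorest-density to the richest-density
        region (weights fixed) cannot reduce concentration."""
        w = [r[0] for r in rows]
        c = [r[1] for r in rows]
        t = table_from(w, c)
        dens = np.array(c, float) / np.array(w, float)
        lo, hi = int(np.argmin(dens)), int(np.argmax(dens))
        if lo == hi or c[lo] == 0:
            return
        before = gini_from_table(t, ResourceKind.PHYSICIANS, "population").coefficient
        c2 = list(c)
        c2[lo] -= 1
        c2[hi] += 1
        after = gini_from_table(table_from(w, c2), ResourceKind.PHYSICIANS, "population").coefficient
        assert after >= before - 1e-12


class TestFixtureCoefficients:
    @pytest.mark.parametrize(
        "resource, basis, printed",
        [
            ("physicians", "population", 0.18),
            ("nurses", "population", 0.07),
            ("hospital_beds", "population", 0.07),
            ("physicians", "area", 0.74),
            ("nurses", "area", 0.68),
            ("hospital_beds", "area", 0.69),
        ],
    )
    def test_two_decimal_coefficients(self, mongolia, resource, basis, printed):
        g = gini_from_table(mongolia, ResourceKind(resource), basis)
        assert g.rounded(2) == pytest.approx(printed)

    def test_grouped_and_trapezoid_agree_at_national_weights(self, mongolia):
        """With millions of atomic units the two conventions coincide to ≥5 d.p."""
        for resource in ResourceKind:
            for basis in ("population", "area"):
                trap = gini_from_table(mongolia, resource, basis).coefficient
                grp = gini_from_table(mongolia, resource, basis, "grouped_formula").coefficient
                assert abs(trap - grp) < 1e-5
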