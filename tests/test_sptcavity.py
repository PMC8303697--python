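"""SPT cavity-creation work: printed-table reproduction and structural invariants."""

import numpy as np
import pytest

from printed_tables import TABLE3
from sptdsc.composition import PackingState, number_density
from sptdsc.geometry import CavityGeometry, DENATURED_GEOMETRY, NATIVE_GEOMETRY
from sptdsc.report import cavity_table
from sptdsc.sptcavity import cavity_work, ddGc, ddGc_prime

T25 = 298.15


def _packing(registry, pairs):
    return PackingState(
        tuple((registry[name], number_density(c)) for name, c in pairs)
    )


class TestCavityWorkExamples:
    def test_pure_water_sphere(self, water_packing):
        w = cavity_work(water_packing, NATIVE_GEOMETRY, T25)
        assert w.total == pytest.approx(1074, rel=0.005)

    def test_pure_water_spherocylinder(self, water_packing):
        w = cavity_work(water_packing, DENATURED_GEOMETRY, T25)
        assert w.total == pytest.approx(1878, rel=0.005)

    def test_fructose_solution_both_shapes(self, registry):
        from sptdsc.composition import SolutionComposition, packing_state

        comp = SolutionComposition(
            cosolutes=((registry["fructose"], 1.0),), density=1066.0
        )
        state = packing_state(comp, registry)
        assert cavity_work(state, NATIVE_GEOMETRY, T25).total == pytest.approx(
            1125, rel=0.005
        )
        assert cavity_work(state, DENATURED_GEOMETRY, T25).total == pytest.approx(
            1967, rel=0.005
        )

    def test_empty_solvent_costs_nothing(self):
        empty = PackingState(())
        assert cavity_work(empty, NATIVE_GEOMETRY, T25).total == 0.0

    def test_total_is_sum_of_terms(self, water_packing):
        w = cavity_work(water_packing, DENATURED_GEOMETRY, T25)
        assert w.total == pytest.approx(sum(w.terms.values()), rel=1e-12)

    def test_pv_term_is_negligible_at_1_atm(self, water_packing):
        with_pv = cavity_work(water_packing, NATIVE_GEOMETRY, T25, include_pv_term=True)
        without = cavity_work(water_packing, NATIVE_GEOMETRY, T25)
        assert 0 < with_pv.total - without.total < 1.0  # kJ/mol


class TestStabilityDifferences:
    def test_ddgc_in_water(self, water_packing):
        assert ddGc(water_packing, NATIVE_GEOMETRY, DENATURED_GEOMETRY, T25) == (
            pytest.approx(804, rel=0.005)
        )

    def test_ddgc_gdmcl_glucose_ternary(self, solutions, registry):
        from sptdsc.composition import packing_state

        comp = next(s for s in solutions if s.label == "1 M GdmCl + 1 M glucose")
        state = packing_state(comp, registry)
        assert ddGc(state, NATIVE_GEOMETRY, DENATURED_GEOMETRY, T25) == (
            pytest.approx(916, rel=0.005)
        )

    def test_identical_geometries_give_zero(self, water_packing):
        assert ddGc(water_packing, NATIVE_GEOMETRY, NATIVE_GEOMETRY, T25) == 0.0

    def test_ddgc_prime_examples(self, solutions, registry):
        from sptdsc.composition import packing_state

        water = next(s for s in solutions if s.label == "water")
        ref = ddGc(packing_state(water, registry), NATIVE_GEOMETRY, DENATURED_GEOMETRY, T25)
        assert ddGc_prime(ref, ref) == 0.0
        for label, expected, tol in [
            ("1 M NaClO4 + 1 M trehalose", 210, 4.0),
            ("1 M urea", 27, 3.0),
        ]:
            comp = next(s for s in solutions if s.label == label)
            val = ddGc(packing_state(comp, registry), NATIVE_GEOMETRY, DENATURED_GEOMETRY, T25)
            assert ddGc_prime(val, ref) == pytest.approx(expected, abs=tol), label


def test_full_cavity_table_reproduction(solutions, registry):
    """All 30 published rows: dGc within 0.5%, excess stabilization within 4 kJ/mol."""
    df = cavity_table(solutions, registry=registry)
    assert len(df) == 30
    for row in df.itertuples(index=False):
        gn, gd, dd, prime = TABLE3[row.label]
        assert row.dGc_N == pytest.approx(gn, rel=0.005), row.label
        assert row.dGc_D == pytest.approx(gd, rel=0.005), row.label
        assert row.ddGc == pytest.approx(dd, rel=0.005), row.label
        if prime is not None:
            assert row.ddGc_prime == pytest.approx(prime, abs=4.0), row.label


def test_ternary_ordering_exceeds_binaries(solutions, registry):
    """Excluded-volume stabilization: ternary > binary denaturant > water, every pair."""
    df = cavity_table(solutions, registry=registry).set_index("label")
    water = df.loc["water", "ddGc"]
    for den, dm in [("urea", "1"), ("TMU", "1"), ("NaClO4", "1"),
                    ("GdmCl", "1"), ("GdmSCN", "0.5")]:
        binary = df.loc[f"{dm} M {den}", "ddGc"]
        assert binary > water
        for sugar in ("fructose", "glucose", "sucrose", "trehalose"):
            ternary = df.loc[f"{dm} M {den} + 1 M {sugar}", "ddGc"]
            sugar_binary = df.loc[f"1 M {sugar}", "ddGc"]
            assert ternary > binary, (den, sugar)
            assert ternary > sugar_binary, (den, sugar)


class TestInvariants:
    def test_spherocylinder_with_zero_length_equals_sphere(self, registry):
        """The l = 0 limit matches the sphere formula to machine precision."""
        rng = np.random.default_rng(7)
        water = registry["water"]
        glucose = registry["glucose"]
        for _ in range(1000):
            w, g = rng.uniform(20, 55), rng.uniform(0, 2)
            a = rng.uniform(1, 30)
            state = _packing(registry, [("water", w), ("glucose", g)])
            sphere = cavity_work(state, CavityGeometry(a=a), T25).total
            cyl = cavity_work(state, CavityGeometry(a=a, l=0.0), T25).total
            assert cyl == sphere

    def test_work_vanishes_in_ideal_gas_limit(self, registry):
        prev = np.inf
        for scale in (1.0, 1e-2, 1e-4, 1e-6):
            state = _packing(registry, [("water", 55.3 * scale)])
            w = cavity_work(state, DENATURED_GEOMETRY, T25).total
            assert 0 < w < prev
            prev = w
        assert prev < 1e-2

    def test_monotone_in_density_and_geometry(self, registry):
        base = _packing(registry, [("water", 50.0), ("sucrose", 0.5)])
        denser = _packing(registry, [("water", 50.0), ("sucrose", 0.8)])
        geom = CavityGeometry(a=10.0, l=50.0)
        assert cavity_work(denser, geom, T25).total > cavity_work(base, geom, T25).total
        assert (
            cavity_work(base, CavityGeometry(a=11.0, l=50.0), T25).total
            > cavity_work(base, geom, T25).total
        )
        assert (
            cavity_work(base, CavityGeometry(a=10.0, l=60.0), T25).total
            > cavity_work(base, geom, T25).total
        )

    def test_every_term_nonnegative(self, solutions, registry):
        from sptdsc.composition import packing_state

        for comp in solutions:
            w = cavity_work(packing_state(comp, registry), DENATURED_GEOMETRY, T25)
            assert all(v >= 0 for v in w.terms.values()), comp.label

    def test_negative_geometry_rejected(self):
        with pytest.raises(ValueError):
            CavityGeometry(a=-1.0)
        with pytest.raises(ValueError):
            CavityGeometry(a=1.0, l=-0.5)
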