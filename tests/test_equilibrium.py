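"""Coupled-equilibrium solver, inversions and excess scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transglyq import (
    EquilibriumConstants,
    ExcessResult,
    InconsistentObservationError,
    InvalidInputError,
    ReactionMix,
    TransglySystem,
    conversion_curve,
    infer_K_donor,
    infer_K_product,
    required_excess,
    solve_equilibrium,
)
from transglyq.equilibrium import gibbs_grid_oracle

from conftest import FIVEFOLD_MIX, random_system

# regression fixture frozen from the brute-force extent-grid search
# (grid_n=2000) for K_donor=0.2, K_product=2.0, D0=5, B0=1, P0=0.5 mM
DERIVED_CONVERSION = 0.3914363


class TestSolveEquilibrium:
    def test_symmetric_equimolar_gives_half_conversion(self):
        # equal constants, equimolar loadings, vanishing phosphate:
        # [B_d][N_p]/([N_d][B_p]) = 1 forces x = 1/2
        system = TransglySystem(
            ReactionMix(1.0, 1.0, 1e-6), EquilibriumConstants(1.0, 1.0)
        )
        assert solve_equilibrium(system).conversion == pytest.approx(0.5, abs=1e-4)

    def test_no_donor_returns_boundary_with_flag(self):
        system = TransglySystem(
            ReactionMix(0.0, 1.0, 0.09), EquilibriumConstants(1.0, 2.0)
        )
        result = solve_equilibrium(system)
        assert result.conversion == 0.0
        assert result.extent_phosphorolysis == 0.0
        assert result.extent_glycosylation == 0.0
        assert result.degenerate

    def test_matches_frozen_grid_oracle_value(self):
        system = TransglySystem(
            ReactionMix(5.0, 1.0, 0.5), EquilibriumConstants(0.2, 2.0)
        )
        assert solve_equilibrium(system).conversion == pytest.approx(
            DERIVED_CONVERSION, abs=5e-4
        )

    def test_negative_loading_rejected(self):
        with pytest.raises(InvalidInputError):
            ReactionMix(-1.0, 1.0, 0.1)

    def test_bad_tolerance_rejected(self):
        system = TransglySystem(
            ReactionMix(5.0, 1.0, 0.09), EquilibriumConstants(0.3, 9.37)
        )
        with pytest.raises(InvalidInputError):
            solve_equilibrium(system, rel_tol=0.1)

    def test_mass_balances_and_residuals(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            system = random_system(rng)
            mix = system.mix
            r = solve_equilibrium(system)
            D0 = mix.donor_nucleoside_0
            B0 = mix.acceptor_base_0
            P0 = mix.phosphate_0
            assert (
                r.donor_nucleoside + r.pentose1P + r.product_nucleoside
                == pytest.approx(D0, rel=1e-12)
            )
            assert r.donor_nucleoside + r.donor_base == pytest.approx(D0, rel=1e-12)
            assert r.acceptor_base + r.product_nucleoside == pytest.approx(
                B0, rel=1e-12
            )
            assert r.phosphate + r.pentose1P == pytest.approx(P0, rel=1e-12)
            assert all(v >= 0 for v in r.species.values())
            assert max(r.residuals.values()) <= 1e-9
            assert r.extent_phosphorolysis == pytest.approx(r.donor_base)
            assert r.extent_glycosylation == pytest.approx(r.product_nucleoside)

    def test_conversion_monotone_in_donor_and_constants(self):
        base = dict(D=5.0, B=1.0, P=0.09, kd=0.3, kp=9.37)

        def conv(**kw):
            p = {**base, **kw}
            return solve_equilibrium(
                TransglySystem(
                    ReactionMix(p["D"], p["B"], p["P"]),
                    EquilibriumConstants(p["kd"], p["kp"]),
                )
            ).conversion

        x0 = conv()
        assert conv(D=10.0) > x0  # more donor pushes the coupled equilibria
        assert conv(kd=0.6) > x0  # easier donor phosphorolysis
        assert conv(kp=20.0) < x0  # product more prone to phosphorolysis

    def test_closed_form_limit_as_phosphate_vanishes(self):
        # with P0 -> 0 the shared pool drops out and x solves
        # K_d/K_p = x^2 B0 / ((D0 - x B0)(1 - x))
        rng = np.random.default_rng(5)
        for _ in range(20):
            kd = float(10 ** rng.uniform(-2, 2))
            kp = float(10 ** rng.uniform(-2, 2))
            D0 = float(10 ** rng.uniform(-1, 1))
            B0 = float(10 ** rng.uniform(-1, 1))
            rho = kd / kp
            a = B0 * (1.0 - rho)
            b = rho * (D0 + B0)
            c = -rho * D0
            if abs(a) < 1e-12:
                x_cf = -c / b
            else:
                disc = np.sqrt(b * b - 4 * a * c)
                roots = [(-b + disc) / (2 * a), (-b - disc) / (2 * a)]
                x_cf = next(r for r in roots if 0 < r < 1)
            x = solve_equilibrium(
                TransglySystem(
                    ReactionMix(D0, B0, 1e-8 * B0), EquilibriumConstants(kd, kp)
                )
            ).conversion
            assert x == pytest.approx(x_cf, abs=1e-4)


class TestGridOracle:
    def test_symmetric_case(self):
        system = TransglySystem(
            ReactionMix(1.0, 1.0, 1e-6), EquilibriumConstants(1.0, 1.0)
        )
        assert gibbs_grid_oracle(system, 2000).conversion == pytest.approx(
            0.5, abs=1e-3
        )

    def test_derived_fixture_value(self):
        system = TransglySystem(
            ReactionMix(5.0, 1.0, 0.5), EquilibriumConstants(0.2, 2.0)
        )
        assert gibbs_grid_oracle(system, 2000).conversion == pytest.approx(
            DERIVED_CONVERSION, abs=5e-4
        )

    def test_rejects_tiny_grid(self):
        system = TransglySystem(
            ReactionMix(5.0, 1.0, 0.5), EquilibriumConstants(0.2, 2.0)
        )
        with pytest.raises(InvalidInputError):
            gibbs_grid_oracle(system, 50)


class TestInversions:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        kd=st.floats(0.01, 100.0),
        kp=st.floats(0.01, 100.0),
        d0=st.floats(0.01, 100.0),
        b0=st.floats(0.01, 100.0),
        p0=st.floats(0.01, 100.0),
    )
    def test_round_trip_recovers_both_constants(self, kd, kp, d0, b0, p0):
        mix = ReactionMix(d0, b0, p0)
        system = TransglySystem(mix, EquilibriumConstants(kd, kp))
        x = solve_equilibrium(system).conversion
        assert infer_K_product(mix, kd, x) == pytest.approx(kp, rel=1e-6)
        assert infer_K_donor(mix, kp, x) == pytest.approx(kd, rel=1e-6)

    def test_printed_pair_is_self_consistent(self):
        # fivefold-excess observation at x=0.305 with product constant 9.37:
        # calibrating the donor constant and inverting back must return 9.37
        kd = infer_K_donor(FIVEFOLD_MIX, 9.37, 0.305)
        assert infer_K_product(FIVEFOLD_MIX, kd, 0.305) == pytest.approx(
            9.37, rel=1e-9
        )

    def test_unit_donor_constant_linear_branch(self):
        mix = ReactionMix(5.0, 1.0, 0.5)
        x = solve_equilibrium(
            TransglySystem(mix, EquilibriumConstants(1.0, 3.0))
        ).conversion
        assert infer_K_product(mix, 1.0, x) == pytest.approx(3.0, rel=1e-6)

    def test_calibrated_constant_reproduces_observation(self):
        kd = infer_K_donor(FIVEFOLD_MIX, 4.85, 0.33)
        assert kd > 0
        x = solve_equilibrium(
            TransglySystem(FIVEFOLD_MIX, EquilibriumConstants(kd, 4.85))
        ).conversion
        assert x == pytest.approx(0.33, abs=1e-9)

    def test_vanishing_conversion_needs_vanishing_donor_constant(self):
        kd = infer_K_donor(FIVEFOLD_MIX, 9.37, 1e-8)
        assert 0 < kd < 1e-6

    def test_conversion_beyond_sugar_balance_rejected(self):
        mix = ReactionMix(donor_nucleoside_0=1.0, acceptor_base_0=5.0, phosphate_0=0.09)
        with pytest.raises(InconsistentObservationError):
            infer_K_product(mix, 1.0, 0.5)  # needs 2.5 mM sugar from 1 mM donor
        with pytest.raises(InvalidInputError):
            infer_K_product(FIVEFOLD_MIX, 1.0, 1.5)


class TestExcessScans:
    def test_curve_is_strictly_increasing(self, calibrated_1a):
        curve = conversion_curve(1.0, 0.09, calibrated_1a, [1, 2, 5, 10, 20, 50])
        conversions = [c for _, c in curve]
        assert all(b > a for a, b in zip(conversions, conversions[1:]))

    def test_curve_reproduces_calibration_point(self, calibrated_1a):
        (_, conv5), = conversion_curve(1.0, 0.09, calibrated_1a, [5])
        assert conv5 == pytest.approx(0.305, abs=1e-9)

    def test_tenfold_prediction_close_to_printed_value(self, calibrated_1a):
        (_, conv10), = conversion_curve(1.0, 0.09, calibrated_1a, [10])
        assert conv10 == pytest.approx(0.39, abs=0.03)

    def test_invalid_excess_rejected(self, calibrated_1a):
        with pytest.raises(InvalidInputError):
            conversion_curve(1.0, 0.09, calibrated_1a, [-1.0])
        with pytest.raises(InvalidInputError):
            conversion_curve(1.0, 0.09, calibrated_1a, [5], phosphate_policy="weird")

    def test_already_attained_target_returns_unity(self, calibrated_1a):
        res = required_excess(1.0, 0.09, calibrated_1a, 0.01)
        assert isinstance(res, ExcessResult)
        assert res.attained
        assert res.excess == 1.0

    def test_half_conversion_needs_roughly_twentyfold(self, calibrated_1a):
        res = required_excess(1.0, 0.09, calibrated_1a, 0.5, excess_cap=100.0)
        assert res.attained
        assert 15.0 <= res.excess <= 25.0
        # returned excess actually achieves the target
        (_, conv), = conversion_curve(1.0, 0.09, calibrated_1a, [res.excess])
        assert conv == pytest.approx(0.5, abs=1e-6)

    def test_proportional_phosphate_can_make_target_unattainable(self):
        # scaling phosphate with the donor keeps the system self-similar, so
        # a strongly unfavorable product constant caps the conversion
        constants = EquilibriumConstants(K_donor=0.05, K_product=50.0)
        res = required_excess(
            1.0,
            0.09,
            constants,
            0.5,
            excess_cap=100.0,
            phosphate_policy="proportional",
        )
        assert not res.attained
        assert res.excess == 100.0
        assert res.conversion < 0.5
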