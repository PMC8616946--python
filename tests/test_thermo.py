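"""Unit and property tests for the competing-reaction thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sodscreen import (
    AdsorptionEnergies,
    Conditions,
    DegenerateFitError,
    FreeEnergyModel,
    InvalidInputError,
    ScalingRelation,
    adsorption_energy_from_totals,
    audit_constants,
    criterion_thresholds,
    evaluate_adsorption_criterion,
    fit_scaling_relation,
    o_from_oh,
    partition_fractions,
    reaction_free_energies,
    resolve_o,
    x1_grid,
)

finite_ads = st.floats(min_value=-6.0, max_value=2.0, allow_nan=False)


class TestScalingRelation:
    @pytest.mark.parametrize(
        "ho, expected",
        [(0.0, 1.42), (-2.7, 1.87 * (-2.7) + 1.42), (1.0, 3.29)],
    )
    def test_default_line(self, ho, expected):
        assert o_from_oh(ho) == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InvalidInputError):
            o_from_oh(float("nan"))

    def test_two_point_exact_fit(self):
        rel = fit_scaling_relation([(0.0, 1.0), (1.0, 3.0)])
        assert rel.slope == pytest.approx(2.0, abs=1e-12)
        assert rel.intercept == pytest.approx(1.0, abs=1e-12)
        assert rel.residual_rms == pytest.approx(0.0, abs=1e-12)
        assert rel.n_points == 2

    def test_noiseless_recovery(self):
        x = np.linspace(-5, 0, 50)
        rel = fit_scaling_relation(list(zip(x, 1.87 * x + 1.42)))
        assert rel.slope == pytest.approx(1.87, abs=1e-10)
        assert rel.intercept == pytest.approx(1.42, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateFitError):
            fit_scaling_relation([(1.0, 5.0), (1.0, 6.0)])
        with pytest.raises(DegenerateFitError):
            fit_scaling_relation([(1.0, 5.0)])

    def test_unbiased_under_gaussian_noise(self):
        # mean slope error over repeated noisy refits tends to zero
        errs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-5, 0, 60)
            y = 1.87 * x + 1.42 + rng.normal(0, 0.2, 60)
            errs.append(fit_scaling_relation(list(zip(x, y))).slope - 1.87)
        assert abs(np.mean(errs)) < 0.01

    def test_resolve_o_fills_and_respects_explicit(self):
        filled = resolve_o(AdsorptionEnergies(-1.0, -1.0))
        assert filled.e_ads_o == pytest.approx(1.87 * -1.0 + 1.42)
        explicit = resolve_o(AdsorptionEnergies(-1.0, -1.0, e_ads_o=-2.5))
        assert explicit.e_ads_o == -2.5


class TestReactionFreeEnergies:
    def test_zero_adsorption_gives_canonical_constants(self):
        g = reaction_free_energies(AdsorptionEnergies(0.0, 0.0))
        assert g.drG == pytest.approx((-1.3, 1.4, 2.1, 8.54, 16.4), abs=1e-12)

    def test_threshold_point(self):
        g = reaction_free_energies(AdsorptionEnergies(-2.7, -3.4))
        assert g.drG == pytest.approx((-1.3, -1.3, -1.3, 0.791, 2.902), abs=1e-12)

    def test_ph_shift_is_one_nernst_term_per_reaction(self):
        g7 = reaction_free_energies(AdsorptionEnergies(0.0, 0.0))
        g8 = reaction_free_energies(AdsorptionEnergies(0.0, 0.0), Conditions(ph=8.0))
        for a, b in zip(g7.drG, g8.drG):
            assert b - a == pytest.approx(0.0592, abs=1e-12)

    def test_missing_field_raises(self):
        with pytest.raises(InvalidInputError):
            reaction_free_energies(AdsorptionEnergies(None, 0.0))


class TestPartitionFractions:
    def test_equal_energies_give_uniform_fractions(self):
        res = partition_fractions([1.0] * 5)
        assert res.fractions == pytest.approx((0.2,) * 5, abs=1e-15)
        assert not res.passes  # 0.2 is not > 0.5

    def test_dominant_channel_limit(self):
        res = partition_fractions([-5.0, 5.0, 5.0, 5.0, 5.0])
        assert abs(res.x1 - 1.0) < 1e-30
        assert res.passes

    def test_selectivity_boundary(self):
        g = reaction_free_energies(AdsorptionEnergies(-2.7, 0.0))
        res = partition_fractions(g)
        assert res.x1 == pytest.approx(0.5, abs=1e-6)
        assert not res.passes  # strictly greater than 0.5 required

    def test_extreme_magnitudes_stay_normalised(self):
        kt = Conditions().kt
        res = partition_fractions(np.array([-1e3, 1e3, 0.0, 5e2, -5e2]) * kt)
        assert all(math.isfinite(f) for f in res.fractions)
        assert sum(res.fractions) == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            partition_fractions([0.0, 1.0, float("inf"), 0.0, 0.0])

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=5))
    def test_fractions_normalised_and_bounded(self, drg):
        res = partition_fractions(drg)
        assert sum(res.fractions) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= f <= 1.0 for f in res.fractions)
        assert res.x1 == res.fractions[0]

    @given(finite_ads, finite_ads, st.floats(0.01, 0.5))
    def test_x1_strictly_increasing_in_both_energies(self, ho, h, step):
        base = partition_fractions(reaction_free_energies(AdsorptionEnergies(ho, h)))
        up_ho = partition_fractions(
            reaction_free_energies(AdsorptionEnergies(ho + step, h))
        ).x1
        up_h = partition_fractions(
            reaction_free_energies(AdsorptionEnergies(ho, h + step))
        ).x1
        assert up_ho >= base.x1 and up_h >= base.x1
        # strictness is representable only while the channels that depend on
        # the bumped energy still carry non-negligible Boltzmann weight
        f = base.fractions
        if f[1] + f[3] + f[4] > 1e-9 and base.x1 < 1.0 - 1e-12:
            assert up_ho > base.x1
        if f[2] + f[4] > 1e-9 and base.x1 < 1.0 - 1e-12:
            assert up_h > base.x1

    @given(finite_ads, finite_ads, st.floats(0.0, 14.0))
    def test_x1_invariant_to_ph_with_default_proton_coefficients(self, ho, h, ph):
        ads = AdsorptionEnergies(ho, h)
        at_7 = partition_fractions(reaction_free_energies(ads)).x1
        at_ph = partition_fractions(
            reaction_free_energies(ads, Conditions(ph=ph))
        ).x1
        assert at_ph == pytest.approx(at_7, rel=1e-9, abs=1e-12)


class TestCriterion:
    def test_default_thresholds(self):
        ho, h = criterion_thresholds()
        assert ho == pytest.approx(-2.7, abs=1e-12)
        assert h == pytest.approx(-3.4, abs=1e-12)

    @pytest.mark.parametrize("ph", [0.0, 3.0, 7.0, 11.0, 14.0])
    def test_thresholds_ph_independent_at_defaults(self, ph):
        assert criterion_thresholds(Conditions(ph=ph)) == pytest.approx(
            criterion_thresholds(), abs=1e-12
        )

    def test_custom_constants_direct_solve(self):
        model = FreeEnergyModel(
            constants=(0.0, 1.0, 1.0, 8.54, 16.4),
            ho_coefficients=(0.0, 1.0, 0.0, 2.87, 3.74),
            h_coefficients=(0.0, 0.0, 1.0, 0.0, 1.0),
        )
        ho, _ = criterion_thresholds(model=model)
        assert ho == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "ads, expected",
        [
            (AdsorptionEnergies(-2.0, -3.68), False),  # pristine ceria (111): H* too strong
            (AdsorptionEnergies(-0.76, -4.25), False),  # MIL-47(V)-like frame
            (AdsorptionEnergies(-2.5, -3.0), True),
            (AdsorptionEnergies(-2.7, -1.0), False),  # exactly at threshold fails (strict)
        ],
    )
    def test_rectangle_examples(self, ads, expected):
        passes, x1 = evaluate_adsorption_criterion(ads, mode="rectangle")
        assert passes is expected
        assert 0.0 <= x1 <= 1.0

    @given(finite_ads, finite_ads)
    def test_rectangle_agrees_with_full_x1_away_from_thresholds(self, ho, h):
        ho_thr, h_thr = criterion_thresholds()
        if abs(ho - ho_thr) < 0.1 or abs(h - h_thr) < 0.1:
            return  # thin band near the corner where leading terms compete
        rect, _ = evaluate_adsorption_criterion(AdsorptionEnergies(ho, h), mode="rectangle")
        full, _ = evaluate_adsorption_criterion(AdsorptionEnergies(ho, h), mode="full_x1")
        assert rect == full

    def test_unknown_mode_rejected(self):
        with pytest.raises(InvalidInputError):
            evaluate_adsorption_criterion(AdsorptionEnergies(-1.0, -1.0), mode="banana")


class TestX1Grid:
    def test_pass_region_corners(self):
        grid = x1_grid((-2.0, -0.5), (-2.5, -0.5), 2, 2)
        assert np.all(grid.x1 > 0.5)

    def test_monotone_along_both_axes(self):
        grid = x1_grid((-5.0, 0.0), (-6.0, 0.0), 25, 25)
        assert np.all(np.diff(grid.x1, axis=1) >= 0)  # in e_ads_ho
        assert np.all(np.diff(grid.x1, axis=0) >= 0)  # in e_ads_h

    def test_boundary_cell(self):
        grid = x1_grid((-2.7, 0.0), (0.0, 1.0), 2, 2)
        assert grid.x1[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_invalid_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            x1_grid((-1.0, -1.0), (0.0, 1.0), 2, 2)
        with pytest.raises(InvalidInputError):
            x1_grid((-1.0, 0.0), (0.0, 1.0), 1, 2)


class TestAdsorptionFromTotals:
    @pytest.mark.parametrize(
        "inputs, expected",
        [((-105, -100, -3), -2.0), ((-100, -100, 0), 0.0), ((-104.5, -100, -3), -1.5)],
    )
    def test_arithmetic(self, inputs, expected):
        assert adsorption_energy_from_totals(*inputs) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            adsorption_energy_from_totals(float("nan"), 0.0, 0.0)


class TestConstantsAudit:
    def test_reaction_i_and_ii_reconstruct(self):
        audit = audit_constants()
        # -0.86 + 0.0592*7 - 0.86 = -1.3056, printed -1.3
        assert audit.reconstructed[0] == pytest.approx(-1.3056, abs=1e-10)
        assert abs(audit.reconstructed[0] - audit.printed[0]) < 0.01
        assert not audit.flagged[0]
        # reaction ii constant rounds to 1.4 at two significant figures
        assert round(audit.reconstructed[1], 1) == pytest.approx(1.4)
        assert not audit.flagged[1]

    def test_reactions_iii_to_v_flagged_not_fatal(self):
        audit = audit_constants()
        assert audit.flagged[2] and audit.flagged[3] and audit.flagged[4]
        # the canonical constants are reported unchanged alongside
        assert audit.printed == pytest.approx((-1.3, 1.4, 2.1, 8.54, 16.4))

    def test_scaling_substitution_coefficients(self):
        audit = audit_constants()
        assert audit.ho_coefficients_reconstructed == pytest.approx((0, 1, 0, 2.87, 3.74))
        assert audit.h_coefficients_reconstructed == pytest.approx((0, 0, 1, 0, 1))


class TestConditionsValidation:
    def test_invalid_conditions_rejected(self):
        with pytest.raises(InvalidInputError):
            Conditions(temperature=0.0)
        with pytest.raises(InvalidInputError):
            Conditions(proton_coefficients=(1, 1, 1))
        with pytest.raises(InvalidInputError):
            Conditions(nernst_slope=-0.01)

    def test_scaling_relation_validation(self):
        with pytest.raises(InvalidInputError):
            ScalingRelation(slope=float("inf"))
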