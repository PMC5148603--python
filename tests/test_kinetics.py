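"""Time-course assembly, spontaneous subtraction, rates, efficacy."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from hdxpulse.kinetics import (
    RateEstimate,
    TimeCourse,
    assemble_time_course,
    efficacy_regression,
    fit_kinetic_model,
    initial_rate,
    subtract_spontaneous,
)
from hdxpulse.simulate import KINETIC_PRESETS, KineticPreset, two_state_fraction


def _course(times, fractions, sds=None, condition=None, ns=None):
    times = np.asarray(times, dtype=float)
    return TimeCourse(
        condition=condition or {},
        times=times,
        fractions=np.asarray(fractions, dtype=float),
        sds=np.asarray(sds if sds is not None else np.zeros_like(times)),
        ns=np.asarray(ns if ns is not None else np.full(times.shape, 3)),
    )


class TestAssembleTimeCourse:
    def test_replicates_aggregate_to_mean_and_sd(self):
        records = pd.DataFrame(
            {
                "time_min": [30.0, 30.0, 30.0, 5.0],
                "fraction_unfolded": [0.28, 0.29, 0.30, 0.07],
                "cond": ["a"] * 4,
            }
        )
        course = assemble_time_course(records, condition_cols=("cond",))
        assert course.times == pytest.approx([5.0, 30.0])
        assert course.fractions[1] == pytest.approx(0.29)
        assert course.sds[1] == pytest.approx(0.01)

    def test_single_replicate_sd_is_missing_not_zero(self):
        records = pd.DataFrame(
            {"time_min": [1.0, 2.0], "fraction_unfolded": [0.1, 0.2]}
        )
        course = assemble_time_course(records)
        assert np.isnan(course.sds).all()

    def test_mixed_conditions_rejected(self):
        records = pd.DataFrame(
            {
                "time_min": [1.0, 2.0],
                "fraction_unfolded": [0.1, 0.2],
                "inhibitor": ["wt", "e15k"],
            }
        )
        with pytest.raises(ValueError, match="mixed conditions"):
            assemble_time_course(records, condition_cols=("inhibitor",))

    def test_non_monotone_noisy_course_accepted(self):
        records = pd.DataFrame(
            {"time_min": [1.0, 2.0, 3.0], "fraction_unfolded": [0.10, 0.08, 0.12]}
        )
        course = assemble_time_course(records)
        assert course.fractions == pytest.approx([0.10, 0.08, 0.12])


class TestSubtractSpontaneous:
    def test_self_subtraction_is_zero(self):
        course = _course([1, 5, 30], [0.05, 0.1, 0.3], sds=[0.01, 0.01, 0.02])
        diff = subtract_spontaneous(course, course)
        assert diff.fractions == pytest.approx([0.0, 0.0, 0.0])

    def test_printed_five_minute_example(self):
        catalyzed = _course([5.0, 30.0], [0.603, 0.9])
        spontaneous = _course([5.0, 30.0], [0.070, 0.29])
        diff = subtract_spontaneous(catalyzed, spontaneous)
        assert diff.fractions[0] == pytest.approx(0.533)

    def test_negative_difference_clipped_and_flagged(self):
        catalyzed = _course([1.0, 2.0], [0.05, 0.2])
        spontaneous = _course([1.0, 2.0], [0.08, 0.1])
        diff = subtract_spontaneous(catalyzed, spontaneous)
        assert diff.fractions[0] == 0.0
        assert "clipped_negative" in diff.flags[0]

    def test_sds_combine_in_quadrature(self):
        catalyzed = _course([1.0, 2.0], [0.5, 0.6], sds=[0.03, 0.04])
        spontaneous = _course([1.0, 2.0], [0.1, 0.2], sds=[0.04, 0.03])
        diff = subtract_spontaneous(catalyzed, spontaneous)
        assert diff.sds == pytest.approx([0.05, 0.05])

    def test_mismatched_grids_need_interpolation_flag(self):
        catalyzed = _course([1.0, 2.0], [0.5, 0.6])
        spontaneous = _course([1.0, 3.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="interpolate"):
            subtract_spontaneous(catalyzed, spontaneous)
        diff = subtract_spontaneous(catalyzed, spontaneous, interpolate=True)
        assert diff.fractions[1] == pytest.approx(0.6 - 0.15)


class TestInitialRate:
    def test_exact_linear_points(self):
        course = _course([1, 2, 3], [0.1, 0.2, 0.3])
        estimate = initial_rate(course, substrate_conc_um=10.0)
        assert estimate.rate == pytest.approx(0.1)
        assert estimate.molar_rate == pytest.approx(1.0)

    def test_depleted_point_excluded(self):
        course = _course([1, 2, 30], [0.1, 0.2, 0.9])
        estimate = initial_rate(course, substrate_conc_um=10.0)
        assert (30.0, "substrate_depletion") in estimate.excluded
        assert estimate.rate == pytest.approx(0.1)

    def test_invariant_to_adding_excluded_points(self):
        base = _course([1, 2], [0.1, 0.2])
        extended = _course([1, 2, 20, 40], [0.1, 0.2, 0.8, 0.95])
        a = initial_rate(base, substrate_conc_um=10.0)
        b = initial_rate(extended, substrate_conc_um=10.0)
        assert a.rate == pytest.approx(b.rate)

    def test_linear_phase_cap_excludes_late_points(self):
        course = _course([1, 2, 20], [0.05, 0.1, 0.25])
        estimate = initial_rate(course, max_time=10.0, substrate_conc_um=10.0)
        assert (20.0, "beyond_linear_phase") in estimate.excluded

    def test_withheld_below_two_points(self):
        course = _course([1, 2], [0.1, 0.9])
        estimate = initial_rate(course, substrate_conc_um=10.0)
        assert estimate.withheld
        assert math.isnan(estimate.rate)

    def test_small_time_limit_recovers_total_rate(self):
        """At small t the slope of u(t) approaches k_spont + k_cat_eff."""
        preset = KINETIC_PRESETS["wt"]  # k_cat_eff = 1.6 * 1 / 10 = 0.16
        times = np.array([0.01, 0.02, 0.03, 0.04])
        course = _course(times, two_state_fraction(times, preset))
        estimate = initial_rate(course, substrate_conc_um=10.0)
        assert estimate.rate == pytest.approx(
            preset.k_spont + 0.16, rel=0.02
        )


class TestEfficacyRegression:
    def test_exact_rates_give_printed_efficacy(self):
        rates = {
            conc: RateEstimate(rate, rate * 10.0, 0.0, (1.0, 2.0), (), 2)
            for conc, rate in [(1.0, 0.16), (0.5, 0.08), (0.25, 0.04)]
        }
        estimate = efficacy_regression(rates, substrate_conc_um=10.0)
        assert estimate.efficacy == pytest.approx(1.6, abs=1e-9)
        assert estimate.intercept == pytest.approx(0.0, abs=1e-9)
        assert estimate.through_origin_efficacy == pytest.approx(1.6, abs=1e-9)
        assert estimate.r_squared == pytest.approx(1.0)

    def test_zero_rates_give_zero_efficacy(self):
        rates = {
            conc: RateEstimate(0.0, 0.0, 0.0, (1.0, 2.0), (), 2)
            for conc in (0.5, 1.0)
        }
        assert efficacy_regression(rates, 10.0).efficacy == pytest.approx(0.0)

    def test_single_concentration_rejected(self):
        rates = {1.0: RateEstimate(0.1, 1.0, 0.0, (1.0, 2.0), (), 2)}
        with pytest.raises(ValueError):
            efficacy_regression(rates, 10.0)

    def test_withheld_rates_skipped(self):
        rates = {
            1.0: RateEstimate(0.16, 1.6, 0.0, (1.0,), (), 1, "fewer than 2 usable points"),
            0.5: RateEstimate(0.08, 0.8, 0.0, (1.0, 2.0), (), 2),
            0.25: RateEstimate(0.04, 0.4, 0.0, (1.0, 2.0), (), 2),
        }
        estimate = efficacy_regression(rates, 10.0)
        assert estimate.n_concentrations == 2
        assert estimate.efficacy == pytest.approx(1.6)

    def test_molar_rate_units(self):
        estimate = RateEstimate(0.08, 0.8, 0.0, (1.0,), (), 1)
        assert estimate.molar_rate == pytest.approx(estimate.rate * 10.0)


class TestGlobalKineticFit:
    @staticmethod
    def _noisy_courses(template, concs, k_decay, rng):
        times = np.array([0.5, 1.0, 2.5, 5.0, 10.0, 20.0])
        courses = {}
        for conc in [0.0] + list(concs):
            preset = dataclasses.replace(
                template,
                efficacy=0.0 if conc == 0 else template.efficacy,
                inhibitor_conc_um=conc if conc > 0 else 1.0,
                k_decay=k_decay,
            )
            truth = two_state_fraction(times, preset)
            noisy = np.clip(truth + rng.normal(0, 0.005, times.size), 0, 1)
            courses[conc] = _course(times, noisy, sds=np.full(times.size, 0.005))
        return courses

    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(12)
        template = KINETIC_PRESETS["wt"]
        courses = self._noisy_courses(template, (0.25, 0.5, 1.0), 0.0, rng)
        fit = fit_kinetic_model(courses, template, fix_k_decay=0.0)
        assert fit.k_spont == pytest.approx(0.0114, rel=0.10)
        assert fit.efficacy == pytest.approx(1.6, rel=0.10)
        assert fit.fixed_k_decay

    def test_decay_model_preferred_for_e15k_like_data(self):
        rng = np.random.default_rng(13)
        template = KINETIC_PRESETS["e15k"]
        courses = self._noisy_courses(template, (0.5, 1.0, 2.0), 0.05, rng)
        with_decay = fit_kinetic_model(courses, template)
        without = fit_kinetic_model(courses, template, fix_k_decay=0.0)
        assert with_decay.aic < without.aic
        assert with_decay.k_decay == pytest.approx(0.05, rel=0.3)

    def test_missing_control_rejected(self):
        course = _course([1, 2], [0.1, 0.2])
        with pytest.raises(ValueError, match="spontaneous control"):
            fit_kinetic_model({1.0: course, 0.5: course}, KINETIC_PRESETS["wt"])

    def test_single_time_point_not_identifiable(self):
        times = np.array([5.0])
        single = TimeCourse({}, times, np.array([0.1]), np.array([0.01]), np.array([3]))
        with pytest.raises(ValueError, match="single time point"):
            fit_kinetic_model({0.0: single, 1.0: single}, KINETIC_PRESETS["wt"])
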