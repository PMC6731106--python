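"""Bliss scoring: ratios, filter, t-test oracle, tables."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from radscreen.plate_io import Condition
from radscreen.simulate import DesignParams, HillParams, NoiseParams, default_config, simulate_screen
from radscreen.synergy import (
    DegenerateVarianceError,
    InsufficientReplicatesError,
    PairingError,
    UndefinedRatioError,
    apply_inclusion_filter,
    bliss_expected,
    format_cell,
    holm_adjust,
    interaction_frame,
    interaction_ratio,
    one_sample_t_test,
    render_interaction_table,
    score_interactions,
)
from radscreen.viability import Readout, ViabilityValue, summarize_conditions


def vv(drug: str, conc: float, dose: float, value: float, eid: str = "E1") -> ViabilityValue:
    return ViabilityValue(Condition(drug, conc, dose), eid, value, 2, Readout.SI_FMCA)


class TestBlissExpected:
    @pytest.mark.parametrize(
        "drug_s,rad_s,expected",
        [(1.0, 0.37, 0.37), (0.5, 0.5, 0.25), (0.0, 0.9, 0.0)],
    )
    def test_product_rule(self, drug_s, rad_s, expected):
        assert bliss_expected(drug_s, rad_s) == expected

    def test_rejects_negative_survival(self):
        with pytest.raises(ValueError):
            bliss_expected(-0.1, 0.5)


class TestInteractionRatio:
    def test_additivity_gives_one(self):
        assert interaction_ratio(0.08, 0.08) == 1.0

    def test_hand_arithmetic(self):
        assert interaction_ratio(0.06, 0.08) == pytest.approx(0.75)

    def test_zero_expected_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            interaction_ratio(0.1, 0.0)

    @given(st.lists(st.floats(0.01, 2.0), min_size=2, max_size=6, unique=True))
    def test_strictly_increasing_in_observed(self, observed):
        ratios = [interaction_ratio(o, 0.3) for o in sorted(observed)]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))


class TestOneSampleTTest:
    def test_mean_exactly_at_null_gives_t_zero(self):
        t, p = one_sample_t_test([0.9, 1.1])
        assert t == 0.0
        assert p == 1.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 11))
            x = rng.normal(1.0, 0.2, size=n)
            t, p = one_sample_t_test(x, 1.0)
            ref = stats.ttest_1samp(x, popmean=1.0)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_single_value_insufficient(self):
        with pytest.raises(InsufficientReplicatesError):
            one_sample_t_test([1.0])

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            one_sample_t_test([1.0, 1.0, 1.0])

    def test_rounding_residue_treated_as_degenerate(self):
        x = [0.9999999999999999] * 5  # identical up to floating rounding
        with pytest.raises(DegenerateVarianceError):
            one_sample_t_test(x)


class TestInclusionFilter:
    @pytest.mark.parametrize(
        "mean_si,expected",
        [(0.24, False), (0.25, False), (0.2500001, True), (0.93, True)],
    )
    def test_strict_threshold(self, mean_si, expected):
        flags = apply_inclusion_filter([vv("d", 1.0, 0.0, mean_si)])
        assert flags[("d", 1.0)] is expected

    def test_filter_uses_across_experiment_mean(self):
        values = [vv("d", 1.0, 0.0, 0.1, "E1"), vv("d", 1.0, 0.0, 0.5, "E2")]
        assert apply_inclusion_filter(values)[("d", 1.0)] is True  # mean 0.3

    def test_empty_input_empty_output(self):
        assert apply_inclusion_filter([]) == {}


def additive_values(n_experiments: int = 3, si_d: float = 0.5) -> list[ViabilityValue]:
    out = []
    for i in range(n_experiments):
        eid = f"E{i + 1}"
        out += [
            vv("d", 1.0, 0.0, si_d, eid),
            vv("", 0.0, 6.0, 0.8, eid),
            vv("d", 1.0, 6.0, si_d * 0.8, eid),
        ]
    return out


class TestScoreInteractions:
    def test_additive_input_gives_unit_ratio_no_significance(self):
        recs = score_interactions(additive_values())
        assert len(recs) == 1
        r = recs[0]
        assert r.mean_ratio == pytest.approx(1.0, abs=1e-12)
        assert r.n_experiments == 3
        assert not r.significant
        assert r.p_value is None  # identical ratios: no variance, no test

    def test_single_experiment_ratio_without_p(self):
        recs = score_interactions(additive_values(n_experiments=1))
        r = recs[0]
        assert r.per_experiment_ratios == (1.0,)
        assert r.p_value is None and r.t_statistic is None

    def test_excluded_condition_has_no_statistics(self):
        recs = score_interactions(additive_values(si_d=0.1))
        r = recs[0]
        assert not r.included
        assert r.per_experiment_ratios == ()
        assert r.mean_ratio is None and r.p_value is None
        assert not r.significant and not r.synergistic_tendency

    def test_no_common_experiment_is_pairing_error(self):
        values = [
            vv("d", 1.0, 0.0, 0.5, "E1"),
            vv("", 0.0, 6.0, 0.8, "E2"),  # radiation measured in another experiment
            vv("d", 1.0, 6.0, 0.4, "E1"),
        ]
        with pytest.raises(PairingError):
            score_interactions(values)

    def test_noise_free_simulation_recovers_rho(self):
        config = default_config(
            drugs={"d": HillParams(ec50=1.0, floor=0.5)},
            design=DesignParams(n_experiments=3, concentrations=(3.0, 1.0, 0.3), doses=(6.0,)),
            noise=NoiseParams(well_cv=0.0, experiment_cv=0.0),
            interaction=0.85,
        )
        recs = score_interactions(summarize_conditions(simulate_screen(config, seed=1)))
        for r in recs:
            assert r.included
            assert r.mean_ratio == pytest.approx(0.85, abs=1e-12)
            assert r.synergistic_tendency

    def test_per_experiment_pairing_uses_matching_experiment(self):
        # experiment-specific radiation efficacy must pair within experiment
        values = [
            vv("d", 1.0, 0.0, 0.5, "E1"), vv("", 0.0, 6.0, 0.8, "E1"),
            vv("d", 1.0, 6.0, 0.5 * 0.8, "E1"),
            vv("d", 1.0, 0.0, 0.6, "E2"), vv("", 0.0, 6.0, 0.5, "E2"),
            vv("d", 1.0, 6.0, 0.6 * 0.5, "E2"),
        ]
        r = score_interactions(values)[0]
        assert r.per_experiment_ratios == pytest.approx((1.0, 1.0))

    def test_log_ratio_variant_tests_logs(self):
        values = []
        ratios = [0.7, 0.8, 0.75]
        for i, rho in enumerate(ratios):
            eid = f"E{i + 1}"
            values += [
                vv("d", 1.0, 0.0, 0.5, eid),
                vv("", 0.0, 6.0, 0.8, eid),
                vv("d", 1.0, 6.0, 0.5 * 0.8 * rho, eid),
            ]
        r = score_interactions(values, log_ratios=True)
        t_ref, p_ref = one_sample_t_test([math.log(x) for x in ratios], 0.0)
        assert r[0].t_statistic == pytest.approx(t_ref)
        assert r[0].p_value == pytest.approx(p_ref)
        assert r[0].mean_ratio == pytest.approx(np.mean(ratios))

    def test_holm_adjustment_is_monotone_and_conservative(self):
        p = [0.01, 0.04, 0.03]
        adj = holm_adjust(p)
        assert all(a >= b for a, b in zip(adj, p))
        assert adj == [0.03, 0.06, 0.06]


class TestRenderTable:
    def _records(self, si_top=0.1):
        values = []
        for i in range(3):
            eid = f"E{i + 1}"
            for rank, conc in enumerate((10.0, 1.0, 0.1)):
                si_d = si_top if rank == 0 else 0.6
                values += [
                    vv("d", conc, 0.0, si_d, eid),
                    vv("d", conc, 6.0, si_d * 0.8 * (0.72 + 0.01 * i), eid),
                ]
            values.append(vv("", 0.0, 6.0, 0.8, eid))
        return score_interactions(values)

    def test_na_for_excluded_and_marks_for_synergy(self):
        text = render_interaction_table(self._records(), dose=6.0)
        lines = text.strip().splitlines()
        assert lines[0] == "ratio\td"
        assert lines[1] == "Highest conc.\tN/A"
        assert "0.73" in lines[2] and "**" in lines[2] and "*" in lines[2]
        assert lines[3].startswith("Lowest conc.")

    def test_significant_synergistic_cell_format(self):
        recs = self._records()
        cell = format_cell([r for r in recs if r.included][0])
        assert cell == "**0.73***"  # bold 0.73 with significance asterisk

    def test_empty_records_render_header_only(self):
        assert render_interaction_table([]) == "ratio\n"

    def test_frame_twin_carries_flags(self):
        df = interaction_frame(self._records())
        assert list(df["included"]) == [False, True, True]
        assert df.loc[~df["included"], "mean_ratio"].isna().all()

    def test_multi_dose_columns_per_drug_dose(self):
        values = []
        for i in range(2):
            eid = f"E{i + 1}"
            for dose in (4.0, 6.0):
                values.append(vv("", 0.0, dose, 0.8, eid))
                values.append(vv("d", 1.0, dose, 0.6 * 0.8 * (0.9 + 0.01 * i), eid))
            values.append(vv("d", 1.0, 0.0, 0.6, eid))
        text = render_interaction_table(score_interactions(values))
        assert text.splitlines()[0] == "ratio\td + 4 Gy\td + 6 Gy"
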