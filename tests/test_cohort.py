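"""Cohort statistics: long table, mixed models, correlations, labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from critspeed import (
    ModelFamily,
    Params,
    SyntheticConfig,
    assemble_long_table,
    correlation_label,
    fit_battery,
    holm_adjust,
    icc_label,
    log_scale_association,
    mixed_model_effects,
    percent_difference,
    sample_cohort,
    variance_explained,
)

TWO, THREE, EXP = ModelFamily.TWO_PARAM, ModelFamily.THREE_PARAM, ModelFamily.THREE_PARAM_EXP


@pytest.fixture(scope="module")
def small_batteries():
    cohort = sample_cohort(SyntheticConfig(n_participants=4, noise_model="none", seed=8))
    return {p.participant_id: fit_battery(p.trials) for p in cohort.participants}


def simulated_cs_table(rng, n=16, offsets=(0.0, -0.27, 0.16), participant_sd=0.4,
                       resid_sd=0.05):
    """CS long table with known family offsets and variance structure."""
    rows = []
    fam_off = dict(zip(("2p", "3p", "3pexp"), offsets))
    for i in range(n):
        b = rng.normal(0.0, participant_sd)
        for fam, off in fam_off.items():
            for form in ("ts", "ds"):
                rows.append(
                    dict(participant_id=f"P{i:02d}", family=fam, formulation=form,
                         outcome="cs", value=4.4 + b + off + rng.normal(0.0, resid_sd))
                )
    return pd.DataFrame(rows)


class TestAssembleLongTable:
    def test_counts_full_battery(self, small_batteries):
        table = assemble_long_table(small_batteries)
        counts = table.groupby("outcome").size()
        assert counts["cs"] == 4 * 6
        assert counts["d_prime"] == 4 * 6
        assert counts["s_max"] == 4 * 4  # absent for the two-parameter family
        assert table.attrs["n_excluded"] == 0

    def test_flagged_fit_excluded_and_counted(self, small_batteries):
        batteries = dict(small_batteries)
        pid = next(iter(batteries))
        crippled = list(batteries[pid])
        crippled[0] = crippled[0].__class__(**{**crippled[0].__dict__, "converged": False})
        batteries[pid] = crippled
        table = assemble_long_table(batteries)
        assert table.attrs["n_excluded"] == 1
        assert len(table[table["outcome"] == "cs"]) == 4 * 6 - 1

    def test_duplicate_cell_rejected(self, small_batteries):
        pid = next(iter(small_batteries))
        doubled = {pid: small_batteries[pid] + small_batteries[pid][:1]}
        with pytest.raises(ValueError, match="duplicate"):
            assemble_long_table(doubled)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            assemble_long_table({})

    def test_exp_dprime_is_derived_dmax(self, small_batteries):
        from critspeed import dprime_max_exp

        table = assemble_long_table(small_batteries)
        pid = next(iter(small_batteries))
        fit = next(
            f for f in small_batteries[pid]
            if f.spec.family is EXP and f.spec.formulation.value == "ts"
        )
        row = table[
            (table.participant_id == pid) & (table.family == "3pexp")
            & (table.formulation == "ts") & (table.outcome == "d_prime")
        ]
        assert row["value"].iloc[0] == pytest.approx(dprime_max_exp(fit.params))


class TestVarianceExplained:
    def test_constructed_decomposition(self):
        r2m, r2c, icc = variance_explained(14.0, 82.0, 4.0)
        assert r2m == pytest.approx(0.14)
        assert r2c == pytest.approx(0.96)
        assert icc == pytest.approx(0.953, abs=5e-4)

    def test_null_case(self):
        assert variance_explained(0.0, 0.0, 0.0) == (0.0, 0.0, 0.0)

    @given(st.floats(0, 100), st.floats(0, 100), st.floats(1e-6, 100))
    def test_invariants(self, vf, vr, ve):
        r2m, r2c, icc = variance_explained(vf, vr, ve)
        assert 0 <= r2m <= r2c <= 1
        assert 0 <= icc <= 1


class TestMixedModelEffects:
    def test_detects_family_not_formulation(self):
        table = simulated_cs_table(np.random.default_rng(42))
        mm = mixed_model_effects(table, "cs")
        assert mm.fixed_effect_p["family"] < 0.05
        assert mm.fixed_effect_p["formulation"] > 0.05
        assert 0 <= mm.r2_marginal <= mm.r2_conditional <= 1
        assert mm.icc > 0.9  # participant spread dominates the residual
        assert len(mm.posthoc) == 3
        assert all(p < 0.05 for _, p in mm.posthoc)

    def test_null_effects_near_zero_components(self):
        table = simulated_cs_table(
            np.random.default_rng(7), offsets=(0.0, 0.0, 0.0), participant_sd=0.0,
            resid_sd=0.05,
        )
        mm = mixed_model_effects(table, "cs")
        assert mm.r2_marginal < 0.2
        assert mm.icc < 0.3
        assert mm.r2_marginal <= mm.r2_conditional

    def test_variance_component_recovery(self):
        """Participant and residual SDs recovered within 25 % at n = 64."""
        rel_err_random, rel_err_resid = [], []
        for seed in range(5):
            table = simulated_cs_table(np.random.default_rng(100 + seed), n=64)
            mm = mixed_model_effects(table, "cs")
            rel_err_random.append(abs(np.sqrt(mm.var_random) - 0.4) / 0.4)
            rel_err_resid.append(abs(np.sqrt(mm.var_resid) - 0.05) / 0.05)
        assert np.median(rel_err_random) < 0.25
        assert np.median(rel_err_resid) < 0.25

    def test_two_level_family_factor(self):
        table = simulated_cs_table(np.random.default_rng(3))
        table = table[table["family"] != "2p"]
        mm = mixed_model_effects(table, "cs")
        assert mm.fixed_effect_p["family"] < 0.05

    def test_single_family_rejected(self):
        table = simulated_cs_table(np.random.default_rng(3))
        with pytest.raises(ValueError):
            mixed_model_effects(table[table["family"] == "2p"], "cs")


class TestLogScaleAssociation:
    def test_perfect_proportionality(self):
        x = np.array([40.0, 45.0, 50.0, 55.0, 60.0])
        res = log_scale_association(x, 0.08 * x)
        assert res.r == pytest.approx(1.0)
        assert res.see_percent == pytest.approx(0.0, abs=1e-9)
        assert res.delta_percent == pytest.approx(0.0, abs=1e-9)

    def test_reciprocal_is_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 9.0])
        assert log_scale_association(x, 1.0 / x).r == pytest.approx(-1.0)

    def test_independent_lognormals_near_zero(self):
        rng = np.random.default_rng(12)
        x = np.exp(rng.normal(size=500))
        y = np.exp(rng.normal(size=500))
        res = log_scale_association(x, y)
        assert abs(res.r) < 0.2
        assert res.ci90[0] < res.r < res.ci90[1]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_scale_association([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            log_scale_association([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestPercentDifference:
    @pytest.mark.parametrize(
        "smaller,larger,expected",
        [(4.12, 4.39, 6.15), (4.12, 4.55, 9.45), (3.0, 3.0, 0.0)],
    )
    def test_values(self, smaller, larger, expected):
        assert percent_difference(smaller, larger) == pytest.approx(expected, abs=0.005)

    def test_integer_rounding_matches_reported_comparisons(self):
        assert round(percent_difference(4.12, 4.39)) == 6
        assert round(percent_difference(4.12, 4.55)) == 9

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestHolm:
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_never_decreases_and_monotone(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestLabels:
    @pytest.mark.parametrize(
        "icc,label",
        [(0.0, "poor"), (0.49, "poor"), (0.5, "moderate"), (0.749, "moderate"),
         (0.75, "good"), (0.89, "good"), (0.9, "excellent"), (1.0, "excellent")],
    )
    def test_icc_labels(self, icc, label):
        assert icc_label(icc) == label

    @pytest.mark.parametrize(
        "r,label",
        [(0.0, "negligible"), (0.29, "negligible"), (0.3, "low"), (0.5, "moderate"),
         (0.7, "high"), (0.9, "very high"), (-0.95, "very high"), (1.0, "very high")],
    )
    def test_correlation_labels(self, r, label):
        assert correlation_label(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            icc_label(1.2)
        with pytest.raises(ValueError):
            correlation_label(1.2)
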