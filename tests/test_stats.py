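import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitload import (
    GaitloadError,
    aggregate_trial,
    assign_mode_slots,
    bonferroni_contrasts,
    correlations,
    diagnostics,
    emm_noload,
    emmeans,
    fit_lmm,
)
from gaitload.synthetic import simulate_trial_table
from gaitload.stats import LOAD_ORDER


def _balanced_table(rng=None, effects=None, trial_sd=0.0, participant_sd=0.0,
                    n_participants=4):
    return simulate_trial_table(
        n_participants=n_participants, rng=rng or np.random.default_rng(0),
        participant_sd=participant_sd, trial_sd=trial_sd,
        rel_speed_sd=0.0, trial_rel_sd=0.0, effects=effects,
    )


class TestAggregateTrial:
    def test_identical_cycles_unchanged(self):
        rows = []
        for cycle in range(2, 7):
            rows.append({"participant_id": "P01", "carry_mode": "side",
                         "load_kg": 4.5, "trial_index": 1, "cycle": cycle,
                         "mrp_coronal": 110.0, "relative_speed": 1.1,
                         "centered_relative_speed": 0.01})
        out = aggregate_trial(pd.DataFrame(rows))
        assert len(out) == 1
        assert out["mrp_coronal"].iloc[0] == 110.0

    def test_nan_cycle_ignored_in_mean(self):
        rows = []
        vals = [100.0, 100.0, 100.0, 100.0, np.nan]
        for cycle, v in zip(range(2, 7), vals):
            rows.append({"participant_id": "P01", "carry_mode": "side",
                         "load_kg": 4.5, "trial_index": 1, "cycle": cycle,
                         "mrp_coronal": v, "relative_speed": 1.1,
                         "centered_relative_speed": 0.0})
        out = aggregate_trial(pd.DataFrame(rows))
        assert out["mrp_coronal"].iloc[0] == 100.0


class TestModeSlots:
    def test_noload_split_between_modes(self):
        tab = _balanced_table()
        tt = assign_mode_slots(tab)
        nl = tt[tt["load_kg"] == 0.0]
        per = nl.groupby(["participant_id", "mode"]).size()
        assert (per == 2).all()
        assert set(tt["mode"]) == {"side", "anterior"}

    def test_loaded_trials_keep_their_mode(self):
        tt = assign_mode_slots(_balanced_table())
        loaded = tt[tt["load_kg"] > 0]
        assert (loaded["mode"] == loaded["carry_mode"]).all()


class TestFitAndEmm:
    def test_emm_equals_cell_means_balanced_noise_free(self):
        effects = {("side", "H"): 20.0, ("anterior", "L"): -5.0}
        tt = assign_mode_slots(_balanced_table(effects=effects))
        fit = fit_lmm(tt, "mrp_coronal")
        emm = emmeans(fit)
        cells = tt.groupby(["mode", "load_kg"])["mrp_coronal"].mean()
        for _, row in emm.iterrows():
            assert row["emm"] == pytest.approx(cells[(row["mode"], row["load_kg"])], abs=1e-6)

    def test_injected_effect_recovered(self):
        effects = {("side", "H"): 20.0}
        rng = np.random.default_rng(12)
        tt = assign_mode_slots(
            simulate_trial_table(rng=rng, effects=effects, trial_sd=2.0,
                                 participant_sd=4.0)
        )
        fit = fit_lmm(tt, "mrp_coronal")
        ct = bonferroni_contrasts(fit)
        row = ct[(ct["family"] == "mode_within_load") & (ct["level"] == "H")].iloc[0]
        assert row["estimate"] == pytest.approx(20.0, abs=3.0)
        assert row["p_adj"] < 0.05

    def test_power_for_mode_effect(self):
        """A +20 deg side-vs-anterior offset at realistic noise is detected
        in at least 80% of simulated studies."""
        effects = {("side", l): 20.0 for l in ("NL", "L", "M", "H")}
        hits = 0
        n_sim = 20
        for i in range(n_sim):
            tt = assign_mode_slots(
                simulate_trial_table(rng=np.random.default_rng(500 + i), effects=effects)
            )
            fit = fit_lmm(tt, "mrp_coronal")
            p = fit.anova.set_index("term").loc["mode", "p"]
            hits += p < 0.05
        assert hits >= 0.8 * n_sim

    def test_constant_response_degenerate_not_crashing(self):
        tt = assign_mode_slots(_balanced_table())
        tt["mrp_coronal"] = 42.0
        fit = fit_lmm(tt, "mrp_coronal")
        assert fit.structure == "degenerate"
        assert (fit.anova["F"] == 0.0).all()
        assert (fit.anova["p"] == 1.0).all()

    def test_noload_emm_invariant_to_slot_labels(self):
        rng = np.random.default_rng(7)
        tab = simulate_trial_table(rng=rng, trial_sd=3.0, participant_sd=5.0)
        tt = assign_mode_slots(tab)
        fit = fit_lmm(tt, "mrp_coronal")
        # swap which no-load trials go to which mode
        swapped = tt.copy()
        nl = swapped["load_kg"] == 0.0
        swapped.loc[nl, "mode"] = swapped.loc[nl, "mode"].map(
            {"side": "anterior", "anterior": "side"}
        )
        fit2 = fit_lmm(swapped, "mrp_coronal")
        assert emm_noload(fit) == pytest.approx(emm_noload(fit2), abs=1e-6)

    def test_two_participants_required(self):
        tab = _balanced_table(n_participants=1)
        with pytest.raises(GaitloadError, match="2 participants"):
            fit_lmm(assign_mode_slots(tab), "mrp_coronal")


class TestBonferroni:
    def test_adjustment_multiplies_and_caps(self):
        tt = assign_mode_slots(_balanced_table(
            rng=np.random.default_rng(3), trial_sd=5.0, participant_sd=3.0))
        fit = fit_lmm(tt, "mrp_coronal")
        ct = bonferroni_contrasts(fit)
        load_rows = ct[ct["family"] == "load_within_mode"]
        assert np.allclose(
            load_rows["p_adj"], np.minimum(1.0, 6 * load_rows["p_raw"]), atol=1e-12
        )
        mode_rows = ct[ct["family"] == "mode_within_load"]
        assert np.allclose(mode_rows["p_adj"], np.minimum(1.0, mode_rows["p_raw"]))
        assert (ct["p_adj"] >= ct["p_raw"] - 1e-15).all()
        assert (ct["p_adj"] <= 1.0).all()
        assert len(load_rows) == 12 and len(mode_rows) == 4

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(p=st.floats(1e-8, 1.0), m=st.integers(1, 10))
    def test_adjusted_p_monotone_in_raw(self, p, m):
        assert min(1.0, m * p) >= p - 1e-15
        assert min(1.0, m * 0.02) == pytest.approx(min(1.0, 0.02 * m))


class TestCorrelationsAndDiagnostics:
    def test_self_correlation_unity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"mrp_coronal": rng.normal(size=30)})
        df["mrp_transverse"] = 2 * df["mrp_coronal"] + rng.normal(0, 1e-9, 30)
        c = correlations(df, ["mrp_coronal", "mrp_transverse"])
        assert c.loc["mrp_coronal", "mrp_coronal"] == pytest.approx(1.0)
        assert c.loc["mrp_coronal", "mrp_transverse"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_column_reported_missing(self):
        df = pd.DataFrame({"mrp_coronal": np.arange(10.0), "mrp_sagittal": np.ones(10)})
        c = correlations(df, ["mrp_coronal", "mrp_sagittal"])
        assert np.isnan(c.loc["mrp_coronal", "mrp_sagittal"])

    def test_independent_columns_mostly_uncorrelated(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(40):
            x, y = rng.normal(size=(2, 144))
            r = np.corrcoef(x, y)[0, 1]
            hits += abs(r) < 0.25
        assert hits >= 0.95 * 40

    def test_too_few_rows_rejected(self):
        with pytest.raises(GaitloadError):
            correlations(pd.DataFrame({"mrp_coronal": [1.0, 2.0]}))

    def test_diagnostics_summary(self):
        tt = assign_mode_slots(_balanced_table(
            rng=np.random.default_rng(9), trial_sd=4.0, participant_sd=2.0))
        fit = fit_lmm(tt, "mrp_coronal")
        d = diagnostics(fit)
        assert len(d["residual_table"]) == fit.n_obs
        assert 0.0 <= d["shapiro_p"] <= 1.0
        assert d["structure"] in ("intercept+slope", "intercept", "ols")
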