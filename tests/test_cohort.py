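"""Mixed-model estimates: correction effect, AL interaction, group contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octmag import (
    EffectEstimate,
    adjust_pvalues,
    analyze_cohort,
    cohort_table,
    fit_al_interaction,
    fit_correction_effect,
    fit_group_contrast,
)


def _long_table(n_participants, rng, sectors=("C",), al_mean=23.6, al_sd=0.9,
                participant_sd=10.0, eye_sd=3.0, noise_sd=1.0,
                correction_fn=None, group_effect=0.0):
    """Hand-built analysis table with a known data-generating process.

    ``correction_fn(al)`` gives the true per-eye (corrected − raw)
    difference; ``group_effect`` shifts myopic eyes in both states.
    """
    correction_fn = correction_fn or (lambda al: 0.0)
    rows = []
    for i in range(n_participants):
        pid = f"P{i:04d}"
        base = 300.0 + rng.normal(0, participant_sd)
        sex = "M" if rng.random() < 0.5 else "F"
        eth = rng.choice(["Caucasian", "East Asian", "other/mixed"])
        al_p = rng.normal(al_mean, al_sd)
        for eye in ("OD", "OS"):
            al = al_p + rng.normal(0, 0.25)
            group = "myope" if al > 24.1 else "non-myope"
            raw = base + rng.normal(0, eye_sd) \
                + (group_effect if group == "myope" else 0.0)
            for corr, value in ((False, raw),
                                (True, raw + correction_fn(al))):
                for sector in sectors:
                    rows.append({
                        "participant_id": pid, "eye": eye, "sector": sector,
                        "corrected": corr,
                        "thickness_um": value + rng.normal(0, noise_sd),
                        "axial_length_mm": al, "refractive_group": group,
                        "sex": sex, "ethnicity": eth,
                        "corr01": int(corr),
                        "is_myope": int(group == "myope"),
                    })
    return pd.DataFrame(rows)


class TestCohortTable:
    def _inputs(self):
        sector_df = pd.DataFrame([
            {"participant_id": "P1", "eye": "OD", "corrected": c,
             "sector": s, "mean_um": 300.0, "n_pixels": 10,
             "truncation_fraction": 0.0}
            for c in (False, True) for s in ("C", "T2")])
        biometry = pd.DataFrame([{
            "participant_id": "P1", "eye": "OD", "axial_length_mm": 23.0,
            "sex": "F", "ethnicity": "Caucasian",
            "refractive_group": "non-myope"}])
        return sector_df, biometry

    def test_join_produces_paired_rows(self):
        sector_df, biometry = self._inputs()
        table = cohort_table(sector_df, biometry)
        assert len(table) == 4
        assert set(table["corr01"]) == {0, 1}
        assert (table["thickness_um"] == 300.0).all()

    def test_eye_missing_from_biometry_rejected(self):
        sector_df, biometry = self._inputs()
        with pytest.raises(ValueError, match="missing from biometry"):
            cohort_table(sector_df, biometry.iloc[0:0])

    def test_unpaired_rows_rejected(self):
        sector_df, biometry = self._inputs()
        with pytest.raises(ValueError, match="raw and one corrected"):
            cohort_table(sector_df[sector_df["corrected"]], biometry)


class TestCorrectionEffect:
    def test_identical_states_give_exact_zero(self):
        rng = np.random.default_rng(0)
        table = _long_table(30, rng)  # correction_fn ≡ 0 but noise differs
        table.loc[table.corr01 == 1, "thickness_um"] = \
            table.loc[table.corr01 == 0, "thickness_um"].to_numpy()
        est = fit_correction_effect(table, "C")
        assert est.estimate == 0.0
        assert est.ci_low == est.ci_high == 0.0
        assert est.p_value == 1.0
        assert est.model == "degenerate_zero_difference"

    def test_noise_free_effect_equals_mean_paired_difference(self):
        """With no residual noise the fixed effect reproduces the arithmetic
        mean of the per-eye (corrected − raw) differences exactly."""
        rng = np.random.default_rng(1)
        table = _long_table(25, rng, noise_sd=0.0,
                            correction_fn=lambda al: 3.0 + 2.0 * (al - 23.6))
        wide = table.pivot_table(index=["participant_id", "eye"],
                                 columns="corr01", values="thickness_um")
        target = (wide[1] - wide[0]).mean()
        est = fit_correction_effect(table, "C")
        assert est.estimate == pytest.approx(target, abs=1e-6)

    def test_recovers_injected_effect_within_ci(self):
        rng = np.random.default_rng(2)
        table = _long_table(60, rng, correction_fn=lambda al: 4.0)
        est = fit_correction_effect(table, "C")
        assert est.ci_low < 4.0 < est.ci_high
        assert est.p_value < 0.001

    def test_pooled_estimate_between_half_cohorts(self):
        rng = np.random.default_rng(3)
        half_a = _long_table(40, rng, correction_fn=lambda al: 2.0)
        half_b = _long_table(40, rng, correction_fn=lambda al: 6.0)
        half_b["participant_id"] = "B" + half_b["participant_id"]
        pooled = pd.concat([half_a, half_b], ignore_index=True)
        est_a = fit_correction_effect(half_a, "C").estimate
        est_b = fit_correction_effect(half_b, "C").estimate
        est_p = fit_correction_effect(pooled, "C").estimate
        assert min(est_a, est_b) < est_p < max(est_a, est_b)

    def test_requires_two_participants(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="two participants"):
            fit_correction_effect(_long_table(1, rng), "C")


class TestAlInteraction:
    def test_no_magnification_interaction_near_zero(self):
        """Correction identical to raw for every eye: the AL×correction
        interaction is estimated at ~0 with a CI covering 0."""
        rng = np.random.default_rng(5)
        table = _long_table(60, rng, al_mean=24.385, al_sd=0.5)
        table.loc[table.corr01 == 1, "thickness_um"] = \
            table.loc[table.corr01 == 0, "thickness_um"].to_numpy()
        res = fit_al_interaction(table, "C")
        assert res.interaction.estimate == pytest.approx(0.0, abs=1.0)
        assert res.interaction.ci_low <= 0.0 <= res.interaction.ci_high

    def test_recovers_known_interaction_and_simple_slopes(self):
        rng = np.random.default_rng(6)
        table = _long_table(80, rng,
                            correction_fn=lambda al: 1.5 * (al - 24.0))
        res = fit_al_interaction(table, "C")
        assert res.interaction.ci_low < 1.5 < res.interaction.ci_high
        diff = res.slope_corrected.estimate - res.slope_raw.estimate
        assert diff == pytest.approx(1.5, abs=0.8)

    def test_zero_al_variance_rejected(self):
        rng = np.random.default_rng(7)
        table = _long_table(20, rng)
        table["axial_length_mm"] = 24.385
        with pytest.raises(ValueError, match="variance"):
            fit_al_interaction(table, "C")


class TestGroupContrast:
    def test_null_groups_estimate_near_zero(self):
        rng = np.random.default_rng(8)
        table = _long_table(120, rng)
        res = fit_group_contrast(table, "C")
        for est in res.values():
            assert abs(est.estimate) < 3.0
            assert est.p_value > 0.01

    def test_recovers_injected_myope_thinning(self):
        rng = np.random.default_rng(9)
        table = _long_table(150, rng, group_effect=-6.0)
        res = fit_group_contrast(table, "C")
        assert res["corrected"].ci_low < -6.0 < res["corrected"].ci_high
        assert res["raw"].ci_low < -6.0 < res["raw"].ci_high

    def test_single_group_rejected(self):
        rng = np.random.default_rng(10)
        table = _long_table(20, rng)
        table["is_myope"] = 0
        with pytest.raises(ValueError, match="group"):
            fit_group_contrast(table, "C")


class TestAdjustPvalues:
    def _est(self, p, sector="C"):
        return EffectEstimate(sector=sector, term="t", estimate=1.0,
                              ci_low=0.0, ci_high=2.0, p_value=p,
                              n_eyes=10, n_participants=5)

    def test_family_of_nine_multiplies_by_nine(self):
        ests = [self._est(0.004)] + [self._est(0.5) for _ in range(8)]
        out = adjust_pvalues(ests)
        assert out[0].p_adjusted == pytest.approx(0.036)

    def test_capped_at_one(self):
        out = adjust_pvalues([self._est(0.2) for _ in range(9)])
        assert all(e.p_adjusted == 1.0 for e in out)

    def test_family_of_one_unchanged(self):
        out = adjust_pvalues([self._est(0.03)])
        assert out[0].p_adjusted == pytest.approx(0.03)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_never_below_raw(self, pvals):
        out = adjust_pvalues([self._est(p) for p in pvals])
        assert all(e.p_adjusted >= e.p_value - 1e-15 for e in out)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([])


class TestEffectEstimate:
    def test_ci_must_contain_estimate(self):
        with pytest.raises(ValueError, match="confidence interval"):
            EffectEstimate(sector="C", term="t", estimate=5.0, ci_low=1.0,
                           ci_high=2.0, p_value=0.5, n_eyes=2,
                           n_participants=1)


def test_analyze_cohort_families_and_adjustment():
    rng = np.random.default_rng(11)
    table = _long_table(40, rng, sectors=("C", "N1", "T2"),
                        correction_fn=lambda al: 2.0 * (24.385 - al))
    results = analyze_cohort(table, sectors=("C", "N1", "T2"))
    assert set(results) == {"correction_effect", "al_interaction",
                            "group_contrast"}
    assert len(results["correction_effect"]) == 3
    assert len(results["group_contrast"]) == 6  # raw + corrected per sector
    for df in results.values():
        assert (df["p_adjusted"] >= df["p_value"] - 1e-15).all()
        assert ((df["ci_low"] <= df["estimate_um"])
                & (df["estimate_um"] <= df["ci_high"])).all()
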