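import math

import numpy as np
import pandas as pd
import pytest

from lesiondyn import (PatientCovariates, build_outcomes, cox_fit, dichotomize,
                       ets, km_estimate, logrank, median_cc,
                       CONTINUOUS_CC_TERMS, BINARY_CC_TERMS, INTERACTION_TERMS)
from lesiondyn.crosscorr import CCRecord
from _oracles import km_product_limit, logrank_two_group


def _cc(pid, v):
    return CCRecord(pid, "a", "b", v, v, 0, 4, {0: v}, kind="inter")


def _outcomes(rows):
    return pd.DataFrame(rows, columns=["patient_id", "arm", "kras", "ecog",
                                       "os_time", "os_event", "ts0",
                                       "ts_ratio8", "median_cc", "cc_group"])


def _row(pid, t, e, group, kras="wt", ecog="fully_active", ts0=50.0,
         ratio=0.2, mcc=0.5):
    return {"patient_id": pid, "arm": "cetuximab", "kras": kras, "ecog": ecog,
            "os_time": t, "os_event": e, "ts0": ts0, "ts_ratio8": ratio,
            "median_cc": mcc, "cc_group": group}


class TestMedianCC:
    def test_median_of_three_pairs(self):
        recs = [_cc("P1", 0.9), _cc("P1", 0.8), _cc("P1", -0.2)]
        assert median_cc(recs)["P1"] == pytest.approx(0.8)

    def test_single_pair(self):
        assert median_cc([_cc("P1", 0.4)])["P1"] == pytest.approx(0.4)

    def test_no_pairs_is_missing(self):
        assert "P1" not in median_cc([])
        assert "P1" not in median_cc([_cc("P1", float("nan"))])

    def test_even_count_midpoint(self):
        recs = [_cc("P1", 0.2), _cc("P1", 0.6)]
        assert median_cc(recs)["P1"] == pytest.approx(0.4)

    def test_undefined_ccs_excluded(self):
        recs = [_cc("P1", 0.9), _cc("P1", float("nan"))]
        assert median_cc(recs)["P1"] == pytest.approx(0.9)


class TestDichotomize:
    @pytest.mark.parametrize("value,expected", [
        (0.35, "low"),    # equal-to rule
        (0.36, "high"),
        (-1.0, "low"),
        (1.0, "high"),
        (None, None),
        (float("nan"), None),
    ])
    def test_threshold_rule(self, value, expected):
        assert dichotomize(value) == expected

    def test_sensitivity_threshold(self):
        assert dichotomize(0.45, threshold=0.5) == "low"
        assert dichotomize(0.55, threshold=0.5) == "high"


class TestETS:
    @pytest.mark.parametrize("ts0,ts8,expected", [
        (100.0, 70.0, 0.30), (50.0, 50.0, 0.0), (40.0, 0.0, 1.0),
        (40.0, 60.0, -0.5),
    ])
    def test_ratio(self, ts0, ts8, expected):
        assert ets(ts0, ts8) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="ts0"):
            ets(0.0, 10.0)

    def test_missing_ts8_propagates(self):
        assert ets(40.0, None) is None


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        rows = [_row(f"P{i}", float(i), 1, "high") for i in range(1, 11)]
        km = km_estimate(_outcomes(rows), "cc_group")["high"]
        assert km.median == 5.0
        steps, median = km_product_limit([(float(i), 1) for i in range(1, 11)])
        assert median == 5.0
        for t, s in steps:
            got = km.survival[km.times == t][0]
            assert got == pytest.approx(s, abs=1e-12)

    def test_six_subject_hand_table(self):
        rows = [_row("P1", 6, 1, "low"), _row("P2", 10, 1, "low"),
                _row("P3", 15, 0, "low"), _row("P4", 8, 1, "high"),
                _row("P5", 12, 0, "high"), _row("P6", 20, 1, "high")]
        km = km_estimate(_outcomes(rows), "cc_group")
        # hand product-limit: A: S(6)=2/3, S(10)=1/3 -> median 10
        a = km["low"]
        assert a.median == 10.0
        assert a.survival[a.times == 6.0][0] == pytest.approx(2 / 3)
        assert a.survival[a.times == 10.0][0] == pytest.approx(1 / 3)
        b = km["high"]
        assert b.median == 20.0
        assert b.survival[b.times == 8.0][0] == pytest.approx(2 / 3)
        assert b.survival[b.times == 20.0][0] == pytest.approx(0.0)

    def test_single_subject(self):
        rows = [_row("P1", 3.0, 1, "high"), _row("P2", 9.0, 1, "low")]
        km = km_estimate(_outcomes(rows), "cc_group")["high"]
        assert km.survival[km.times < 3.0] == pytest.approx(1.0)
        assert km.survival[km.times == 3.0][0] == pytest.approx(0.0)

    def test_all_censored_median_not_reached(self):
        rows = [_row("P1", 5.0, 0, "high"), _row("P2", 9.0, 0, "high"),
                _row("P3", 4.0, 1, "low"), _row("P4", 7.0, 1, "low")]
        km = km_estimate(_outcomes(rows), "cc_group")
        assert math.isinf(km["high"].median)
        assert (km["high"].survival == 1.0).all()

    def test_risk_table_counts(self):
        rows = [_row("P1", 6, 1, "low"), _row("P2", 10, 1, "low"),
                _row("P3", 15, 0, "low")]
        rows += [_row("P4", 8, 1, "high")]
        km = km_estimate(_outcomes(rows), "cc_group", risk_times=(0, 7, 12))
        rt = km["low"].risk_table
        assert list(rt["n_at_risk"]) == [3, 2, 1]


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        rows = [_row("P1", 5, 1, "low"), _row("P2", 9, 0, "low"),
                _row("P3", 5, 1, "high"), _row("P4", 9, 0, "high")]
        stat, dof, p = logrank(_outcomes(rows), "cc_group")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_oe_v_table(self):
        a = [(6.0, 1), (10.0, 1), (15.0, 0)]
        b = [(8.0, 1), (12.0, 0), (20.0, 1)]
        O, E, V, chi2 = logrank_two_group(a, b)
        assert (O, E, V) == (2.0, 1.4, pytest.approx(0.74))
        rows = [_row("P1", 6, 1, "low"), _row("P2", 10, 1, "low"),
                _row("P3", 15, 0, "low"), _row("P4", 8, 1, "high"),
                _row("P5", 12, 0, "high"), _row("P6", 20, 1, "high")]
        stat, dof, p = logrank(_outcomes(rows), "cc_group")
        assert stat == pytest.approx(chi2, abs=1e-12)
        assert chi2 == pytest.approx(0.36 / 0.74)

    def test_relabeling_invariance(self):
        rows = [_row("P1", 4, 1, "low"), _row("P2", 9, 1, "low"),
                _row("P3", 6, 1, "high"), _row("P4", 11, 0, "high")]
        out = _outcomes(rows)
        stat1, _, _ = logrank(out, "cc_group")
        flipped = out.assign(cc_group=out["cc_group"].map(
            {"low": "high", "high": "low"}))
        stat2, _, _ = logrank(flipped, "cc_group")
        assert stat1 == pytest.approx(stat2, abs=1e-12)

    def test_single_group_rejected(self):
        rows = [_row("P1", 4, 1, "low"), _row("P2", 9, 1, "low")]
        with pytest.raises(ValueError, match="2 non-empty groups"):
            logrank(_outcomes(rows), "cc_group")


class TestCox:
    def test_three_subject_closed_form(self):
        # partial likelihood e^b/(2e^b+1) * 1/(1+e^b) maximized at
        # e^(2b) = 1/2, i.e. b = -ln(2)/2
        rows = [_row("P1", 1.0, 1, "high", mcc=1.0),
                _row("P2", 2.0, 1, "high", mcc=0.0),
                _row("P3", 3.0, 1, "high", mcc=1.0)]
        fit = cox_fit(_outcomes(rows), terms=("median_cc",))
        assert fit.loc[0, "coef"] == pytest.approx(-0.5 * math.log(2), abs=1e-3)
        assert fit.loc[0, "hr"] == pytest.approx(math.exp(-0.5 * math.log(2)),
                                                 abs=1e-3)

    def test_standard_terms_fit_and_missing_cc_rows_dropped(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(120):
            mcc = float(rng.uniform(-1, 1)) if i % 3 else float("nan")
            rows.append(_row(
                f"P{i}", float(rng.exponential(50) + 1), int(rng.random() < 0.8),
                dichotomize_val(mcc),
                kras="mut" if rng.random() < 0.4 else "wt",
                ecog="not_fully_active" if rng.random() < 0.3 else "fully_active",
                ts0=float(rng.uniform(20, 120)),
                ratio=float(rng.uniform(-0.3, 0.8)), mcc=mcc))
        out = _outcomes(rows)
        fit = cox_fit(out, CONTINUOUS_CC_TERMS)
        assert set(fit["term"]) == set(CONTINUOUS_CC_TERMS)
        assert fit["n"].iloc[0] == out["median_cc"].notna().sum()
        assert np.isfinite(fit[["coef", "hr", "p"]].to_numpy()).all()
        fitb = cox_fit(out, BINARY_CC_TERMS)
        assert "cc_low" in set(fitb["term"])
        fiti = cox_fit(out, INTERACTION_TERMS)
        assert "kras_mut_x_median_cc" in set(fiti["term"])

    def test_wald_ci_brackets_hr(self):
        rng = np.random.default_rng(1)
        rows = [_row(f"P{i}", float(rng.exponential(40) + 1),
                     int(rng.random() < 0.8), "high",
                     mcc=float(rng.uniform(-1, 1))) for i in range(80)]
        fit = cox_fit(_outcomes(rows), terms=("median_cc",))
        assert fit.loc[0, "hr_ci_low"] <= fit.loc[0, "hr"] <= fit.loc[0, "hr_ci_high"]


def dichotomize_val(v):
    if isinstance(v, float) and math.isnan(v):
        return None
    return "low" if v <= 0.35 else "high"


class TestBuildOutcomes:
    def test_columns_and_consistency(self, small_trial):
        from lesiondyn import classify_all, merge_rare_classes
        from lesiondyn.heterogeneity import build_all_ctls, interclass_pairs
        series = small_trial["series"]
        classified, _ = merge_rare_classes(classify_all(series))
        inter = interclass_pairs(build_all_ctls(series, classified))
        out = build_outcomes(small_trial["covariates"], inter, series)
        assert len(out) == len(series)
        have = out["median_cc"].notna()
        assert (out.loc[have & (out.median_cc <= 0.35), "cc_group"] == "low").all()
        assert (out.loc[have & (out.median_cc > 0.35), "cc_group"] == "high").all()
        assert out.loc[~have, "cc_group"].isna().all()
        # ts_ratio8 <= 1 whenever defined (sizes are non-negative)
        ratios = out["ts_ratio8"].dropna()
        assert (ratios <= 1.0 + 1e-12).all()
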