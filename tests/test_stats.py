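"""Tests for MRC, ICC(2,1), banding, selection and companion statistics."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

import texrobust as tx
from texrobust.errors import DomainError

from oracles import icc_2way_anova_bruteforce


def table_from_arrays(r1: dict, r2: dict, mode="3D") -> tx.PairedFeatureTable:
    df1, df2 = pd.DataFrame(r1), pd.DataFrame(r2)
    ids = [f"l{i}" for i in range(len(df1))]
    return tx.PairedFeatureTable(lesion_ids=ids, reader1=df1, reader2=df2,
                                 roi_mode=mode)


class TestRelativeChange:
    @pytest.mark.parametrize("rf1,rf2,expected", [
        (5.0, 5.0, 0.0), (2.0, 1.0, 0.5), (1.0, 2.0, -1.0),
        (-2.0, -1.0, 0.5),      # signed denominator for negative features
    ])
    def test_values(self, rf1, rf2, expected):
        assert tx.relative_change(rf1, rf2) == expected

    def test_zero_reference_undefined(self):
        with pytest.raises(DomainError):
            tx.relative_change(0.0, 1.0)


class TestMeanRelativeChange:
    def test_identical_readers_zero(self):
        vals = {"A": [1.0, 2.0, 3.0], "B": [-1.0, 4.0, 0.5]}
        mrc = tx.mean_relative_change(table_from_arrays(vals, vals))
        assert (mrc["mrc_pct"] == 0.0).all()

    def test_absolute_aggregation(self):
        """Changes {+0.1, -0.1} average to 10%, not 0."""
        t = table_from_arrays({"A": [1.0, 1.0]}, {"A": [0.9, 1.1]})
        mrc = tx.mean_relative_change(t)
        assert mrc.loc["A", "mrc_pct"] == pytest.approx(10.0)

    def test_zero_denominators_excluded(self):
        t = table_from_arrays({"A": [0.0, 2.0, 2.0]}, {"A": [1.0, 1.0, 1.0]})
        mrc = tx.mean_relative_change(t)
        assert mrc.loc["A", "n_valid"] == 2
        assert mrc.loc["A", "n_excluded"] == 1
        assert mrc.loc["A", "mrc_pct"] == pytest.approx(50.0)


class TestIcc:
    def test_perfect_agreement(self):
        y = np.array([1.0, 2.0, 5.0, 9.0, 3.0, 7.0])
        icc, n = tx.icc_2_1_values(y, y)
        assert icc == pytest.approx(1.0)
        assert n == 6

    def test_noise_destroys_agreement(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.01, size=200)            # tiny lesion effect
        icc, _ = tx.icc_2_1_values(y, y + rng.normal(0, 10.0, size=200))
        assert abs(icc) < 0.2

    def test_matches_anova_oracle_and_pingouin(self):
        y1 = np.array([9.0, 10.0, 6.0, 12.0, 11.0, 4.0])
        y2 = np.array([8.0, 11.0, 7.0, 12.5, 10.0, 5.0])
        icc, _ = tx.icc_2_1_values(y1, y2)
        assert icc == pytest.approx(icc_2way_anova_bruteforce(y1, y2), abs=1e-10)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(6), 2),
            "raters": np.tile(["R1", "R2"], 6),
            "scores": np.column_stack([y1, y2]).ravel(),
        })
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        icc2 = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc == pytest.approx(icc2, abs=1e-10)

    def test_affine_invariance(self):
        """Rescaling and shifting both readers identically leaves ICC(2,1)
        unchanged (absolute agreement is affine-equivariant for a common
        transform)."""
        rng = np.random.default_rng(5)
        y1 = rng.normal(10, 3, 40)
        y2 = y1 + rng.normal(0, 1, 40)
        base, _ = tx.icc_2_1_values(y1, y2)
        scaled, _ = tx.icc_2_1_values(3.7 * y1 + 2.0, 3.7 * y2 + 2.0)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_consistency_form_ignores_rater_shift(self):
        rng = np.random.default_rng(6)
        y1 = rng.normal(0, 2, 100)
        y2 = y1 + 5.0                          # pure rater offset
        agree, _ = tx.icc_2_1_values(y1, y2, form="agreement")
        consist, _ = tx.icc_2_1_values(y1, y2, form="consistency")
        assert consist == pytest.approx(1.0)
        assert agree < consist

    def test_constant_rows_undefined(self):
        icc, _ = tx.icc_2_1_values(np.ones(5), np.ones(5))
        assert np.isnan(icc)


class TestClassifyAndSelect:
    @pytest.mark.parametrize("icc,band", [
        (0.50, "poor"), (0.51, "moderate"), (0.75, "moderate"),
        (0.76, "good"), (0.90, "good"), (0.91, "excellent"),
        (-0.2, "poor"), (float("nan"), "undefined"),
    ])
    def test_bands(self, icc, band):
        assert tx.classify_icc(icc) == band

    def test_strict_selection_rule(self):
        rob = pd.DataFrame({
            "icc": [0.95, 0.90, 0.99, 0.95],
            "mrc_pct": [5.0, 5.0, 10.0, 9.99],
        }, index=["ok", "icc_at_boundary", "mrc_at_boundary", "ok2"])
        rob["robust"] = (rob["icc"] > 0.90) & (rob["mrc_pct"] < 10.0)
        assert tx.select_robust(rob) == ["ok", "ok2"]

    def test_robustness_table_identical_readers(self):
        rng = np.random.default_rng(2)
        vals = {f: rng.normal(10, 3, 8) for f in ("A", "B")}
        rt = tx.robustness_table(table_from_arrays(vals, vals))
        assert rt["robust"].all()
        assert (rt["band"] == "excellent").all()
        assert (rt["mrc_pct"] == 0.0).all()


class TestCompanionStatistics:
    def test_wilcoxon_all_zero_undefined(self):
        out = tx.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert np.isnan(out["p_value"]) and out["n"] == 0

    def test_wilcoxon_mirrored_pairs_large_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, -1.0, -2.0, -3.0, -4.0])
        out = tx.wilcoxon_signed_rank(x, np.zeros(8))
        assert out["p_value"] > 0.5

    def test_wilcoxon_exact_concordant(self):
        x = np.arange(1.0, 9.0)
        out = tx.wilcoxon_signed_rank(x, np.zeros(8))
        assert out["p_value"] == pytest.approx(2.0 / 2**8)

    def test_spearman_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 9.0])
        assert tx.spearman_rho(x, x**3)["rho"] == pytest.approx(1.0)
        assert tx.spearman_rho(x, -x)["rho"] == pytest.approx(-1.0)

    def test_spearman_ties_match_manual_ranking(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        # manual average ranks: x -> [1, 2.5, 2.5, 4, 5, 6]
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])
        ry = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert tx.spearman_rho(x, y)["rho"] == pytest.approx(expected, abs=1e-12)

    def test_spearman_constant_undefined(self):
        out = tx.spearman_rho(np.ones(5), np.arange(5.0))
        assert np.isnan(out["rho"])

    def test_evans_labels(self):
        assert tx.evans_strength(0.1) == "very weak"
        assert tx.evans_strength(-0.45) == "moderate"
        assert tx.evans_strength(0.85) == "very strong"


class TestSizeAgreement:
    def test_size_independent_jitter_gives_weak_rho(self):
        rng = np.random.default_rng(7)
        size = rng.uniform(10, 80, 70)
        dc = rng.uniform(0.7, 0.9, 70)          # independent of size
        hd = rng.uniform(0.5, 2.0, 70)
        rep = tx.size_agreement_analysis({"diameter": size}, dc, hd)
        assert (rep["rho"].abs() < 0.3).all()

    def test_size_dependent_agreement_detected(self):
        rng = np.random.default_rng(8)
        size = rng.uniform(10, 80, 70)
        dc = 0.6 + 0.004 * size + rng.normal(0, 0.02, 70)
        hd = rng.uniform(0.5, 2.0, 70)
        rep = tx.size_agreement_analysis({"diameter": size}, dc, hd)
        row = rep[(rep["similarity_index"] == "DC")].iloc[0]
        assert row["rho"] > 0.5 and row["p_value"] < 0.001
        assert row["ols_slope"] == pytest.approx(0.004, rel=0.3)

    def test_constant_size_flagged(self):
        rep = tx.size_agreement_analysis({"d": np.ones(10)},
                                         np.linspace(0, 1, 10),
                                         np.linspace(1, 0, 10))
        assert rep["rho"].isna().all()
        assert (rep["strength"] == "undefined").all()


class TestCircularComparison:
    def _vectors(self, values: dict[str, list[float]]):
        feats = {f: 1.0 for f in tx.TEXTURE_FEATURES}
        feats.update({f: 1.0 for f in tx.MORPHOLOGY_FEATURES})
        out = []
        n = len(next(iter(values.values())))
        for i in range(n):
            f = dict(feats)
            for name, vals in values.items():
                f[name] = vals[i]
            out.append(tx.FeatureVector(features=f, lesion_id=f"l{i}"))
        return out

    def test_identical_circles_zero_mrc(self):
        r1 = self._vectors({"Contrast": [2.0, 3.0]})
        rep = tx.circular_roi_comparison(r1, r1, r1, r1)
        assert (rep["mrc_enclosing_pct"] == 0.0).all()
        assert (rep["mrc_inscribed_pct"] == 0.0).all()

    def test_preponderance_flag(self):
        r1 = self._vectors({"Contrast": [2.0, 2.0]})
        r2 = self._vectors({"Contrast": [3.0, 1.0]})      # 50% inter-reader MRC
        enc = self._vectors({"Contrast": [2.2, 2.2]})     # 10%
        ins = self._vectors({"Contrast": [1.9, 1.9]})     # 5%
        rep = tx.circular_roi_comparison(r1, enc, ins, r2)
        assert bool(rep.loc["Contrast", "inter_reader_preponderant"])
        # other features: inter-reader MRC 0 vs circle MRC 0 -> still >= both
        assert bool(rep.loc["Energy", "inter_reader_preponderant"])

    def test_divergent_circle_behaviour_signs(self):
        """Enclosing vs inscribed circles shift a monotone feature in
        opposite directions relative to the manual ROI."""
        r1 = self._vectors({"SumAverage": [10.0, 12.0]})
        enc = self._vectors({"SumAverage": [12.0, 14.0]})   # shifted up
        ins = self._vectors({"SumAverage": [8.0, 10.0]})    # shifted down
        r2 = self._vectors({"SumAverage": [10.0, 12.0]})
        rep = tx.circular_roi_comparison(r1, enc, ins, r2)
        assert (rep.loc["SumAverage", "mean_rc_enclosing_pct"]
                * rep.loc["SumAverage", "mean_rc_inscribed_pct"]) < 0
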