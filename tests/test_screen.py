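"""Differential screening: fold change, Welch test, PLS-VIP, calling rules."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fluoromics as fm
from fluoromics.containers import OmicsFeatureTable
from fluoromics.errors import ValidationError


def _table(values: np.ndarray, layer="protein", groups=("A", "A", "A", "B", "B", "B")):
    samples = [f"s{i}" for i in range(len(groups))]
    return OmicsFeatureTable(
        layer=layer,
        values=pd.DataFrame(values, columns=samples,
                            index=[f"f{i}" for i in range(values.shape[0])]),
        design=pd.Series(dict(zip(samples, groups))),
    )


class TestFoldChange:
    def test_equal_means_give_unit_fc(self):
        t = _table(np.array([[2.0, 2, 2, 2, 2, 2]]))
        rec = fm.fold_change(t, "AvsB")
        assert rec.loc["f0", "fc"] == 1.0
        assert rec.loc["f0", "log2fc"] == 0.0

    def test_fourfold_mean_gives_log2fc_two(self):
        t = _table(np.array([[1.0, 1, 1, 4, 4, 4]]))
        assert fm.fold_change(t, "AvsB").loc["f0", "log2fc"] == pytest.approx(2.0)

    def test_zero_control_mean_needs_offset(self):
        t = _table(np.array([[0.0, 0, 0, 4, 4, 4]]))
        with pytest.raises(ValidationError, match="zero"):
            fm.fold_change(t, "AvsB")
        rec = fm.fold_change(t, "AvsB", zero_offset=0.5)
        assert rec.attrs["zero_offset"] == 0.5
        assert np.isfinite(rec.loc["f0", "fc"])

    def test_bad_comparison_string(self):
        t = _table(np.ones((1, 6)))
        with pytest.raises(ValidationError):
            fm.fold_change(t, "A-B")


class TestWelchTest:
    def test_identical_groups_give_p_one(self):
        t = _table(np.array([[3.0, 3, 3, 3, 3, 3]]))
        with pytest.warns(UserWarning, match="constant"):
            p = fm.welch_test(t, "AvsB")
        assert p["f0"] == 1.0

    def test_matches_textbook_welch_formula(self):
        # independent oracle: Welch statistic and Satterthwaite df by hand
        a = np.array([5.1, 4.8, 5.6])
        b = np.array([7.9, 8.4, 7.1])
        t = _table(np.array([np.r_[a, b]]))
        p_impl = fm.welch_test(t, "AvsB")["f0"]
        la, lb = np.log2(a), np.log2(b)
        va, vb = la.var(ddof=1) / 3, lb.var(ddof=1) / 3
        t_stat = (lb.mean() - la.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_hand = 2 * stats.t.sf(abs(t_stat), df)
        assert p_impl == pytest.approx(p_hand, rel=1e-12)

    def test_null_type_one_error_calibrated(self):
        # five replicates per group keep the Welch-Satterthwaite
        # approximation accurate enough for a tight calibration check
        rng = np.random.default_rng(0)
        values = np.exp2(rng.normal(8.0, 1.0, size=(2000, 10)))
        groups = ("A",) * 5 + ("B",) * 5
        p = fm.welch_test(_table(values, groups=groups), "AvsB")
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.02)


class TestPLSVIP:
    def test_vip_normalisation_identity(self, small_omics):
        _, tabs = small_omics
        vip = fm.pls_vip(tabs["metabolite"], "AvsB")
        assert np.nansum(vip**2) == pytest.approx(vip.notna().sum(), rel=1e-9)

    def test_separating_feature_has_max_vip_above_one(self):
        rng = np.random.default_rng(1)
        values = np.exp2(rng.normal(8, 0.2, size=(5, 6)))
        values[0] = [10, 11, 10.5, 300, 310, 290]  # clean group separation
        vip = fm.pls_vip(_table(values, layer="metabolite"), "AvsB")
        assert vip.idxmax() == "f0"
        assert vip["f0"] > 1.0

    def test_label_permutation_breaks_the_ranking(self):
        rng = np.random.default_rng(2)
        values = np.exp2(rng.normal(8, 0.5, size=(5, 6)))
        values[0] = [10, 11, 10.5, 300, 310, 290]
        top_hits = 0
        perms = 100
        for _ in range(perms):
            groups = rng.permutation(["A", "A", "A", "B", "B", "B"])
            vip = fm.pls_vip(_table(values, layer="metabolite", groups=groups), "AvsB")
            top_hits += vip.idxmax() == "f0"
        assert top_hits / perms < 0.75  # no longer systematically first

    def test_constant_features_dropped_with_warning(self):
        values = np.vstack([np.full(6, 7.0), np.random.default_rng(0).normal(8, 1, (3, 6))])
        with pytest.warns(UserWarning, match="constant"):
            vip = fm.pls_vip(_table(values, layer="metabolite"), "AvsB")
        assert np.isnan(vip["f0"])


class TestScreeningRules:
    def test_protein_boundary_just_below_fold_threshold_is_ns(self):
        rec = pd.DataFrame({"fc": [1.19], "pvalue": [0.001]}, index=["p1"])
        out = fm.screen_differential(rec, "protein")
        assert out.loc["p1", "call"] == "ns"

    @pytest.mark.parametrize(
        "layer,row,expected",
        [
            ("protein", {"fc": 1.25, "pvalue": 0.01}, "up"),
            ("protein", {"fc": 0.80, "pvalue": 0.01}, "down"),
            ("protein", {"fc": 1.25, "pvalue": 0.10}, "ns"),
            ("metabolite", {"fc": 1.6, "vip": 1.2}, "up"),
            ("metabolite", {"fc": 0.6, "vip": 1.2}, "down"),
            ("metabolite", {"fc": 1.6, "vip": 0.9}, "ns"),
            ("transcript", {"fc": 1.01, "qvalue": 0.01}, "up"),
            ("transcript", {"fc": 0.99, "qvalue": 0.01}, "down"),
            ("transcript", {"fc": 2.0, "qvalue": 0.06}, "ns"),
        ],
    )
    def test_layer_rules(self, layer, row, expected):
        rec = pd.DataFrame([row], index=["x"])
        assert fm.screen_differential(rec, layer).loc["x", "call"] == expected

    def test_missing_vip_for_metabolites_is_an_error(self):
        rec = pd.DataFrame({"fc": [2.0]}, index=["m"])
        with pytest.raises(ValidationError, match="vip"):
            fm.screen_differential(rec, "metabolite")

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        fc_up=st.floats(min_value=1.2, max_value=3.0),
        p_th=st.floats(min_value=0.001, max_value=0.05),
    )
    def test_raising_thresholds_never_adds_calls(self, fc_up, p_th):
        rng = np.random.default_rng(7)
        rec = pd.DataFrame(
            {"fc": np.exp2(rng.normal(0, 1, 200)), "pvalue": rng.uniform(0, 1, 200)}
        )
        base = fm.screen_differential(rec, "protein")
        stricter = fm.screen_differential(
            rec, "protein",
            fm.ScreenThresholds(protein_p=p_th, protein_fc_up=max(fc_up, 1.2)),
        )
        base_called = set(base.index[base["call"] != "ns"])
        strict_called = set(stricter.index[stricter["call"] != "ns"])
        assert strict_called <= base_called

    def test_bh_qvalues_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = pd.Series(rng.uniform(0, 1, 500))
        q = fm.bh_qvalues(p)
        assert (q <= 1).all()
        order = np.argsort(p.values)
        assert np.all(np.diff(q.values[order]) >= -1e-12)


class TestZScore:
    def test_rows_standardised(self, small_omics):
        _, tabs = small_omics
        z = fm.zscore_matrix(tabs["transcript"])
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_matches_brute_force_row_standardisation(self, small_omics):
        _, tabs = small_omics
        v = tabs["metabolite"].values
        z = fm.zscore_matrix(v)
        for fid in v.index[:5]:
            row = v.loc[fid].to_numpy()
            expected = (row - row.mean()) / row.std(ddof=1)
            np.testing.assert_allclose(z.loc[fid].to_numpy(), expected, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            fm.zscore_matrix(pd.DataFrame({"s1": [1.0, 2.0]}))
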