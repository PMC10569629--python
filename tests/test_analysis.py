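"""Support contributions and the study's statistical comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from tfsupport.analysis import (
    net_and_external_compartment_curves,
    paired_model_test,
    pointwise_paired_ttest,
    regeneration_group_contrast,
    support_contributions,
)
from tfsupport.errors import InputError
from tfsupport.geometry import CompartmentGeometry


def curves(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()},
                        index=np.linspace(0, 100, n))


class TestContributions:
    def test_proportional_split(self):
        res = support_contributions({"lateral": curves(a=[3.0] * 101, b=[1.0] * 101)})
        assert np.allclose(res.contributions["lateral"]["a"], 75.0)
        assert np.allclose(res.contributions["lateral"]["b"], 25.0)
        assert res.stance_average["lateral"]["a"] == pytest.approx(75.0)

    def test_opposing_muscle_negative_percentage(self):
        res = support_contributions({"lateral": curves(a=[2.0] * 101, b=[-1.0] * 101)})
        assert np.allclose(res.contributions["lateral"]["a"], 100.0)
        assert np.allclose(res.contributions["lateral"]["b"], -50.0)

    def test_single_muscle_is_100_percent(self):
        res = support_contributions({"medial": curves(a=[-1.5] * 101)})
        assert np.allclose(res.contributions["medial"]["a"], 100.0)
        assert res.support_sign["medial"] == -1.0

    def test_supporting_contributions_sum_to_100(self):
        rng = np.random.default_rng(0)
        df = curves(**{f"m{i}": rng.normal(0, 2, 101) for i in range(6)})
        res = support_contributions({"lateral": df})
        c = res.contributions["lateral"].to_numpy()
        s = res.support_sign["lateral"]
        supp_sum = np.where(c > 0, c, 0.0).sum(axis=1)
        ok = ~res.masked["lateral"]
        assert np.allclose(supp_sum[ok], 100.0)

    def test_zero_denominator_masked(self):
        df = curves(a=[1.0] * 50 + [0.0] * 51, b=[0.5] * 50 + [0.0] * 51)
        res = support_contributions({"lateral": df})
        assert res.masked["lateral"].sum() == 51
        assert np.isnan(res.contributions["lateral"]["a"].iloc[-1])

    def test_peak_is_signed_extremum_of_largest_magnitude(self):
        x = np.zeros(101)
        x[30], x[70] = 4.0, -6.0
        res = support_contributions({"lateral": curves(a=x, b=np.ones(101))})
        assert res.peak["lateral"]["a"] == -6.0


class TestNetAndExternal:
    def test_net_equals_sum_of_muscles(self):
        rng = np.random.default_rng(1)
        per = {c: curves(**{f"m{i}": rng.normal(size=101) for i in range(4)})
               for c in ("medial", "lateral")}
        out = net_and_external_compartment_curves(
            per, np.zeros(101), np.zeros(101), CompartmentGeometry())
        assert np.allclose(out["net_muscle_medial"], per["medial"].sum(axis=1))
        assert np.allclose(out["net_muscle_lateral"], per["lateral"].sum(axis=1))

    def test_external_axial_force_toggle(self):
        per = {c: curves(m=np.ones(101)) for c in ("medial", "lateral")}
        ext_m = np.full(101, 2.0)
        fax = np.full(101, 1000.0)
        cg = CompartmentGeometry(d_med=0.02, d_lat=0.03)
        with_ax = net_and_external_compartment_curves(per, ext_m, fax, cg)
        without = net_and_external_compartment_curves(per, ext_m, fax, cg,
                                                      include_external_axial=False)
        assert np.allclose(with_ax["external_medial"], 2.0 - 1000.0 * 0.02)
        assert np.allclose(with_ax["external_lateral"], 2.0 + 1000.0 * 0.03)
        assert np.allclose(without["external_medial"], 2.0)


class TestPairedTest:
    def test_closed_form_example(self):
        # differences [1, 2, 3]: t = 2 / (1/sqrt(3)), df = 2, p ~ 0.0742
        out = paired_model_test(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert out["t"] == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-9)
        assert out["df"] == 2
        assert out["p"] == pytest.approx(0.0742, abs=2e-4)

    def test_sign_flip_symmetry(self):
        x, y = np.array([3.0, 5.0, 4.0, 6.0]), np.array([2.0, 5.5, 3.0, 4.0])
        a, b = paired_model_test(x, y), paired_model_test(y, x)
        assert a["t"] == pytest.approx(-b["t"])
        assert a["p"] == pytest.approx(b["p"])

    def test_identical_vectors_degenerate(self):
        out = paired_model_test(np.ones(5), np.ones(5))
        assert out["degenerate"] and np.isnan(out["p"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InputError):
            paired_model_test(np.ones(2), np.zeros(2))


class TestPointwiseTest:
    def test_identical_curves_all_masked(self):
        X = np.tile(np.sin(np.linspace(0, 3, 101)), (6, 1))
        out = pointwise_paired_ttest(X, X.copy())
        assert out["degenerate"].all()
        assert np.all(np.isnan(out["p"]))

    def test_single_point_matches_paired_test(self):
        rng = np.random.default_rng(3)
        X, Y = rng.normal(size=(18, 101)), rng.normal(size=(18, 101))
        out = pointwise_paired_ttest(X, Y)
        ref = paired_model_test(X[:, 40], Y[:, 40])
        assert out["t"][40] == pytest.approx(ref["t"])
        assert out["p"][40] == pytest.approx(ref["p"])

    def test_bonferroni_scales_p(self):
        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(10, 101)), rng.normal(size=(10, 101))
        raw = pointwise_paired_ttest(X, Y)["p"]
        corr = pointwise_paired_ttest(X, Y, bonferroni=True)["p"]
        assert np.allclose(corr, np.minimum(raw * 101, 1.0), equal_nan=True)

    def test_type_one_error_rate_under_null(self):
        # n = 18 subjects, 1000 replicates: rejection rate near alpha = 0.05
        rng = np.random.default_rng(12345)
        X = rng.normal(size=(1000, 18, 101))
        Y = rng.normal(size=(1000, 18, 101))
        rates = []
        for k in range(1000):
            p = pointwise_paired_ttest(X[k], Y[k])["p"]
            rates.append(np.mean(p < 0.05))
        assert 0.035 < np.mean(rates) < 0.065


class TestRegenerationContrast:
    def test_identical_groups_null(self):
        v = np.array([1.0, 1.0, 1.0, 1.0])
        g = np.array(["none", "none", "both", "both"])
        out = regeneration_group_contrast(v, g)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(0, 1e-6, 3), 1.0 + rng.normal(0, 1e-6, 3)])
        g = np.array(["none"] * 3 + ["both"] * 3)
        out = regeneration_group_contrast(v, g)
        assert out["p"] < 1e-6

    def test_label_swap_negates_t(self):
        v = np.array([0.1, 0.4, 0.2, 0.9, 1.1, 0.8])
        g = np.array(["none"] * 3 + ["both"] * 3)
        g2 = np.array(["both"] * 3 + ["none"] * 3)
        a, b = regeneration_group_contrast(v, g), regeneration_group_contrast(v, g2)
        assert a["t"] == pytest.approx(-b["t"])
        assert a["p"] == pytest.approx(b["p"])

    def test_one_tendon_group_excluded_but_described(self):
        v = np.arange(8.0)
        g = np.array(["none", "none", "one", "one", "one", "both", "both", "both"])
        out = regeneration_group_contrast(v, g)
        assert out["df"] == 3  # 2 + 3 - 2
        assert out["descriptives"]["one"]["n"] == 3
        # matches scipy's pooled-variance two-sample t on the contrasted groups
        t_ref, p_ref = sstats.ttest_ind(v[:2], v[5:], equal_var=True)
        assert out["t"] == pytest.approx(t_ref)

    def test_too_small_group_rejected(self):
        v = np.arange(4.0)
        g = np.array(["none", "both", "both", "both"])
        with pytest.raises(InputError):
            regeneration_group_contrast(v, g)
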