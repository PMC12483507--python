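"""Regression and phylogenetic-signal machinery: OLS/PGLS fits, Blomberg's K,
allometry classification, covariate adjustment."""

import numpy as np
import pandas as pd
import pytest

from hoverscale.errors import (
    CollinearityWarning,
    DegenerateTraitError,
    InvalidParameterError,
    TreeDegeneracyError,
)
from hoverscale.phylostats import (
    ScalingFit,
    ScalingRegression,
    allometry_classify,
    blomberg_k,
    covariate_adjustment,
    ols_loglog,
    pgls_loglog,
)
from hoverscale.trees import star_tree, tree_from_newick, vcv_matrix


class TestOlsLoglog:
    def test_exact_power_law(self):
        x = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
        fit = ols_loglog(x, x**2)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.ci_low <= 2.0 <= fit.ci_high

    def test_constant_response(self):
        x = np.array([1.0, 2.0, 5.0, 10.0])
        fit = ols_loglog(x, np.full(4, 3.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_nonpositive_data_rejected(self):
        with pytest.raises(InvalidParameterError):
            ols_loglog([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegenerateTraitError):
            ols_loglog([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])

    def test_ci_coverage_near_nominal(self):
        # slope 1, n = 8, log-residual SD 0.05: coverage 95% +/- 2%
        cover = 0
        n_rep = 5000
        for i in range(n_rep):
            r = np.random.default_rng(i)
            x = 10 ** r.uniform(0.5, 2.0, 8)
            y = 10 ** (0.3 + np.log10(x) + r.normal(0.0, 0.05, 8))
            fit = ols_loglog(x, y)
            cover += fit.ci_low <= 1.0 <= fit.ci_high
        assert abs(cover / n_rep - 0.95) < 0.02

    def test_unit_rescaling_leaves_slope(self):
        x = np.array([1.0, 3.0, 7.0, 20.0])
        y = x**1.5 * 2.0
        f1 = ols_loglog(x, y)
        f2 = ols_loglog(x * 1000.0, y / 3600.0)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-12)

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (8, 32, 128):
            r = np.random.default_rng(42)
            x = 10 ** r.uniform(0.5, 2.0, n)
            y = 10 ** (np.log10(x) + r.normal(0.0, 0.1, n))
            fit = ols_loglog(x, y)
            widths.append(fit.ci_high - fit.ci_low)
        assert widths[0] > widths[1] > widths[2]


class TestPglsLoglog:
    def test_star_tree_reduces_to_ols(self, rng):
        labels = [f"t{i}" for i in range(10)]
        tree = star_tree(labels)
        x = pd.Series(10 ** rng.uniform(0.5, 2.0, 10), index=labels)
        y = pd.Series(
            10 ** (0.5 + 1.2 * np.log10(x.to_numpy()) + rng.normal(0, 0.1, 10)),
            index=labels)
        fp = pgls_loglog(tree, x, y)
        fo = ols_loglog(x.to_numpy(), y.to_numpy())
        assert fp.slope == pytest.approx(fo.slope, abs=1e-10)
        assert fp.intercept == pytest.approx(fo.intercept, abs=1e-10)
        assert fp.ci_low == pytest.approx(fo.ci_low, abs=1e-10)

    def test_duplicated_tip_at_zero_distance_is_singular(self):
        tree = tree_from_newick("((a:0.0,b:0.0):1.0,c:1.0);")
        x = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        y = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(TreeDegeneracyError):
            pgls_loglog(tree, x, y)

    def test_bm_regression_slope_recovery(self, yule_tree, chol16):
        # traits simulated under the BM regression model with slope 4/3
        labels, L = chol16
        n = len(labels)
        slopes = []
        for i in range(1000):
            r = np.random.default_rng(i)
            lx = 1.0 + 0.5 * (L @ r.standard_normal(n))
            ly = 0.2 + (4.0 / 3.0) * lx + 0.1 * (L @ r.standard_normal(n))
            x = pd.Series(10**lx, index=labels)
            y = pd.Series(10**ly, index=labels)
            slopes.append(pgls_loglog(yule_tree, x, y).slope)
        assert np.mean(slopes) == pytest.approx(4.0 / 3.0, abs=0.02)

    def test_species_mismatch_rejected(self, yule_tree):
        x = pd.Series([1.0, 2.0, 3.0], index=["x1", "x2", "x3"])
        with pytest.raises(Exception) as err:
            pgls_loglog(yule_tree, x, x)
        assert "species" in str(err.value)

    def test_sklearn_params_roundtrip(self):
        est = ScalingRegression(method="pgls", conf_level=0.9)
        params = est.get_params()
        assert params["method"] == "pgls"
        est2 = ScalingRegression().set_params(**params)
        assert est2.conf_level == 0.9


class TestBlombergK:
    def test_mean_K_near_one_under_bm(self, yule_tree, chol16):
        labels, L = chol16
        Ks = []
        for i in range(1000):
            r = np.random.default_rng(i)
            x = pd.Series(L @ r.standard_normal(len(labels)), index=labels)
            Ks.append(blomberg_k(yule_tree, x, n_perm=1, seed=i).K)
        se = np.std(Ks) / np.sqrt(len(Ks))
        assert abs(np.mean(Ks) - 1.0) < max(4 * se, 0.05)

    def test_permutation_p_uniform_under_exchangeable_null(self, yule_tree):
        # calibration handled at scale in the acceptance suite; spot-check
        labels = [leaf.taxon.label for leaf in yule_tree.leaf_node_iter()]
        rng = np.random.default_rng(3)
        ps = [
            blomberg_k(yule_tree,
                       pd.Series(rng.standard_normal(len(labels)), index=labels),
                       n_perm=199, seed=i).p
            for i in range(200)
        ]
        assert abs(np.mean(ps) - 0.5) < 0.08

    def test_constant_trait_rejected(self, yule_tree):
        labels = [leaf.taxon.label for leaf in yule_tree.leaf_node_iter()]
        with pytest.raises(DegenerateTraitError):
            blomberg_k(yule_tree, pd.Series(1.0, index=labels))

    def test_strong_signal_exceeds_shuffled(self, yule_tree, chol16):
        labels, L = chol16
        r = np.random.default_rng(1)
        bm = pd.Series(L @ r.standard_normal(len(labels)), index=labels)
        shuffled = pd.Series(r.permutation(bm.to_numpy()), index=labels)
        K_bm = blomberg_k(yule_tree, bm, n_perm=1, seed=0).K
        K_sh = blomberg_k(yule_tree, shuffled, n_perm=1, seed=0).K
        assert K_bm > K_sh


class TestAllometryClassify:
    def _fit(self, slope, lo, hi):
        return ScalingFit("m", 28, slope, 0.0, lo, hi, 0.9, 0.001, "PGLS-BM")

    def test_reported_s2_row_is_negative_allometry(self):
        assert allometry_classify(self._fit(1.008, 0.767, 1.250), 4 / 3) == "negative"

    def test_reported_chord_row_is_isometry(self):
        assert allometry_classify(self._fit(0.294, 0.229, 0.359), 1 / 3) == "isometry"

    def test_boundary_touching_ci_counts_as_isometry(self):
        assert allometry_classify(self._fit(0.5, 1 / 3, 0.6), 1 / 3) == "isometry"

    def test_positive_allometry(self):
        assert allometry_classify(self._fit(0.5, 0.4, 0.6), 1 / 3) == "positive"


class TestCovariateAdjustment:
    def test_orthogonal_covariates_leave_mass_coefficient(self, rng):
        n = 64
        # orthogonal design: covariates uncorrelated with log-mass by construction
        lm = np.tile([-1.0, 1.0], n // 2)
        speed = np.tile([-1.0, -1.0, 1.0, 1.0], n // 4)
        climb = rng.standard_normal(n)
        climb -= (climb @ lm) / (lm @ lm) * lm
        climb -= (climb @ speed) / (speed @ speed) * speed
        y = pd.Series(2.0 + 0.7 * lm + rng.normal(0, 0.1, n), name="omega")
        covs = pd.DataFrame({"speed": speed, "climb": climb})
        mass = pd.Series(10**lm)
        fit = covariate_adjustment(y, covs, mass)
        simple = np.polyfit(lm, y.to_numpy(), 1)[0]
        assert fit.mass_coef == pytest.approx(simple, abs=1e-10)

    def test_speed_effect_recovered_mass_null(self, rng):
        n = 60
        speed = rng.standard_normal(n)
        mass = pd.Series(10 ** rng.uniform(0.5, 2.0, n))
        y = pd.Series(2.0 * speed + rng.normal(0, 0.2, n), name="resp")
        fit = covariate_adjustment(y, pd.DataFrame({"speed": speed}), mass)
        assert fit.covariate_coefs["speed"] == pytest.approx(2.0, abs=0.1)
        assert fit.mass_p > 0.001  # mass truly unrelated here

    def test_duplicated_covariate_warns(self, rng):
        n = 30
        speed = rng.standard_normal(n)
        covs = pd.DataFrame({"speed": speed, "speed2": speed})
        y = pd.Series(speed + rng.normal(0, 0.1, n))
        mass = pd.Series(10 ** rng.uniform(0.5, 2.0, n))
        with pytest.warns(CollinearityWarning):
            covariate_adjustment(y, covs, mass)
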