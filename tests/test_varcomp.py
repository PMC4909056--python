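"""REML variance partitioning, boundary-corrected LRT, CV/VC decompositions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import dense_gaussian_loglik

from beechtrial.simulate import TraitEffectSpec, TrialDesign, simulate_trial
from beechtrial.varcomp import (
    cv_components,
    fit_climate_model,
    fit_random_model,
    lrt_provenance,
    reml_loglik,
    variance_component_percents,
    variance_partition_summary,
)
from beechtrial.varcomp import fit_block_only_model


def small_instance(seed=42, n_per_cell=2, p=2, b=2):
    rng = np.random.default_rng(seed)
    n = p * b * n_per_cell
    prov = np.repeat([f"p{i}" for i in range(p)], b * n_per_cell)
    block = np.tile(np.repeat([f"b{j}" for j in range(b)], n_per_cell), p)
    y = rng.normal(5, 1, n)
    return y, prov, block


class TestLoglik:
    @pytest.mark.parametrize(
        "variances", [(0.5, 0.3, 1.2), (0.0, 0.0, 2.0), (1.5, 0.0, 0.7)]
    )
    @pytest.mark.parametrize("method", ["REML", "ML"])
    def test_matches_dense_matrix_oracle(self, variances, method):
        y, prov, block = small_instance()
        ours = reml_loglik(variances, y, prov, block, method=method)
        oracle = dense_gaussian_loglik(variances, y, prov, block, method=method)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_iid_face_matches_closed_form(self):
        y, prov, block = small_instance(n_per_cell=5)
        n = len(y)
        s2 = np.var(y, ddof=1)
        closed = -0.5 * (
            (n - 1) * np.log(2 * np.pi) + n * np.log(s2) + np.log(n / s2) + (n - 1)
        )
        assert reml_loglik((0, 0, s2), y, prov, block) == pytest.approx(closed)

    def test_translation_invariance_of_reml(self):
        y, prov, block = small_instance()
        a = reml_loglik((0.5, 0.2, 1.0), y, prov, block)
        b = reml_loglik((0.5, 0.2, 1.0), y + 17.3, prov, block)
        assert a == pytest.approx(b, abs=1e-9)

    def test_all_zero_variances_rejected(self):
        y, prov, block = small_instance()
        with pytest.raises(ValueError):
            reml_loglik((0.0, 0.0, 0.0), y, prov, block)


class TestRandomModelFit:
    def test_matches_method_of_moments_on_balanced_interior(self, balanced_trial):
        df = balanced_trial
        y = df["y"].to_numpy()
        fit = fit_random_model(y, df["provenance"], df["block"])
        p, b, n = 10, 3, 10
        gm = y.mean()
        pm = df.groupby("provenance")["y"].mean()
        bm = df.groupby("block")["y"].mean()
        ssp = b * n * ((pm - gm) ** 2).sum()
        ssb = p * n * ((bm - gm) ** 2).sum()
        sse = ((y - gm) ** 2).sum() - ssp - ssb
        msp, msb, mse = ssp / (p - 1), ssb / (b - 1), sse / (p * b * n - p - b + 1)
        assert fit.sigma2_inter == pytest.approx((msp - mse) / (b * n), rel=1e-4)
        assert fit.sigma2_block == pytest.approx((msb - mse) / (p * n), rel=1e-4)
        assert fit.sigma2_intra == pytest.approx(mse, rel=1e-4)

    def test_fit_maximizes_dense_oracle_likelihood(self):
        """On a tiny instance the fitted loglik dominates a lattice of
        alternatives evaluated with the brute-force dense likelihood."""
        y, prov, block = small_instance(seed=1, n_per_cell=3)
        fit = fit_random_model(y, prov, block)
        ll_hat = dense_gaussian_loglik(
            (fit.sigma2_inter, fit.sigma2_block, fit.sigma2_intra), y, prov, block
        )
        assert fit.loglik == pytest.approx(ll_hat, abs=1e-8)
        for s2p in [0.0, 0.3, 1.0]:
            for s2b in [0.0, 0.3]:
                for s2e in [0.5, 1.0, 2.0]:
                    assert ll_hat >= dense_gaussian_loglik(
                        (s2p, s2b, s2e), y, prov, block
                    ) - 1e-7

    def test_boundary_recovery_when_provenance_variance_zero(self):
        df = simulate_trial(
            TrialDesign(10, 3, 50, seed=5), {"y": TraitEffectSpec(0.0, 0.0, 0.0, 2.0)}
        )
        fit = fit_random_model(df["y"], df["provenance"], df["block"])
        assert fit.sigma2_inter == pytest.approx(0.0, abs=0.05)
        assert fit.sigma2_intra == pytest.approx(4.0, rel=0.15)

    def test_row_permutation_invariance(self, balanced_trial):
        df = balanced_trial
        perm = df.sample(frac=1.0, random_state=0)
        a = fit_random_model(df["y"], df["provenance"], df["block"])
        b = fit_random_model(perm["y"], perm["provenance"], perm["block"])
        assert a.sigma2_inter == pytest.approx(b.sigma2_inter, rel=1e-6, abs=1e-10)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)

    def test_parameter_recovery_within_asymptotic_error(self):
        """Mean absolute error of each σ̂² stays below twice its asymptotic SE
        over repeated simulated trials."""
        truth = np.array([1.0, 0.25, 2.0])
        spec = {"y": TraitEffectSpec(10.0, 1.0, 0.5, np.sqrt(2.0))}
        ests = []
        for seed in range(60):
            df = simulate_trial(TrialDesign(10, 3, 10, seed=seed), spec)
            f = fit_random_model(df["y"], df["provenance"], df["block"])
            ests.append([f.sigma2_inter, f.sigma2_block, f.sigma2_intra])
        mae = np.mean(np.abs(np.array(ests) - truth), axis=0)
        # asymptotic SEs: provenance ~ σ_P²√(2/(p−1)), block ~ σ_B²√(2/(b−1)),
        # residual ~ σ_E²√(2/n)
        se = np.array(
            [1.0 * np.sqrt(2 / 9), 0.25 * np.sqrt(2 / 2), 2.0 * np.sqrt(2 / 300)]
        )
        assert np.all(mae < 2 * se)

    def test_cross_check_against_statsmodels(self, balanced_trial):
        smf = pytest.importorskip("statsmodels.formula.api")
        df = balanced_trial.assign(one=1)
        ours = fit_random_model(df["y"], df["provenance"], df["block"])
        m = smf.mixedlm(
            "y ~ 1",
            df,
            groups="one",
            vc_formula={"prov": "0 + C(provenance)", "blk": "0 + C(block)"},
        ).fit(reml=True)
        assert ours.sigma2_inter == pytest.approx(float(m.vcomp[1]), rel=1e-2)
        assert ours.sigma2_block == pytest.approx(float(m.vcomp[0]), rel=1e-2)
        assert ours.sigma2_intra == pytest.approx(float(m.scale), rel=1e-2)
        assert ours.loglik >= m.llf - 1e-4


class TestLRT:
    def test_zero_lr_gives_half(self):
        fit = fit_random_model(*small_instance())
        lr, d_aic, p = lrt_provenance(fit, fit)
        assert lr == 0.0
        assert p == pytest.approx(0.5)
        assert d_aic == pytest.approx(-2.0)

    def test_chi2_quantile_halved(self):
        class F:  # minimal stand-ins with fixed logliks
            method = "REML"

        full, red = F(), F()
        red.loglik = 0.0
        full.loglik = 3.84 / 2
        lr, _, p = lrt_provenance(full, red)
        assert lr == pytest.approx(3.84)
        assert p == pytest.approx(0.5 * stats.chi2.sf(3.84, 1), rel=1e-12)
        assert p == pytest.approx(0.025, abs=5e-4)

    def test_method_mismatch_rejected(self):
        y, prov, block = small_instance()
        full = fit_random_model(y, prov, block, method="REML")
        red = fit_block_only_model(y, prov, block, method="ML")
        with pytest.raises(ValueError):
            lrt_provenance(full, red)

    def test_corrected_p_never_above_half(self):
        for seed in range(20):
            y, prov, block = small_instance(seed=seed, n_per_cell=4, p=4, b=3)
            full = fit_random_model(y, prov, block)
            red = fit_block_only_model(y, prov, block)
            _, _, p = lrt_provenance(full, red)
            assert 0 < p <= 0.5


class TestCVandVC:
    def test_cv_inter_from_known_means(self):
        y = np.repeat([8.0, 10.0, 12.0], 4) + np.tile([-0.5, 0.5, -0.5, 0.5], 3)
        prov = np.repeat(list("abc"), 4)
        cv_inter, cv_intra = cv_components(y, prov)
        assert cv_inter == pytest.approx(20.0)
        assert cv_intra > 0

    def test_identical_values_give_zero_cv(self):
        y = np.full(12, 7.0)
        prov = np.repeat(list("abc"), 4)
        cv_inter, cv_intra = cv_components(y, prov)
        assert cv_inter == 0.0 and cv_intra == 0.0

    def test_scale_invariance(self):
        y, prov, _ = small_instance(n_per_cell=5)
        a = cv_components(y, prov)
        b = cv_components(3.7 * y, prov)
        assert a == pytest.approx(b)

    def test_pooled_option_differs_for_unequal_groups(self):
        y = np.array([1.0, 2.0, 3.0, 10.0, 10.1, 30.0])
        prov = np.array(["a", "a", "a", "b", "b", "b"])
        assert cv_components(y, prov, intra="mean") != pytest.approx(
            cv_components(y, prov, intra="pooled")
        )

    def test_vc_percentages(self):
        from beechtrial.varcomp import RandomModelFit

        fit = RandomModelFit(0, 1.0, 1.0, 2.0, 0.0, "REML", True)
        assert variance_component_percents(fit) == pytest.approx((25, 25, 50))
        fit0 = RandomModelFit(0, 0.0, 1.0, 3.0, 0.0, "REML", True)
        vc = variance_component_percents(fit0)
        assert vc[0] == 0.0 and sum(vc) == pytest.approx(100.0)
        fitc = RandomModelFit(0, 5.0, 5.0, 10.0, 0.0, "REML", True)
        assert variance_component_percents(fitc) == pytest.approx((25, 25, 50))

    def test_summary_sums_to_100(self, balanced_trial):
        df = balanced_trial
        s = variance_partition_summary("y", df["y"], df["provenance"], df["block"])
        assert s.vc_inter + s.vc_block + s.vc_intra == pytest.approx(100.0, abs=1e-6)
        assert 0 < s.p_corrected <= 0.5
        assert s.delta_aic == pytest.approx(s.lr - 2.0)


class TestClimateModel:
    def fai_map(self, provs):
        return {p: 2.0 + i for i, p in enumerate(sorted(set(provs)))}

    def test_noiseless_slope_recovered(self):
        df = simulate_trial(
            TrialDesign(6, 3, 4, seed=0), {"y": TraitEffectSpec(0.0, 0, 0, 0)}
        )
        fai = self.fai_map(df["provenance"])
        y = 1.5 + 0.4 * df["provenance"].map(fai)
        fit = fit_climate_model(y, fai, df["provenance"], df["block"])
        assert fit.beta == pytest.approx(0.4, abs=1e-6)
        assert fit.alpha == pytest.approx(1.5, abs=1e-5)

    def test_null_slope_gives_large_p(self):
        ps = []
        for seed in range(30):
            df = simulate_trial(
                TrialDesign(10, 3, 4, seed=seed),
                {"y": TraitEffectSpec(5.0, 0.0, 0.3, 1.0)},
            )
            fai = self.fai_map(df["provenance"])
            fit = fit_climate_model(df["y"], fai, df["provenance"], df["block"])
            ps.append(fit.p)
        assert (np.array(ps) < 0.05).mean() <= 0.2

    def test_strong_signal_detected(self):
        hits = 0
        n_reps = 40
        for seed in range(n_reps):
            df = simulate_trial(
                TrialDesign(10, 3, 4, seed=seed),
                {"y": TraitEffectSpec(0.0, 0.05, 0.05, 0.3)},
            )
            fai = self.fai_map(df["provenance"])
            y = df["y"] + 0.4 * df["provenance"].map(fai)
            fit = fit_climate_model(y, fai, df["provenance"], df["block"])
            hits += fit.p < 0.05
        assert hits / n_reps >= 0.95

    def test_log_transform_requires_positive(self):
        df = simulate_trial(
            TrialDesign(4, 2, 3, seed=0), {"y": TraitEffectSpec(0.0, 0, 0, 1)}
        )
        fai = self.fai_map(df["provenance"])
        with pytest.raises(ValueError):
            fit_climate_model(
                df["y"], fai, df["provenance"], df["block"], log_transform=True
            )

    def test_constant_fai_rejected(self):
        df = simulate_trial(TrialDesign(4, 2, 3, seed=0))
        fai = {p: 3.0 for p in df["provenance"].unique()}
        with pytest.raises(ValueError):
            fit_climate_model(df["DBH"], fai, df["provenance"], df["block"])
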