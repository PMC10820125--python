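import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import mcsagree as mg
from mcsagree.errors import DegenerateDataError, NumericalDomainError
from mcsagree.mixed_model import ParamLayout

from conftest import dense_loglik, make_dataset


def small_random_dataset(seed, linked=False, n_subjects=3, n_rep=3):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_subjects):
        base = 3.0 + 0.3 * rng.standard_normal()
        for m in ("ref", "tst"):
            for k in range(1, n_rep + 1):
                recs.append((f"s{i}", m, k,
                             base + 0.1 * rng.standard_normal()))
    return make_dataset(recs, linkage="linked" if linked else "unlinked")


class TestMarginalLoglik:
    def test_closed_form_shared_subject_effect(self):
        """Residual-free pairs with sigma_b2=1, errors 1: MVN([[2,1],[1,2]])."""
        ds = make_dataset([("a", "ref", 1, 3.0), ("a", "tst", 1, 3.0),
                           ("b", "ref", 1, 3.0), ("b", "tst", 1, 3.0)])
        spec = mg.ModelSpec(linkage="unlinked", heteroscedastic=False)
        layout = ParamLayout((), False, False)
        params = layout.pack(beta0=0.0, mu_b=3.0, sigma_b2=1.0, psi2=1e-300,
                             sigma_e2=(1.0, 1.0))
        expected = 2 * stats.multivariate_normal(
            mean=[0, 0], cov=[[2, 1], [1, 2]]).logpdf([0, 0])
        got = mg.marginal_loglik(params, ds, spec)
        assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("linked,hetero,seed", [
        (False, False, 0), (False, True, 1), (True, False, 2), (True, True, 3),
    ])
    def test_dense_oracle_equivalence(self, linked, hetero, seed):
        """Blocked per-subject evaluation equals one dense MVN density."""
        ds = small_random_dataset(seed, linked=linked)
        spec = mg.ModelSpec(linkage="linked" if linked else "unlinked",
                            heteroscedastic=hetero)
        layout = ParamLayout((), linked, hetero)
        rng = np.random.default_rng(100 + seed)
        for _ in range(3):
            comp = {"beta0": rng.normal(scale=0.3), "mu_b": 3.0 + rng.normal(),
                    "sigma_b2": rng.uniform(0.05, 0.5),
                    "psi2": rng.uniform(0.001, 0.05),
                    "sigma_c2": rng.uniform(0.001, 0.05),
                    "sigma_e2": rng.uniform(0.001, 0.05, size=2),
                    "delta": (rng.uniform(0, 2, size=2) if hetero
                              else np.zeros(2))}
            params = layout.pack(comp["beta0"], comp["mu_b"],
                                 comp["sigma_b2"], comp["psi2"],
                                 comp["sigma_e2"], delta=comp["delta"],
                                 sigma_c2=comp["sigma_c2"] if linked else None)
            got = mg.marginal_loglik(params, ds, spec)
            want = dense_loglik(ds, comp, linked=linked)
            assert got == pytest.approx(want, abs=1e-8)

    def test_location_invariance_when_homoscedastic(self):
        ds = small_random_dataset(7)
        spec = mg.ModelSpec(linkage="unlinked", heteroscedastic=False)
        layout = ParamLayout((), False, False)
        params = layout.pack(0.1, 3.0, 0.2, 0.01, (0.02, 0.03))
        shifted_df = ds.df.assign(value=ds.df["value"] + 5.0)
        ds2 = mg.MCSDataset(shifted_df, linkage="unlinked",
                            method_labels=ds.method_labels)
        params2 = params.copy()
        params2[1] += 5.0
        assert mg.marginal_loglik(params, ds, spec) == pytest.approx(
            mg.marginal_loglik(params2, ds2, spec), abs=1e-9)

    def test_overflowing_exponent_raises_domain_error(self):
        ds = small_random_dataset(7)
        spec = mg.ModelSpec(linkage="unlinked", heteroscedastic=True)
        layout = ParamLayout((), False, True)
        params = layout.pack(0.0, 3.0, 0.2, 0.01, (1.0, 1.0),
                             delta=(400.0, 400.0))
        with pytest.raises(NumericalDomainError):
            mg.marginal_loglik(params, ds, spec)


class TestFit:
    def test_recovers_fixed_bias_within_wald_error(self, study_fit, study_cfg):
        assert abs(study_fit.beta0 - study_cfg.beta0) \
            < 3 * study_fit.se("beta0")

    def test_delta_estimates_near_truth(self, study_fit, study_cfg):
        assert abs(study_fit.delta[0] - study_cfg.delta[0]) < 0.5 + \
            3 * study_fit.se("delta1")
        assert abs(study_fit.delta[1] - study_cfg.delta[1]) < 0.5 + \
            3 * study_fit.se("delta2")

    def test_degenerate_data_never_silently_fit(self):
        recs = [(s, m, k, 3.0) for s in "abc" for m in ("ref", "tst")
                for k in (1, 2, 3)]
        ds = make_dataset(recs)
        with pytest.raises(DegenerateDataError):
            mg.fit(ds, mg.ModelSpec(linkage="unlinked", heteroscedastic=False))

    def test_invariant_to_subject_relabeling_and_order(self, study_ds):
        spec = mg.ModelSpec(linkage="unlinked", heteroscedastic=True)
        a = mg.fit(study_ds, spec)
        df = study_ds.df.sample(frac=1.0, random_state=3).copy()
        df["subject"] = df["subject"].map(lambda s: f"Z{s}")
        b = mg.fit(mg.MCSDataset(df, linkage="unlinked",
                                 method_labels=study_ds.method_labels), spec)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-3)
        assert np.allclose(a.params, b.params, atol=1e-2)

    def test_heteroscedastic_nests_homoscedastic(self, study_ds, study_fit):
        homo = mg.fit(study_ds, mg.ModelSpec(linkage="unlinked",
                                             heteroscedastic=False))
        assert study_fit.loglik >= homo.loglik - 1e-6

    def test_small_instance_matches_dense_oracle_optimum(self):
        """The blocked fit reaches the optimum of a dense-MVN objective."""
        ds = small_random_dataset(11, n_subjects=2, n_rep=3)
        spec = mg.ModelSpec(linkage="unlinked", heteroscedastic=False)
        layout = ParamLayout((), False, False)

        def oracle_negll(theta):
            comp = layout.unpack(theta)
            try:
                return -dense_loglik(ds, comp, linked=False)
            except (np.linalg.LinAlgError, ValueError):
                return np.inf

        res = mg.fit(ds, spec)
        best = np.inf
        for s in range(3):
            rng = np.random.default_rng(s)
            x0 = res.params + rng.normal(scale=0.5, size=layout.size)
            r = optimize.minimize(oracle_negll, x0, method="Nelder-Mead",
                                  options={"maxiter": 4000, "fatol": 1e-10,
                                           "xatol": 1e-8})
            best = min(best, r.fun)
        assert res.loglik >= -best - 1e-4

    def test_anchor_choice_barely_matters(self, study_ds, study_fit):
        alt = mg.fit(study_ds, dataclasses.replace(
            study_fit.spec, variance_anchor="reference_mean"))
        assert abs(alt.beta0 - study_fit.beta0) < 0.01


class TestInformationCriteria:
    def make_fit(self, loglik, df, hetero=True, covs=()):
        layout = ParamLayout(tuple(covs), False, hetero)
        return mg.FitResult(
            spec=mg.ModelSpec(linkage="unlinked", heteroscedastic=hetero,
                              covariate_names=tuple(covs)),
            layout=layout, params=np.zeros(layout.size), vcov=None,
            loglik=loglik, df=df, n_obs=600, converged=True)

    def test_published_model_comparison_prefers_heteroscedastic(self):
        homo = self.make_fit(1478.945, 6, hetero=False)
        het = self.make_fit(1507.564, 8)
        assert homo.aic == pytest.approx(-2945.889, abs=1e-3)
        assert het.aic == pytest.approx(-2999.128, abs=1e-3)
        sel = mg.select([homo, het])
        assert sel.preferred is het

    def test_published_covariate_comparison_prefers_plain_model(self):
        plain = self.make_fit(1507.564, 8)
        covs = self.make_fit(1330.749, 10, covs=("fruit", "temp"))
        assert covs.aic == pytest.approx(-2641.498, abs=1e-3)
        assert mg.select([plain, covs]).preferred is plain

    def test_aic_tie_broken_by_bic(self):
        a = self.make_fit(100.0, 4)
        b = self.make_fit(101.0, 5)  # same AIC -192, larger BIC penalty
        assert a.aic == b.aic
        assert mg.select([b, a]).preferred is a

    def test_df_accounting_matches_model_family(self, study_ds):
        """6 free parameters homoscedastic, 8 heteroscedastic, 10 with
        two covariate terms."""
        rng = np.random.default_rng(0)
        df = study_ds.df.copy()
        df["temp"] = rng.uniform(10, 20, size=len(df))
        ds = mg.MCSDataset(df, linkage="unlinked",
                           method_labels=study_ds.method_labels)
        homo = mg.fit(ds, mg.ModelSpec(linkage="unlinked",
                                       heteroscedastic=False))
        het = mg.fit(ds, mg.ModelSpec(linkage="unlinked",
                                      heteroscedastic=True))
        full = mg.fit(ds, mg.ModelSpec(linkage="unlinked",
                                       heteroscedastic=True,
                                       covariate_names=("cluster", "temp")))
        assert (homo.df, het.df, full.df) == (6, 8, 10)


class TestResidualDiagnostics:
    def test_residual_count_and_normality(self, study_fit, study_ds):
        diag = mg.residual_diagnostics(study_fit, study_ds)
        assert len(diag) == len(study_ds)
        r = np.corrcoef(np.sort(diag["residual"]),
                        np.sort(diag["normal_quantile"]))[0, 1]
        assert r > 0.99

    def test_calibrated_under_the_truth(self, study_cfg):
        """QQ correlation > 0.99 in >= 90% of replicate fits."""
        spec = mg.ModelSpec(linkage="unlinked", heteroscedastic=True)
        hits = 0
        n = 20
        for child in np.random.SeedSequence(17).spawn(n):
            ds = mg.simulate(study_cfg, seed=child)
            res = mg.fit(ds, spec)
            if not res.converged:
                continue
            diag = mg.residual_diagnostics(res, ds)
            r = np.corrcoef(np.sort(diag["residual"]),
                            np.sort(diag["normal_quantile"]))[0, 1]
            hits += r > 0.99
        assert hits >= 0.9 * n
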