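import numpy as np
import pytest

import mcsagree as mg
from mcsagree.errors import NumericalDomainError

ARBITRARY = mg.FitResult.from_components(
    beta0=-0.15, mu_b=3.1, sigma_b2=0.06, psi2=0.004,
    sigma_e2=(4e-4, 2.5e-4), delta=(1.3, 0.8), u_range=(2.5, 4.0))


def simulate_differences(fit, u, n, seed=0):
    """MC oracle: draw D = Y2 - Y1 directly from the generative model."""
    rng = np.random.default_rng(seed)
    c = fit.components
    d = (c["beta0"]
         + rng.standard_normal(n) * np.sqrt(2 * c["psi2"])
         + rng.standard_normal(n) * np.sqrt(c["sigma_e2"][0]) * u ** c["delta"][0] * (-1)
         + rng.standard_normal(n) * np.sqrt(c["sigma_e2"][1]) * u ** c["delta"][1])
    return d


def simulate_pairs(fit, u, n, seed=0):
    rng = np.random.default_rng(seed)
    c = fit.components
    b = rng.standard_normal(n) * np.sqrt(c["sigma_b2"])
    y1 = b + rng.standard_normal(n) * np.sqrt(c["psi2"]) \
        + rng.standard_normal(n) * np.sqrt(c["sigma_e2"][0]) * u ** c["delta"][0]
    y2 = c["beta0"] + b + rng.standard_normal(n) * np.sqrt(c["psi2"]) \
        + rng.standard_normal(n) * np.sqrt(c["sigma_e2"][1]) * u ** c["delta"][1]
    return y1, y2


class TestDiffDistribution:
    def test_trivial_unit_variances(self):
        fit = mg.FitResult.from_components(
            beta0=0.0, mu_b=0.0, sigma_b2=1.0, psi2=1e-300,
            sigma_e2=(1.0, 1.0), delta=(0.0, 0.0), u_range=(1.0, 2.0))
        dist = mg.diff_distribution(fit, 1.0)
        assert dist.mean == 0.0
        assert dist.variance == pytest.approx(2.0)

    def test_published_components_at_grid_max(self, published_fit):
        """tau2(3.7) recomputed from the printed components, MC-checked."""
        dist = mg.diff_distribution(published_fit, 3.7)
        assert dist.mean == -0.22
        assert dist.variance == pytest.approx(0.0040478, abs=2e-5)
        d = simulate_differences(published_fit, 3.7, 10**6, seed=1)
        assert d.var() == pytest.approx(dist.variance, rel=0.01)

    def test_mean_independent_of_magnitude(self, published_fit):
        for u in (2.78, 3.0, 3.7):
            assert mg.diff_distribution(published_fit, u).mean == -0.22

    def test_rejects_nonpositive_magnitude(self, published_fit):
        with pytest.raises(NumericalDomainError):
            mg.diff_distribution(published_fit, 0.0)

    def test_tau2_identity_with_intra_variances(self, published_fit):
        """tau2 = 2*psi2 + v1/2 + v2/2 with v_j the intra variances."""
        for u in (2.78, 3.2, 3.7):
            v1 = mg.intra_distribution(published_fit, 1, u).variance
            v2 = mg.intra_distribution(published_fit, 2, u).variance
            assert mg.tau2(published_fit, u) == pytest.approx(
                2 * published_fit.psi2 + v1 / 2 + v2 / 2, rel=1e-12)


class TestCCC:
    def test_perfect_agreement_limit(self):
        fit = mg.FitResult.from_components(
            beta0=0.0, mu_b=3.0, sigma_b2=1.0, psi2=1e-300,
            sigma_e2=(1e-12, 1e-12), delta=(0.0, 0.0), u_range=(1.0, 2.0))
        assert mg.ccc(fit, 1.0)[0] == pytest.approx(1.0, abs=1e-9)

    def test_mc_oracle(self):
        """CCC equals 2*cov/(var1+var2+mean_diff^2) over 10^6 pairs."""
        u = 3.2
        est, _ = mg.ccc(ARBITRARY, u)
        y1, y2 = simulate_pairs(ARBITRARY, u, 10**6, seed=2)
        mc = 2 * np.cov(y1, y2)[0, 1] / (
            y1.var() + y2.var() + (y2.mean() - y1.mean()) ** 2)
        assert est == pytest.approx(mc, abs=0.005)

    def test_strictly_decreasing_in_magnitude(self, published_fit):
        grid = np.linspace(2.78, 3.7, 10)
        vals = [mg.ccc(published_fit, u)[0] for u in grid]
        assert np.all(np.diff(vals) < 0)

    def test_lower_bound_below_estimate(self, study_fit):
        est, lb = mg.ccc(study_fit, 3.2)
        assert lb < est <= 1.0


class TestTDI:
    def test_central_folded_quantile(self):
        fit = mg.FitResult.from_components(
            beta0=0.0, mu_b=0.0, sigma_b2=1.0, psi2=1e-300,
            sigma_e2=(0.5, 0.5), delta=(0.0, 0.0), u_range=(1.0, 2.0))
        est, _ = mg.tdi(fit, 0.9, 1.0)
        assert est == pytest.approx(1.6449 * np.sqrt(mg.tau2(fit, 1.0)),
                                    abs=1e-3)

    def test_mc_oracle(self):
        u = 3.0
        est, _ = mg.tdi(ARBITRARY, 0.9, u)
        d = simulate_differences(ARBITRARY, u, 10**6, seed=3)
        assert est == pytest.approx(np.quantile(np.abs(d), 0.9), rel=0.005)

    def test_monotone_in_p_and_tau(self, published_fit):
        tdis = [mg.tdi(published_fit, p, 3.0)[0] for p in (0.5, 0.8, 0.9, 0.99)]
        assert np.all(np.diff(tdis) > 0)
        assert mg.tdi(published_fit, 0.9, 3.7)[0] \
            > mg.tdi(published_fit, 0.9, 2.78)[0]

    def test_upper_bound_above_estimate(self, study_fit):
        est, ub = mg.tdi(study_fit, 0.9, 3.2)
        assert 0 < est < ub


class TestLOA:
    def test_unit_case(self):
        fit = mg.FitResult.from_components(
            beta0=0.0, mu_b=0.0, sigma_b2=1.0, psi2=0.5,
            sigma_e2=(1e-300, 1e-300), delta=(0.0, 0.0), u_range=(1.0, 2.0))
        assert mg.loa(fit, 1.0) == pytest.approx((-1.96, 1.96))

    def test_widen_with_magnitude_and_symmetric_about_bias(self, published_fit):
        widths, mids = [], []
        for u in np.linspace(2.78, 3.7, 8):
            lo, hi = mg.loa(published_fit, u)
            widths.append(hi - lo)
            mids.append((hi + lo) / 2)
        assert np.all(np.diff(widths) > 0)
        assert np.allclose(mids, published_fit.beta0, atol=1e-12)

    def test_published_extremes_bracketed(self, published_fit):
        """Printed limits at u=3.7 recomputed within rounding of delta1."""
        lo, hi = mg.loa(published_fit, 3.7)
        assert lo == pytest.approx(-0.3464, abs=0.003)
        assert hi == pytest.approx(-0.0966, abs=0.003)


class TestProfileAndRecalibration:
    def test_homoscedastic_profile_constant(self, study_ds):
        res = mg.fit(study_ds, mg.ModelSpec(linkage="unlinked",
                                            heteroscedastic=False))
        prof = mg.agreement_profile(res, mg.MagnitudeGrid.from_fit(res, 5))
        tab = prof.table
        for col in ("ccc", "tdi", "loa_lo", "loa_hi"):
            assert tab[col].nunique() == 1

    def test_grid_defaults_to_anchor_extremes(self, study_fit):
        grid = mg.MagnitudeGrid.from_fit(study_fit, 20)
        assert len(grid) == 20
        assert grid.points[0] == pytest.approx(study_fit.u_anchor.min())
        assert grid.points[-1] == pytest.approx(study_fit.u_anchor.max())

    def test_profile_deterministic(self, study_fit):
        g = mg.MagnitudeGrid.from_fit(study_fit, 6)
        a = mg.agreement_profile(study_fit, g).table
        b = mg.agreement_profile(study_fit, g).table
        assert a.equals(b)

    def test_recalibration_zeroes_fixed_bias(self, study_ds, study_fit):
        adj, refit, prof = mg.recalibrate_fixed_bias(study_ds, study_fit)
        assert abs(refit.beta0) < 0.01
        assert abs(refit.beta0) < refit.se("beta0")
        # reference untouched
        assert np.allclose(adj.method_values("reference"),
                           study_ds.method_values("reference"))
        # agreement improves once the offset is gone
        assert prof.table["ccc"].min() \
            > mg.agreement_profile(study_fit).table["ccc"].max()

    def test_recalibration_idempotent(self, study_ds, study_fit):
        adj, refit, _ = mg.recalibrate_fixed_bias(study_ds, study_fit)
        adj2, _, _ = mg.recalibrate_fixed_bias(adj, refit)
        assert np.allclose(adj2.method_values("test"),
                           adj.method_values("test"), atol=0.01)
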