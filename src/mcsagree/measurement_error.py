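"""Measurement-error models: differential and proportional bias.

The mixed-effects track assumes the two methods share a common scale
(proportional bias 1).  When that assumption is in doubt, the
measurement-error model lets the test method be an affine distortion of
the latent true value x:

    y_1ik = x_i + e_1ik                 (reference, mean-zero errors)
    y_2ik = alpha + beta * x_i + e_2ik  (test)

``alpha`` is the differential (fixed) bias, ``beta`` the proportional
bias, and ``total_bias(u) = alpha + (beta - 1) * u`` the systematic
disagreement at magnitude u.

Estimation is a two-stage scheme: (1) empirical-Bayes estimates of each
subject's true value from the reference replicates under
``x_i ~ N(mu_x, sigma_x2)``; (2) ordinary least squares of the test
replicates on those estimates.  The EB shrinkage exactly compensates
the attenuation that plugging noisy covariates into OLS would otherwise
cause, so the slope is consistent for beta.  Confidence intervals come
from a nonparametric bootstrap over subjects, which also propagates
stage-1 uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import MagnitudeGrid
from .datasets import MCSDataset
from .errors import DegenerateDataError, DesignError, NumericalDomainError

_VAR_FLOOR = 1e-12


def _stage1_eb(ref_means: np.ndarray, ref_vars: np.ndarray,
               ref_n: np.ndarray) -> np.ndarray:
    """Empirical-Bayes latent means from reference replicates."""
    mu_x = ref_means.mean()
    sigma1_2 = float(np.average(ref_vars, weights=ref_n - 1)) \
        if (ref_n > 1).any() else 0.0
    sigma_x2 = max(float(ref_means.var(ddof=1))
                   - sigma1_2 * float(np.mean(1.0 / ref_n)), _VAR_FLOOR)
    shrink = sigma_x2 / (sigma_x2 + sigma1_2 / ref_n)
    return mu_x + shrink * (ref_means - mu_x)


def _two_stage(sub: pd.DataFrame) -> tuple[float, float, np.ndarray]:
    """alpha, beta and per-subject latent means from a subject table.

    ``sub`` has one row per subject with columns ref_mean, ref_var,
    ref_n, and a list column test_vals.
    """
    x_hat = _stage1_eb(sub["ref_mean"].to_numpy(),
                       sub["ref_var"].to_numpy(),
                       sub["ref_n"].to_numpy(dtype=float))
    xs, ys = [], []
    for x, vals in zip(x_hat, sub["test_vals"]):
        xs.extend([x] * len(vals))
        ys.extend(vals)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if np.ptp(xs) <= 0:
        raise DegenerateDataError("latent means are constant; "
                                  "slope not identifiable")
    beta, alpha = np.polyfit(xs, ys, 1)
    return float(alpha), float(beta), x_hat


def _subject_table(ds: MCSDataset) -> pd.DataFrame:
    ref, test = ds.method_labels
    rows = []
    for subj, grp in ds.df.groupby("subject", sort=False):
        rv = grp.loc[grp["method"] == ref, "value"].to_numpy()
        tv = grp.loc[grp["method"] == test, "value"].to_numpy()
        rows.append({"subject": subj, "ref_mean": rv.mean(),
                     "ref_var": rv.var(ddof=1) if len(rv) > 1 else 0.0,
                     "ref_n": len(rv), "test_vals": tv,
                     "test_var": tv.var(ddof=1) if len(tv) > 1 else 0.0})
    return pd.DataFrame(rows)


def _var_coefs(x: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Quadratic fit of log within-subject variance on latent mean."""
    ls = np.log(np.clip(s2, _VAR_FLOOR, None))
    if np.ptp(x) <= 0:
        return np.array([float(ls.mean()), 0.0, 0.0])
    c2, c1, c0 = np.polyfit(x, ls, 2)
    return np.array([c0, c1, c2])


@dataclass
class MEFit:
    """Differential/proportional bias and variance functions."""

    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    latent_means: pd.Series
    var_coefs: dict            # method role -> [c0, c1, c2] on log-var scale
    boot: np.ndarray           # (B, 2) bootstrap (alpha, beta) draws
    boot_var_coefs: dict       # method role -> (B, 3)
    n_boot: int
    seed: int

    def total_bias(self, u) -> np.ndarray:
        return self.alpha + (self.beta - 1.0) * np.asarray(u, dtype=float)

    def error_sd(self, role: str, u) -> np.ndarray:
        c0, c1, c2 = self.var_coefs[role]
        u = np.asarray(u, dtype=float)
        return np.sqrt(np.exp(c0 + c1 * u + c2 * u * u))


def fit_me(ds: MCSDataset, n_boot: int = 500, seed: int = 0) -> MEFit:
    """Fit the measurement-error model by the two-stage EB scheme."""
    sub = _subject_table(ds)
    if (sub["ref_n"] < 2).any():
        raise DesignError("measurement-error fit needs >= 2 reference "
                          "replicates per subject")
    alpha, beta, x_hat = _two_stage(sub)
    vc = {"reference": _var_coefs(x_hat, sub["ref_var"].to_numpy()),
          "test": _var_coefs(x_hat, sub["test_var"].to_numpy())}

    rng = np.random.default_rng(seed)
    n = len(sub)
    boot = np.empty((n_boot, 2))
    boot_vc = {"reference": np.empty((n_boot, 3)),
               "test": np.empty((n_boot, 3))}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bs = sub.iloc[idx].reset_index(drop=True)
        try:
            a_b, b_b, x_b = _two_stage(bs)
        except DegenerateDataError:
            a_b, b_b, x_b = alpha, beta, x_hat[idx]
        boot[b] = (a_b, b_b)
        boot_vc["reference"][b] = _var_coefs(x_b, bs["ref_var"].to_numpy())
        boot_vc["test"][b] = _var_coefs(x_b, bs["test_var"].to_numpy())

    a_ci = tuple(np.percentile(boot[:, 0], [2.5, 97.5]))
    b_ci = tuple(np.percentile(boot[:, 1], [2.5, 97.5]))
    return MEFit(alpha=alpha, beta=beta, alpha_ci=a_ci, beta_ci=b_ci,
                 latent_means=pd.Series(x_hat, index=sub["subject"]),
                 var_coefs=vc, boot=boot, boot_var_coefs=boot_vc,
                 n_boot=n_boot, seed=seed)


def bias_profile(mefit: MEFit, grid: MagnitudeGrid) -> pd.DataFrame:
    """Total systematic bias alpha + (beta-1)u with bootstrap 95% CI."""
    u = grid.points
    draws = (mefit.boot[:, [0]]
             + (mefit.boot[:, [1]] - 1.0) * u[None, :])  # (B, len(u))
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return pd.DataFrame({"u": u, "bias": mefit.total_bias(u),
                         "bias_lo": lo, "bias_hi": hi})


def precision_profile(mefit: MEFit, grid: MagnitudeGrid) -> pd.DataFrame:
    """Per-method error SD over the grid with bootstrap 95% CI."""
    u = grid.points
    rows = []
    for role in ("reference", "test"):
        sd = mefit.error_sd(role, u)
        c = mefit.boot_var_coefs[role]
        draws = np.sqrt(np.exp(c[:, [0]] + c[:, [1]] * u[None, :]
                               + c[:, [2]] * u[None, :] ** 2))
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        for k in range(len(u)):
            rows.append({"method": role, "u": u[k], "sd": sd[k],
                         "sd_lo": lo[k], "sd_hi": hi[k]})
    return pd.DataFrame(rows)


def me_recalibrate(ds: MCSDataset, mefit: MEFit,
                   grid: MagnitudeGrid | None = None,
                   n_boot: int | None = None):
    """Invert the affine bias on the test method and refit.

    Test values become ``(y - alpha) / beta``.  Returns the adjusted
    dataset, the refitted :class:`MEFit` and its post-adjustment bias
    profile (which should sit at ~0 across the grid).
    """
    if abs(mefit.beta) < 1e-8:
        raise NumericalDomainError("proportional bias ~ 0: calibration "
                                   "not invertible")
    new_vals = (ds.method_values(ds.test).to_numpy() - mefit.alpha) / mefit.beta
    adjusted = ds.replace_test_values(new_vals)
    refit = fit_me(adjusted, n_boot=n_boot or mefit.n_boot, seed=mefit.seed)
    if grid is None:
        lo = float(mefit.latent_means.min())
        hi = float(mefit.latent_means.max())
        grid = MagnitudeGrid.from_range(lo, hi) if hi > lo \
            else MagnitudeGrid(np.array([lo]))
    return adjusted, refit, bias_profile(refit, grid)
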