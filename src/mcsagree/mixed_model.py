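"""Marginal maximum likelihood for two-method mixed-effects models.

The model for measurement ``k`` of subject ``i`` by method ``j``
(j = 1 reference, j = 2 test) is::

    y_ijk = mu_b + beta0 * 1[j = 2] + x_ijk' gamma + b_i + b_ij + c_ik + e_ijk

with independent normal random effects

* ``b_i   ~ N(0, sigma_b2)``   subject effect,
* ``b_ij  ~ N(0, psi2)``       subject x method interaction,
* ``c_ik  ~ N(0, sigma_c2)``   subject x occasion effect (linked data only),
* ``e_ijk ~ N(0, sigma_ej2 * u_i^(2*delta_j))`` heteroscedastic error,

where ``u_i`` is a per-subject magnitude anchor (the mean of the two
methods' replicate means by default) held fixed during estimation, and
``g(u, delta) = u^delta`` is the power-of-magnitude variance function
acting on the error SD.  Setting ``delta_1 = delta_2 = 0`` recovers the
homoscedastic model, which is therefore nested.

Estimation maximizes the marginal likelihood: random effects are
integrated out analytically, leaving one multivariate-normal density
per subject with covariance

    Sigma_i = sigma_b2 * J + psi2 * blockdiag(J, J) [+ sigma_c2 * P] + diag(v)

(J = all-ones, P = same-occasion indicator).  Variances are optimized
on the log scale and ``delta``/fixed effects on the identity scale, so
the parameter vector is unconstrained; the observed-information
covariance comes from a finite-difference Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import LINKED, UNLINKED, MCSDataset
from .errors import (ConvergenceError, DegenerateDataError, DesignError,
                     NumericalDomainError)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which member of the model family to fit."""

    linkage: str = UNLINKED
    heteroscedastic: bool = True
    covariate_names: tuple[str, ...] = ()
    variance_anchor: str = "pairwise_mean"  # or "reference_mean"
    p: float = 0.9  # TDI proportion carried through to reporting

    def __post_init__(self):
        if self.linkage not in (LINKED, UNLINKED):
            raise ValueError(f"bad linkage {self.linkage!r}")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")


@dataclass(frozen=True)
class ParamLayout:
    """Order of the unconstrained (transformed-scale) parameter vector."""

    covariates: tuple[str, ...]
    linked: bool
    heteroscedastic: bool

    @property
    def names(self) -> tuple[str, ...]:
        out = ["beta0", "mu_b"] + [f"coef_{c}" for c in self.covariates]
        out += ["log_sigma_b2", "log_psi2"]
        if self.linked:
            out.append("log_sigma_c2")
        out += ["log_sigma_e1_2", "log_sigma_e2_2"]
        if self.heteroscedastic:
            out += ["delta1", "delta2"]
        return tuple(out)

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def unpack(self, theta: np.ndarray) -> dict:
        """Transformed vector -> natural-scale component dict."""
        theta = np.asarray(theta, dtype=float)
        nc = len(self.covariates)
        i = 2 + nc
        out = {"beta0": theta[0], "mu_b": theta[1],
               "coefs": theta[2:2 + nc],
               "sigma_b2": np.exp(theta[i]), "psi2": np.exp(theta[i + 1])}
        i += 2
        if self.linked:
            out["sigma_c2"] = np.exp(theta[i])
            i += 1
        else:
            out["sigma_c2"] = 0.0
        out["sigma_e2"] = np.exp(theta[i:i + 2])
        i += 2
        if self.heteroscedastic:
            out["delta"] = theta[i:i + 2].copy()
        else:
            out["delta"] = np.zeros(2)
        return out

    def pack(self, beta0, mu_b, sigma_b2, psi2, sigma_e2, delta=(0.0, 0.0),
             sigma_c2=None, coefs=()) -> np.ndarray:
        vec = [beta0, mu_b, *coefs, np.log(sigma_b2), np.log(psi2)]
        if self.linked:
            vec.append(np.log(sigma_c2))
        vec += [np.log(sigma_e2[0]), np.log(sigma_e2[1])]
        if self.heteroscedastic:
            vec += [delta[0], delta[1]]
        return np.asarray(vec, dtype=float)


# ---------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------

@dataclass
class _Group:
    """Subjects sharing one replicate pattern, stacked for batched algebra."""

    subjects: list
    y: np.ndarray          # (S, m)
    X: np.ndarray          # (S, m, c)
    test_ind: np.ndarray   # (m,)
    u: np.ndarray          # (S,)
    B: np.ndarray          # (m, m) same-method block
    P: np.ndarray | None   # (m, m) same-occasion block (linked)
    row_index: np.ndarray  # (S, m) positions in ds.df


def _build_groups(ds: MCSDataset, spec: ModelSpec,
                  u_anchor: pd.Series) -> list[_Group]:
    for c in spec.covariate_names:
        if c not in ds.df.columns:
            raise DesignError(f"covariate {c!r} not in dataset")
    ref, test = ds.method_labels
    df = ds.df.reset_index(drop=True)
    buckets: dict = {}
    for subj, grp in df.groupby("subject", sort=False):
        grp = grp.sort_values(["method", "occasion"],
                              key=lambda s: s.map({ref: 0, test: 1})
                              if s.name == "method" else s)
        is_test = (grp["method"] == test).to_numpy()
        occ = grp["occasion"].to_numpy()
        key = (tuple(is_test.astype(int)), tuple(occ) if spec.linkage == LINKED
               else None)
        buckets.setdefault(key, []).append((subj, grp))
    groups = []
    for (ind_key, occ_key), members in buckets.items():
        test_ind = np.array(ind_key, dtype=float)
        m = len(test_ind)
        B = np.equal.outer(test_ind, test_ind).astype(float)
        P = None
        if occ_key is not None:
            occ = np.array(occ_key)
            P = np.equal.outer(occ, occ).astype(float)
        y = np.stack([g["value"].to_numpy(dtype=float) for _, g in members])
        if spec.covariate_names:
            X = np.stack([g[list(spec.covariate_names)].to_numpy(dtype=float)
                          for _, g in members])
        else:
            X = np.zeros((len(members), m, 0))
        u = np.array([u_anchor[s] for s, _ in members], dtype=float)
        row_index = np.stack([g.index.to_numpy() for _, g in members])
        groups.append(_Group(subjects=[s for s, _ in members], y=y, X=X,
                             test_ind=test_ind, u=u, B=B, P=P,
                             row_index=row_index))
    return groups


def _group_cov(group: _Group, comp: dict) -> np.ndarray:
    """Batched per-subject covariance matrices (S, m, m)."""
    m = len(group.test_ind)
    base = comp["sigma_b2"] * np.ones((m, m)) + comp["psi2"] * group.B
    if group.P is not None and comp["sigma_c2"] > 0:
        base = base + comp["sigma_c2"] * group.P
    with np.errstate(over="ignore", invalid="ignore"):
        pow1 = group.u[:, None] ** (2.0 * comp["delta"][0])
        pow2 = group.u[:, None] ** (2.0 * comp["delta"][1])
        var_e = np.where(group.test_ind[None, :] > 0,
                         comp["sigma_e2"][1] * pow2,
                         comp["sigma_e2"][0] * pow1)
    Sigma = np.broadcast_to(base, (len(group.u), m, m)).copy()
    idx = np.arange(m)
    Sigma[:, idx, idx] += var_e
    return Sigma


def _group_mean(group: _Group, comp: dict) -> np.ndarray:
    mu = comp["mu_b"] + comp["beta0"] * group.test_ind[None, :]
    if group.X.shape[2]:
        mu = mu + group.X @ comp["coefs"]
    return mu


def _negloglik_factory(groups: list[_Group],
                       layout: ParamLayout) -> Callable[[np.ndarray], float]:
    def negll(theta: np.ndarray) -> float:
        comp = layout.unpack(theta)
        total = 0.0
        for g in groups:
            Sigma = _group_cov(g, comp)
            if not np.all(np.isfinite(Sigma)):
                return np.inf
            try:
                L = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return np.inf
            r = g.y - _group_mean(g, comp)
            z = np.linalg.solve(L, r[:, :, None])[:, :, 0]
            logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
            m = r.shape[1]
            total += -0.5 * (r.shape[0] * m * _LOG2PI + logdet + np.sum(z * z))
        return -total
    return negll


def marginal_loglik(params: np.ndarray, ds: MCSDataset, spec: ModelSpec,
                    u_anchor: pd.Series | None = None) -> float:
    """Marginal log-likelihood (natural log, with normalizing constants).

    ``params`` is the transformed-scale vector in :class:`ParamLayout`
    order.  Raises :class:`NumericalDomainError` when the parameter
    point yields a non-finite or non-positive-definite covariance.
    """
    layout = ParamLayout(tuple(spec.covariate_names),
                         spec.linkage == LINKED, spec.heteroscedastic)
    params = np.asarray(params, dtype=float)
    if params.shape != (layout.size,):
        raise ValueError(f"expected {layout.size} parameters "
                         f"({layout.names}), got {params.shape}")
    if u_anchor is None:
        u_anchor = ds.magnitude_anchors(spec.variance_anchor)
    groups = _build_groups(ds, spec, u_anchor)
    val = -_negloglik_factory(groups, layout)(params)
    if not np.isfinite(val):
        raise NumericalDomainError(
            f"non-finite likelihood at {dict(zip(layout.names, params))}")
    return float(val)


# ---------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------

@dataclass
class FitResult:
    """ML estimates and uncertainty for one mixed-effects model variant."""

    spec: ModelSpec
    layout: ParamLayout
    params: np.ndarray            # transformed scale
    vcov: np.ndarray | None       # transformed scale
    loglik: float
    df: int
    n_obs: int
    converged: bool
    u_anchor: pd.Series | None = None
    notes: list = field(default_factory=list)

    # natural-scale accessors -----------------------------------------
    @property
    def components(self) -> dict:
        return self.layout.unpack(self.params)

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def mu_b(self) -> float:
        return float(self.params[1])

    @property
    def covariate_coefs(self) -> dict:
        c = self.components["coefs"]
        return dict(zip(self.layout.covariates, map(float, c)))

    @property
    def sigma_b2(self) -> float:
        return float(self.components["sigma_b2"])

    @property
    def psi2(self) -> float:
        return float(self.components["psi2"])

    @property
    def sigma_c2(self) -> float:
        return float(self.components["sigma_c2"])

    @property
    def sigma_e2(self) -> tuple[float, float]:
        return tuple(map(float, self.components["sigma_e2"]))

    @property
    def delta(self) -> tuple[float, float]:
        return tuple(map(float, self.components["delta"]))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.df

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.df * np.log(self.n_obs)

    def se(self, name: str) -> float:
        if self.vcov is None:
            return np.nan
        i = self.layout.index(name)
        return float(np.sqrt(max(self.vcov[i, i], 0.0)))

    @property
    def u_range(self) -> tuple[float, float]:
        if self.u_anchor is None:
            raise ValueError("fit carries no magnitude anchors")
        return float(self.u_anchor.min()), float(self.u_anchor.max())

    def summary_table(self) -> pd.DataFrame:
        """Parameter/Estimate/SE/95% CI table on the transformed scale."""
        rows = []
        for i, name in enumerate(self.layout.names):
            est = self.params[i]
            se = self.se(name)
            rows.append({"parameter": name, "estimate": est, "se": se,
                         "ci_lower": est - 1.96 * se,
                         "ci_upper": est + 1.96 * se})
        return pd.DataFrame(rows)

    @classmethod
    def from_components(cls, beta0, mu_b, sigma_b2, psi2, sigma_e2, delta,
                        sigma_c2=None, u_range=(0.0, 0.0),
                        spec: ModelSpec | None = None) -> "FitResult":
        """Build a (vcov-free) result from known variance components.

        Useful for evaluating agreement formulas at published or
        simulated-truth parameter values without refitting.
        """
        if spec is None:
            spec = ModelSpec(linkage=LINKED if sigma_c2 is not None
                             else UNLINKED,
                             heteroscedastic=not np.allclose(delta, 0.0))
        layout = ParamLayout((), spec.linkage == LINKED, spec.heteroscedastic)
        params = layout.pack(beta0, mu_b, sigma_b2, psi2, sigma_e2,
                             delta=delta, sigma_c2=sigma_c2)
        anchors = pd.Series(np.asarray(u_range, dtype=float))
        return cls(spec=spec, layout=layout, params=params, vcov=None,
                   loglik=np.nan, df=layout.size, n_obs=0, converged=True,
                   u_anchor=anchors)


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

def _moment_init(ds: MCSDataset, spec: ModelSpec, layout: ParamLayout,
                 u_anchor: pd.Series) -> np.ndarray:
    means = ds.subject_method_means()
    ref, test = ds.method_labels
    beta0 = float((means[test] - means[ref]).mean())
    mu_b = float(means[ref].mean())
    per = ds.df.groupby(["subject", "method"])["value"].agg(["var", "size"])
    log_se = []
    deltas = []
    for m in (ref, test):
        v = per.xs(m, level="method")["var"].clip(lower=1e-10)
        u = u_anchor.reindex(v.index).to_numpy()
        lv = np.log(v.to_numpy())
        if spec.heteroscedastic and np.ptp(np.log(u)) > 0:
            slope, intercept = np.polyfit(np.log(u), lv, 1)
            d = float(np.clip(slope / 2.0, -8.0, 8.0))
        else:
            intercept, d = float(np.mean(lv)), 0.0
        log_se.append(float(np.clip(intercept, -40.0, 10.0)))
        deltas.append(d)
    n_bar = per["size"].mean()
    var_d = float((means[test] - means[ref]).var(ddof=1))
    mean_werr = float(np.exp(log_se[0]) + np.exp(log_se[1])) / max(n_bar, 1.0)
    psi2 = max((var_d - mean_werr) / 2.0, 1e-6)
    sigma_b2 = max(float(means[ref].var(ddof=1)) - psi2, 1e-4)
    return layout.pack(beta0, mu_b, sigma_b2, psi2,
                       np.exp(log_se), delta=deltas,
                       sigma_c2=(np.exp(min(log_se)) if spec.linkage == LINKED
                                 else None),
                       coefs=np.zeros(len(layout.covariates)))


def _num_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                 rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        for j in range(i, n):
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h[i] * h[j])
    return H


def fit(ds: MCSDataset, spec: ModelSpec, init: np.ndarray | None = None,
        tol: float = 1e-8, max_iter: int = 600,
        allow_linked_fallback: bool = True) -> FitResult:
    """Maximize the marginal likelihood by quasi-Newton (L-BFGS-B).

    The magnitude anchors ``u_i`` are computed once from the data
    (plug-in) and held fixed.  On non-convergence three jittered
    restarts are tried; a linked fit that still fails falls back to the
    unlinked model with a note, since the occasion component is the
    usual culprit and the unlinked family is nested sensibly.
    """
    counts = ds.df.groupby(["subject", "method"])["value"].size()
    if (counts < 2).any():
        raise DesignError("error variances need >= 2 replicates "
                          "per subject x method")
    if float(ds.df["value"].var(ddof=1)) <= 0.0:
        raise DegenerateDataError("data carry no variation at all")

    layout = ParamLayout(tuple(spec.covariate_names),
                         spec.linkage == LINKED, spec.heteroscedastic)
    u_anchor = ds.magnitude_anchors(spec.variance_anchor)
    if (u_anchor <= 0).any():
        raise NumericalDomainError("magnitude anchors must be positive")
    groups = _build_groups(ds, spec, u_anchor)
    negll = _negloglik_factory(groups, layout)

    x0 = np.asarray(init, dtype=float) if init is not None \
        else _moment_init(ds, spec, layout, u_anchor)
    if not np.isfinite(negll(x0)):
        x0 = layout.pack(0.0, float(ds.df["value"].mean()), 0.1, 0.01,
                         (0.1, 0.1), sigma_c2=0.01)

    def _minimize(x):
        return optimize.minimize(negll, x, method="L-BFGS-B",
                                 options={"maxiter": max_iter, "ftol": tol,
                                          "maxfun": 20 * max_iter})

    res = _minimize(x0)
    notes: list[str] = []
    if not res.success or not np.isfinite(res.fun):
        rng = np.random.default_rng(0)
        best = res
        for _ in range(3):
            x_j = x0 + rng.normal(scale=0.3, size=layout.size)
            r = _minimize(x_j)
            if np.isfinite(r.fun) and (not np.isfinite(best.fun)
                                       or r.fun < best.fun):
                best = r
        res = best
        if not res.success:
            notes.append("non-convergence after multi-start")

    converged = bool(res.success and np.isfinite(res.fun))
    if not converged and spec.linkage == LINKED and allow_linked_fallback:
        fallback = fit(ds, replace(spec, linkage=UNLINKED), tol=tol,
                       max_iter=max_iter)
        fallback.notes.append("linked fit failed; fell back to unlinked model")
        return fallback

    vcov = None
    if np.isfinite(res.fun):
        H = _num_hessian(negll, res.x)
        if np.all(np.isfinite(H)):
            vcov = np.linalg.pinv(H)
            vcov = (vcov + vcov.T) / 2.0
            w, V = np.linalg.eigh(vcov)
            vcov = (V * np.clip(w, 0.0, None)) @ V.T  # project to PSD
    return FitResult(spec=spec, layout=layout, params=res.x, vcov=vcov,
                     loglik=float(-res.fun), df=layout.size, n_obs=len(ds),
                     converged=converged, u_anchor=u_anchor, notes=notes)


# ---------------------------------------------------------------------
# model selection and diagnostics
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    ranked: list[FitResult]
    table: pd.DataFrame

    @property
    def preferred(self) -> FitResult:
        return self.ranked[0]


def select(fits: Sequence[FitResult],
           labels: Sequence[str] | None = None) -> SelectionResult:
    """Rank fits by AIC (ties: BIC, then fewer df); smallest wins."""
    if not fits:
        raise ValueError("select() needs at least one fit")
    if labels is None:
        labels = [("heteroscedastic" if f.spec.heteroscedastic
                   else "homoscedastic")
                  + ("+covariates" if f.spec.covariate_names else "")
                  for f in fits]
    order = sorted(range(len(fits)),
                   key=lambda i: (fits[i].aic, fits[i].bic, fits[i].df))
    table = pd.DataFrame({
        "model": [labels[i] for i in order],
        "aic": [fits[i].aic for i in order],
        "bic": [fits[i].bic for i in order],
        "loglik": [fits[i].loglik for i in order],
        "df": [fits[i].df for i in order],
        "converged": [fits[i].converged for i in order],
    })
    return SelectionResult(ranked=[fits[i] for i in order], table=table)


def residual_diagnostics(fit_result: FitResult, ds: MCSDataset) -> pd.DataFrame:
    """Standardized conditional residuals with normal quantiles.

    The residual is (y - fitted mean - BLUP of the summed random
    effects) / model error SD; the BLUP is the conditional mean of the
    random part given the subject's full response vector.  Theoretical
    quantiles use the Blom plotting positions, ready for a QQ display.
    """
    if not fit_result.converged:
        raise ConvergenceError("diagnostics need a converged fit")
    spec = fit_result.spec
    comp = fit_result.components
    u_anchor = ds.magnitude_anchors(spec.variance_anchor)
    groups = _build_groups(ds, spec, u_anchor)
    rows = []
    for g in groups:
        Sigma = _group_cov(g, comp)
        m = Sigma.shape[1]
        idx = np.arange(m)
        var_e = Sigma[:, idx, idx].copy()
        r = g.y - _group_mean(g, comp)
        # conditional residual r - blup = E Sigma^-1 r with E = diag(var_e);
        # its variance is (E Sigma^-1 E)_kk, the right standardization scale
        inv_r = np.linalg.solve(Sigma, r[:, :, None])[:, :, 0]
        cond = var_e * inv_r
        inv_diag = np.diagonal(np.linalg.inv(Sigma), axis1=1, axis2=2)
        resid = cond / (var_e * np.sqrt(inv_diag))
        for s, subj in enumerate(g.subjects):
            for k in range(m):
                rows.append({"subject": subj,
                             "row": int(g.row_index[s, k]),
                             "residual": resid[s, k]})
    out = pd.DataFrame(rows).sort_values("row").reset_index(drop=True)
    n = len(out)
    ranks = out["residual"].rank(method="first")
    out["normal_quantile"] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out
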