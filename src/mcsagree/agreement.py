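"""Inter-method agreement indices from a fitted mixed-effects model.

Given the fitted variance components, the between-method difference at
magnitude ``u`` is

    D | u  ~  N(beta0, tau2(u)),
    tau2(u) = 2*psi2 + sigma_e1_2 * u^(2*delta1) + sigma_e2_2 * u^(2*delta2)

(the occasion component sigma_c2 cancels when linked replicates are
differenced at the same occasion, so it never enters tau2).  From this
distribution follow

* the concordance correlation coefficient
  ``CCC(u) = 2*sigma_b2 / (2*sigma_b2 + 2*psi2 + beta0^2 + sum_j sigma_ej2 u^(2 delta_j))``,
* the total deviation index ``TDI(p, u)``, the p-quantile of |D|,
* 95% limits of agreement ``beta0 -+ 1.96 * tau(u)``.

One-sided 95% confidence bounds (lower for CCC, upper for TDI) use the
delta method on transformed scales — Fisher z for CCC, log for TDI —
with gradients taken numerically against the fit's observed-information
covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MCSDataset
from .errors import ConvergenceError, NumericalDomainError
from .mixed_model import FitResult, fit as fit_model

_Z_ONE_SIDED = stats.norm.ppf(0.95)   # 1.6449
_Z_LOA = 1.96


@dataclass(frozen=True)
class MagnitudeGrid:
    """Ordered magnitudes u at which indices are evaluated."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or len(pts) == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if len(pts) > 1 and not np.all(np.diff(pts) > 0):
            raise ValueError("grid points must be strictly increasing")
        if (pts <= 0).any():
            raise NumericalDomainError("magnitudes must be positive")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_fit(cls, fit_result: FitResult, n: int = 20) -> "MagnitudeGrid":
        lo, hi = fit_result.u_range
        if lo == hi:
            return cls(np.array([lo]))
        return cls(np.linspace(lo, hi, n))

    @classmethod
    def from_range(cls, lo: float, hi: float, n: int = 20) -> "MagnitudeGrid":
        return cls(np.linspace(lo, hi, n))

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class DiffDist:
    """Normal law of the between-method difference D at one magnitude."""

    mean: float
    variance: float

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def _comp_tau2(comp: dict, u: float) -> float:
    se = comp["sigma_e2"]
    d = comp["delta"]
    return float(2.0 * comp["psi2"]
                 + se[0] * u ** (2.0 * d[0]) + se[1] * u ** (2.0 * d[1]))


def tau2(fit_result: FitResult, u: float) -> float:
    """Variance of D at magnitude u (occasion effect excluded)."""
    if u <= 0:
        raise NumericalDomainError("u must be positive")
    return _comp_tau2(fit_result.components, u)


def diff_distribution(fit_result: FitResult, u: float) -> DiffDist:
    """Distribution of the between-method difference given u."""
    _require_converged(fit_result)
    return DiffDist(mean=fit_result.beta0, variance=tau2(fit_result, u))


def _require_converged(fit_result: FitResult) -> None:
    if not fit_result.converged:
        raise ConvergenceError("agreement indices need a converged fit")


def _delta_se(fit_result: FitResult, func, rel_step: float = 1e-5) -> float:
    """Delta-method SE of scalar func(theta) at the fitted parameters."""
    if fit_result.vcov is None:
        return np.nan
    x = fit_result.params
    h = rel_step * (1.0 + np.abs(x))
    g = np.empty_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (func(x + e) - func(x - e)) / (2.0 * h[i])
    var = float(g @ fit_result.vcov @ g)
    return float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------

def _comp_ccc(comp: dict, u: float) -> float:
    num = 2.0 * comp["sigma_b2"]
    den = num + 2.0 * comp["psi2"] + comp["beta0"] ** 2 + (
        _comp_tau2(comp, u) - 2.0 * comp["psi2"])
    if den <= 0:
        raise NumericalDomainError("degenerate CCC denominator")
    return float(num / den)


def ccc(fit_result: FitResult, u: float) -> tuple[float, float]:
    """CCC estimate and its one-sided 95% lower bound (Fisher z scale)."""
    _require_converged(fit_result)
    if u <= 0:
        raise NumericalDomainError("u must be positive")
    est = _comp_ccc(fit_result.components, u)
    layout = fit_result.layout
    se_z = _delta_se(fit_result,
                     lambda th: np.arctanh(_comp_ccc(layout.unpack(th), u)))
    lower = np.tanh(np.arctanh(est) - _Z_ONE_SIDED * se_z) \
        if np.isfinite(se_z) else np.nan
    return est, float(lower)


def _comp_tdi(comp: dict, p: float, u: float) -> float:
    t2 = _comp_tau2(comp, u)
    nc = comp["beta0"] ** 2 / t2
    return float(np.sqrt(t2 * stats.ncx2.ppf(p, df=1, nc=nc)))


def tdi(fit_result: FitResult, p: float, u: float) -> tuple[float, float]:
    """TDI(p) estimate and one-sided 95% upper bound (log scale).

    The estimate is the p-quantile of |D| with D ~ N(beta0, tau2(u)):
    tau(u) times the square root of the noncentral chi-square(1)
    quantile with noncentrality beta0^2/tau2(u).
    """
    _require_converged(fit_result)
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if u <= 0:
        raise NumericalDomainError("u must be positive")
    est = _comp_tdi(fit_result.components, p, u)
    layout = fit_result.layout
    se_log = _delta_se(fit_result,
                       lambda th: np.log(_comp_tdi(layout.unpack(th), p, u)))
    upper = np.exp(np.log(est) + _Z_ONE_SIDED * se_log) \
        if np.isfinite(se_log) else np.nan
    return est, float(upper)


def loa(fit_result: FitResult, u: float) -> tuple[float, float]:
    """Model-based 95% limits of agreement beta0 -+ 1.96*tau(u)."""
    _require_converged(fit_result)
    t = np.sqrt(tau2(fit_result, u))
    return (float(fit_result.beta0 - _Z_LOA * t),
            float(fit_result.beta0 + _Z_LOA * t))


@dataclass(frozen=True)
class AgreementProfile:
    """CCC/TDI/LOA with bounds over a magnitude grid."""

    table: pd.DataFrame  # u, ccc, ccc_lb, tdi, tdi_ub, loa_lo, loa_hi
    p: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def agreement_profile(fit_result: FitResult, grid: MagnitudeGrid | None = None,
                      p: float = 0.9) -> AgreementProfile:
    """Evaluate all inter-method indices at every grid point."""
    _require_converged(fit_result)
    if grid is None:
        grid = MagnitudeGrid.from_fit(fit_result)
    rows = []
    for u in grid.points:
        c, c_lb = ccc(fit_result, u)
        t, t_ub = tdi(fit_result, p, u)
        lo, hi = loa(fit_result, u)
        rows.append({"u": u, "ccc": c, "ccc_lb": c_lb,
                     "tdi": t, "tdi_ub": t_ub, "loa_lo": lo, "loa_hi": hi})
    return AgreementProfile(table=pd.DataFrame(rows), p=p)


def recalibrate_fixed_bias(ds: MCSDataset, fit_result: FitResult,
                           grid: MagnitudeGrid | None = None,
                           p: float = 0.9):
    """Subtract the fitted fixed bias from the test method and refit.

    Returns ``(adjusted dataset, new fit, new profile)``.  Indices come
    from a full refit rather than plugging beta0 = 0 into the old fit,
    because removing the offset also shifts the magnitude anchors.
    Reference-method values are never touched.
    """
    _require_converged(fit_result)
    test_vals = ds.method_values(ds.test).to_numpy() - fit_result.beta0
    adjusted = ds.replace_test_values(test_vals)
    new_fit = fit_model(adjusted, fit_result.spec)
    profile = agreement_profile(new_fit, grid, p=p)
    return adjusted, new_fit, profile
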