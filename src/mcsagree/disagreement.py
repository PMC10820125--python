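"""Similarity and repeatability: where does disagreement come from?

*Similarity* compares the two methods' systematic and random error:
the fixed bias ``beta0`` (the mixed-effects track assumes proportional
bias 1) and the precision ratio

    lambda(u) = sigma_e1_2 * u^(2*delta1) / (sigma_e2_2 * u^(2*delta2)),

the ratio of reference to test error variance at magnitude ``u``
(lambda > 1 means the test method is the more precise one).

*Repeatability* is intra-method agreement: the difference of two
replicates of method ``j`` on the same subject is

    D_j | u ~ N(0, 2 * sigma_ej2 * u^(2*delta_j)),

from which intra-method CCC, TDI and limits of agreement follow in
direct analogy to the inter-method versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import MagnitudeGrid, _Z_LOA, _Z_ONE_SIDED, _delta_se
from .errors import ConvergenceError, NumericalDomainError
from .mixed_model import FitResult

_Z_TWO_SIDED = 1.96


def _check(fit_result: FitResult, j: int | None = None,
           u: float | None = None) -> None:
    if not fit_result.converged:
        raise ConvergenceError("indices need a converged fit")
    if j is not None and j not in (1, 2):
        raise ValueError("method index j must be 1 (reference) or 2 (test)")
    if u is not None and u <= 0:
        raise NumericalDomainError("u must be positive")


def _intra_var(comp: dict, j: int, u: float) -> float:
    """Variance of a within-method replicate difference: 2*sigma_ej2*u^2dj."""
    return float(2.0 * comp["sigma_e2"][j - 1]
                 * u ** (2.0 * comp["delta"][j - 1]))


@dataclass(frozen=True)
class IntraDist:
    """Normal law of a same-method replicate difference at magnitude u."""

    method_index: int
    variance: float
    mean: float = 0.0

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def intra_distribution(fit_result: FitResult, j: int, u: float) -> IntraDist:
    _check(fit_result, j, u)
    return IntraDist(method_index=j,
                     variance=_intra_var(fit_result.components, j, u))


@dataclass(frozen=True)
class SimilarityResult:
    fixed_bias: float
    fixed_bias_ci: tuple[float, float]
    precision_ratio: pd.DataFrame  # u, lam, lam_lo, lam_hi


def precision_ratio(fit_result: FitResult, u: float) -> tuple[float, float, float]:
    """lambda(u) with a two-sided 95% log-scale Wald interval.

    log lambda is linear in the transformed parameters, so the interval
    comes straight from the joint vcov of (log error variances, deltas).
    """
    _check(fit_result, u=u)
    comp = fit_result.components
    lam = (comp["sigma_e2"][0] * u ** (2.0 * comp["delta"][0])
           / (comp["sigma_e2"][1] * u ** (2.0 * comp["delta"][1])))
    layout = fit_result.layout
    if fit_result.vcov is None:
        return float(lam), np.nan, np.nan
    g = np.zeros(layout.size)
    g[layout.index("log_sigma_e1_2")] = 1.0
    g[layout.index("log_sigma_e2_2")] = -1.0
    if layout.heteroscedastic:
        g[layout.index("delta1")] = 2.0 * np.log(u)
        g[layout.index("delta2")] = -2.0 * np.log(u)
    se = np.sqrt(max(float(g @ fit_result.vcov @ g), 0.0))
    return (float(lam),
            float(lam * np.exp(-_Z_TWO_SIDED * se)),
            float(lam * np.exp(_Z_TWO_SIDED * se)))


def similarity(fit_result: FitResult,
               grid: MagnitudeGrid | None = None) -> SimilarityResult:
    """Fixed bias with 95% CI plus the precision-ratio profile."""
    _check(fit_result)
    if grid is None:
        grid = MagnitudeGrid.from_fit(fit_result)
    se_b = fit_result.se("beta0")
    rows = []
    for u in grid.points:
        lam, lo, hi = precision_ratio(fit_result, u)
        rows.append({"u": u, "lam": lam, "lam_lo": lo, "lam_hi": hi})
    return SimilarityResult(
        fixed_bias=fit_result.beta0,
        fixed_bias_ci=(fit_result.beta0 - _Z_TWO_SIDED * se_b,
                       fit_result.beta0 + _Z_TWO_SIDED * se_b),
        precision_ratio=pd.DataFrame(rows))


# ---------------------------------------------------------------------
# repeatability indices
# ---------------------------------------------------------------------

def _comp_intra_ccc(comp: dict, j: int, u: float) -> float:
    num = comp["sigma_b2"] + comp["psi2"]
    den = num + comp["sigma_e2"][j - 1] * u ** (2.0 * comp["delta"][j - 1])
    if den <= 0:
        raise NumericalDomainError("degenerate intra-CCC denominator")
    return float(num / den)


def intra_ccc(fit_result: FitResult, j: int, u: float) -> tuple[float, float]:
    """Intra-method CCC with one-sided 95% lower bound (Fisher z)."""
    _check(fit_result, j, u)
    est = _comp_intra_ccc(fit_result.components, j, u)
    layout = fit_result.layout
    se_z = _delta_se(fit_result,
                     lambda th: np.arctanh(_comp_intra_ccc(layout.unpack(th),
                                                           j, u)))
    lower = np.tanh(np.arctanh(est) - _Z_ONE_SIDED * se_z) \
        if np.isfinite(se_z) else np.nan
    return est, float(lower)


def intra_tdi(fit_result: FitResult, j: int, p: float,
              u: float) -> tuple[float, float]:
    """Intra-method TDI(p): central folded-normal quantile, upper bound.

    The replicate difference is centered at zero, so the estimate is
    sqrt(2*sigma_ej2*u^(2 delta_j)) * z_{(1+p)/2}.
    """
    _check(fit_result, j, u)
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    zq = stats.norm.ppf((1.0 + p) / 2.0)

    def est_fn(comp):
        return float(np.sqrt(_intra_var(comp, j, u)) * zq)

    est = est_fn(fit_result.components)
    layout = fit_result.layout
    se_log = _delta_se(fit_result,
                       lambda th: np.log(est_fn(layout.unpack(th))))
    upper = np.exp(np.log(est) + _Z_ONE_SIDED * se_log) \
        if np.isfinite(se_log) else np.nan
    return est, float(upper)


def intra_loa(fit_result: FitResult, j: int, u: float) -> tuple[float, float]:
    """Intra-method 95% limits of agreement, centered at zero."""
    _check(fit_result, j, u)
    half = _Z_LOA * np.sqrt(_intra_var(fit_result.components, j, u))
    return -float(half), float(half)


def repeatability_table(fit_result: FitResult,
                        grid: MagnitudeGrid | None = None,
                        p: float = 0.9) -> pd.DataFrame:
    """Intra-method CCC/TDI/LOA for both methods over the grid."""
    _check(fit_result)
    if grid is None:
        grid = MagnitudeGrid.from_fit(fit_result)
    rows = []
    for j, role in ((1, "reference"), (2, "test")):
        for u in grid.points:
            c, c_lb = intra_ccc(fit_result, j, u)
            t, t_ub = intra_tdi(fit_result, j, p, u)
            lo, hi = intra_loa(fit_result, j, u)
            rows.append({"method": role, "u": u, "ccc": c, "ccc_lb": c_lb,
                         "tdi": t, "tdi_ub": t_ub,
                         "loa_lo": lo, "loa_hi": hi})
    return pd.DataFrame(rows)
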