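"""Exploratory statistics for method-comparison data.

Covers the classic Bland-Altman quantities with confidence intervals,
the extended Bland-Altman proportional-trend check, trellis-plot data
(within- vs between-subject spread) and subject x method / subject x
time interaction summaries.  All outputs are plain pandas objects ready
to be written as CSV plot data; nothing here renders graphics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import LINKED, MCSDataset
from .errors import InsufficientDataError, LinkageError


@dataclass(frozen=True)
class BAStats:
    """Bland-Altman summary: differences are test - reference.

    Confidence intervals follow the classic construction:
    SE(mean) = sd/sqrt(n), SE(limit) = sd*sqrt(3/n), two-sided 95%
    with a t(n-1) quantile.
    """

    pairs: pd.DataFrame  # columns subject, occasion, average, difference
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]
    ci_mean: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    trend_slope: float
    trend_pvalue: float
    z: float


def _matched_pairs(ds: MCSDataset) -> pd.DataFrame:
    """(average, difference) pairs.

    Linked data pair by occasion; unlinked data use one pair of
    per-subject means per subject, avoiding artificial replicate
    pairings.
    """
    ref, test = ds.method_labels
    if ds.linkage == LINKED:
        wide = ds.df.pivot_table(index=["subject", "occasion"],
                                 columns="method", values="value",
                                 aggfunc="first").reset_index()
    else:
        wide = ds.subject_method_means().reset_index()
        wide["occasion"] = 1
    wide = wide.dropna(subset=[ref, test])
    out = wide[["subject", "occasion"]].copy()
    out["average"] = (wide[ref] + wide[test]) / 2.0
    out["difference"] = wide[test] - wide[ref]
    return out.reset_index(drop=True)


def bland_altman(ds: MCSDataset, z: float = 1.96) -> BAStats:
    """Bland-Altman statistics with classic confidence intervals."""
    if z <= 0:
        raise ValueError("z must be positive")
    pairs = _matched_pairs(ds)
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 matched pairs, got {n}")
    d = pairs["difference"].to_numpy()
    a = pairs["average"].to_numpy()
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa = (mean_diff - z * sd_diff, mean_diff + z * sd_diff)
    tq = stats.t.ppf(0.975, n - 1)
    se_mean = sd_diff / np.sqrt(n)
    se_limit = sd_diff * np.sqrt(3.0 / n)
    # Trend on per-subject means: replicate-level pairs share the
    # subject x method effect, so regressing all of them pseudo-replicates
    # and wildly over-rejects the no-trend null.  The proportional-bias
    # question lives at the subject level.
    sub = pairs.groupby("subject")[["average", "difference"]].mean()
    if len(sub) >= 3 and np.ptp(sub["average"].to_numpy()) > 0:
        reg = stats.linregress(sub["average"], sub["difference"])
        slope, pval = float(reg.slope), float(reg.pvalue)
    else:  # constant averages: no trend estimable
        slope, pval = 0.0, 1.0
    return BAStats(
        pairs=pairs, mean_diff=mean_diff, sd_diff=sd_diff, loa=loa,
        ci_mean=(mean_diff - tq * se_mean, mean_diff + tq * se_mean),
        ci_loa_lower=(loa[0] - tq * se_limit, loa[0] + tq * se_limit),
        ci_loa_upper=(loa[1] - tq * se_limit, loa[1] + tq * se_limit),
        trend_slope=slope, trend_pvalue=pval, z=z)


def extended_ba(ds: MCSDataset, alpha: float = 0.05) -> tuple[BAStats, bool]:
    """Bland-Altman plus a proportional-trend verdict.

    A linear trend of differences on averages signals a violation of
    the equal-proportional-bias assumption of the mixed-effects track.
    Returns ``(stats, trend_present)`` with trend declared when the
    two-sided slope p-value is below ``alpha``.
    """
    ba = bland_altman(ds)
    return ba, bool(ba.trend_pvalue < alpha)


@dataclass(frozen=True)
class TrellisData:
    rows: pd.DataFrame            # subject, method, value; subjects ordered
    subject_order: list
    between_range: tuple[float, float]
    within_spread: dict           # method -> mean of per-subject SDs


def trellis_data(ds: MCSDataset) -> TrellisData:
    """Per-subject value rows ordered by subject mean, plus spread stats.

    The between-subject range is the (min, max) of subject-level means
    of pairwise averages; within-subject spread per method is the mean
    of per-subject SDs.
    """
    anchors = ds.magnitude_anchors("pairwise_mean")
    order = list(anchors.sort_values().index)
    rows = ds.df[["subject", "method", "value"]].copy()
    rows["subject_rank"] = rows["subject"].map(
        {s: i for i, s in enumerate(order)})
    rows = rows.sort_values(["subject_rank", "method"]).reset_index(drop=True)
    within = {}
    for m in ds.method_labels:
        sds = (ds.df[ds.df["method"] == m]
               .groupby("subject")["value"].std(ddof=1).fillna(0.0))
        within[m] = float(sds.mean())
    return TrellisData(rows=rows, subject_order=order,
                       between_range=(float(anchors.min()), float(anchors.max())),
                       within_spread=within)


@dataclass(frozen=True)
class InteractionSummary:
    method_profiles: pd.DataFrame  # index subject, columns methods
    time_profiles: pd.DataFrame | None  # index subject, columns occasions
    method_crossings: int
    time_crossings: int | None


def _count_crossings(profiles: pd.DataFrame) -> int:
    """Pairs of subject profile lines whose difference changes sign."""
    vals = profiles.to_numpy()
    n = len(vals)
    crossings = 0
    for i, j in combinations(range(n), 2):
        diff = vals[i] - vals[j]
        sign = np.sign(diff)
        nz = sign[sign != 0]
        if len(nz) and (nz != nz[0]).any():
            crossings += 1
    return crossings


def interaction_summary(ds: MCSDataset,
                        with_time: bool | None = None) -> InteractionSummary:
    """Subject x method and subject x time mean profiles with crossing counts.

    A subject pair "crosses" when the sign of the difference of their
    profiles changes between the two methods (or between adjacent time
    points).  Crossings in the method profiles hint at a subject x
    method interaction (the ψ² component); crossings over time hint at
    linked structure.
    """
    if with_time is None:
        with_time = ds.linkage == LINKED
    method_profiles = ds.subject_method_means()
    time_profiles = None
    time_crossings = None
    if with_time:
        if ds.linkage != LINKED:
            raise LinkageError("subject x time profiles require linked data")
        time_profiles = ds.df.pivot_table(index="subject", columns="occasion",
                                          values="value", aggfunc="mean")
        time_crossings = _count_crossings(time_profiles)
    return InteractionSummary(method_profiles=method_profiles,
                              time_profiles=time_profiles,
                              method_crossings=_count_crossings(method_profiles),
                              time_crossings=time_crossings)
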