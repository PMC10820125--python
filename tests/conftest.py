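"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import mcsagree as mg


@pytest.fixture(scope="session")
def study_cfg():
    return mg.default_study_config()


@pytest.fixture(scope="session")
def study_ds(study_cfg):
    """One synthetic study with the published design and components."""
    return mg.simulate(study_cfg, seed=1)


@pytest.fixture(scope="session")
def study_fit(study_ds):
    """Heteroscedastic unlinked fit, as the published analysis used."""
    res = mg.fit(study_ds, mg.ModelSpec(linkage="unlinked",
                                        heteroscedastic=True))
    assert res.converged
    return res


@pytest.fixture(scope="session")
def published_fit():
    """Variance components as printed for the study's selected model."""
    return mg.FitResult.from_components(
        beta0=-0.22, mu_b=3.27,
        sigma_b2=0.03934918, psi2=0.002548149 / 2.0,
        sigma_e2=(2.615606e-8, 7.374885e-8), delta=(4.07, 3.28),
        u_range=(2.78, 3.7))


def make_dataset(records, linkage="unlinked", labels=("ref", "tst")):
    """Small hand-written dataset from (subject, method, occasion, value)."""
    df = pd.DataFrame(records, columns=["subject", "method", "occasion",
                                        "value"])
    return mg.MCSDataset(df, linkage=linkage, method_labels=labels)


def dense_loglik(ds, comp, linked, u_anchor=None):
    """Brute-force oracle: one dense MVN over the full stacked vector.

    Builds the complete observation covariance element by element from
    the random-effects structure — independent of the package's
    per-subject blocked evaluation.
    """
    df = ds.df.reset_index(drop=True)
    ref, test = ds.method_labels
    if u_anchor is None:
        u_anchor = ds.magnitude_anchors("pairwise_mean")
    n = len(df)
    subj = df["subject"].to_numpy()
    meth = df["method"].to_numpy()
    occ = df["occasion"].to_numpy()
    y = df["value"].to_numpy(dtype=float)
    mean = np.full(n, comp["mu_b"], dtype=float)
    mean[meth == test] += comp["beta0"]
    cov = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if subj[a] != subj[b]:
                continue
            cov[a, b] += comp["sigma_b2"]
            if meth[a] == meth[b]:
                cov[a, b] += comp["psi2"]
            if linked and occ[a] == occ[b]:
                cov[a, b] += comp.get("sigma_c2", 0.0)
            if a == b:
                j = 0 if meth[a] == ref else 1
                u = float(u_anchor[subj[a]])
                cov[a, b] += comp["sigma_e2"][j] * u ** (2 * comp["delta"][j])
    return float(multivariate_normal(mean=mean, cov=cov).logpdf(y))
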