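"""Data model and I/O for method-comparison datasets.

A method comparison study (MCS) measures the same subjects with two
methods (a *reference* and a *test* method), each several times.  When
the replicates of the two methods are paired by a common measurement
occasion the data are *linked*; when they are obtained separately they
are *unlinked*.  The distinction changes both validation rules and the
covariance structure used downstream.

The canonical in-memory container is :class:`MCSDataset`, a thin,
validated wrapper around a long-format :class:`pandas.DataFrame` with
columns ``subject``, ``method``, ``occasion``, ``value`` plus any
covariates.  Method labels are always stored as the ordered pair
``(reference, test)`` and every signed quantity downstream is
``test - reference``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, ParseError, SchemaError

LINKED = "linked"
UNLINKED = "unlinked"

#: canonical column names of the internal long-format frame
CORE_COLUMNS = ("subject", "method", "occasion", "value")


@dataclass(frozen=True)
class Measurement:
    """One observation: a subject measured once by one method."""

    subject: object
    method: str
    occasion: int
    value: float
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("measurement value must be finite")
        if self.occasion < 1:
            raise ValueError("occasion index starts at 1")


@dataclass(frozen=True)
class DesignSummary:
    """Shape and six-number summaries of a study design."""

    n_subjects: int
    replicates: pd.DataFrame  # index subject, columns method labels, counts
    balanced: bool
    per_method_summary: pd.DataFrame  # rows method, cols min/q1/median/mean/q3/max
    covariate_list: tuple[str, ...]


class MCSDataset:
    """Replicated two-method measurements with linkage structure.

    Parameters
    ----------
    df
        Long-format frame with at least the columns ``subject``,
        ``method``, ``occasion``, ``value``.  Extra columns are treated
        as covariates.
    linkage
        ``"linked"`` if replicates are paired across methods by
        occasion, else ``"unlinked"``.
    method_labels
        Ordered pair, reference first.
    """

    def __init__(self, df: pd.DataFrame, linkage: str = UNLINKED,
                 method_labels: Sequence[str] | None = None,
                 n_dropped: int = 0):
        df = df.copy()
        for col in CORE_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        if linkage not in (LINKED, UNLINKED):
            raise DesignError(f"linkage must be linked/unlinked, got {linkage!r}")
        labels = list(pd.unique(df["method"])) if method_labels is None \
            else list(method_labels)
        if len(labels) != 2:
            raise DesignError(f"exactly two method labels required, got {labels}")
        extra = set(pd.unique(df["method"])) - set(labels)
        if extra:
            raise DesignError(f"unregistered method labels {sorted(map(str, extra))}")
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
        if not np.isfinite(df["value"]).all():
            raise ParseError("non-finite measurement values present")
        df["occasion"] = df["occasion"].astype(int)
        if (df["occasion"] < 1).any():
            raise DesignError("occasion indices must be >= 1")

        self.df = df.reset_index(drop=True)
        self.linkage = linkage
        self.method_labels: tuple[str, str] = (labels[0], labels[1])
        self.n_dropped = n_dropped
        self._validate()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        subjects = self.df["subject"].unique()
        if len(subjects) < 2:
            raise DesignError("a method comparison study needs >= 2 subjects")
        counts = self.df.pivot_table(index="subject", columns="method",
                                     values="value", aggfunc="size", fill_value=0)
        for lab in self.method_labels:
            if lab not in counts.columns or (counts[lab] < 1).any():
                raise DesignError(
                    f"every subject needs >= 1 record for method {lab!r}")
        if self.linkage == LINKED:
            ref, test = self.method_labels
            for subj, grp in self.df.groupby("subject", sort=False):
                occ_ref = sorted(grp.loc[grp["method"] == ref, "occasion"])
                occ_test = sorted(grp.loc[grp["method"] == test, "occasion"])
                if occ_ref != occ_test:
                    raise DesignError(
                        f"linked data require matching occasion sets per subject; "
                        f"subject {subj!r} has {occ_ref} vs {occ_test}")
                if len(set(occ_ref)) != len(occ_ref):
                    raise DesignError(
                        f"duplicate occasions for subject {subj!r}")

    # -- accessors ----------------------------------------------------
    @property
    def reference(self) -> str:
        return self.method_labels[0]

    @property
    def test(self) -> str:
        return self.method_labels[1]

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.df["subject"]))

    @property
    def n_subjects(self) -> int:
        return self.df["subject"].nunique()

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.df.columns if c not in CORE_COLUMNS)

    @property
    def records(self) -> Iterator[Measurement]:
        covs = self.covariate_names
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield Measurement(subject=d["subject"], method=d["method"],
                              occasion=int(d["occasion"]), value=float(d["value"]),
                              covariates={c: d[c] for c in covs})

    def method_values(self, method: str) -> pd.Series:
        return self.df.loc[self.df["method"] == method, "value"]

    def subject_method_means(self) -> pd.DataFrame:
        """Per-subject mean value for each method (columns ref, test)."""
        tab = self.df.pivot_table(index="subject", columns="method",
                                  values="value", aggfunc="mean")
        return tab[list(self.method_labels)]

    def magnitude_anchors(self, kind: str = "pairwise_mean") -> pd.Series:
        """Per-subject magnitude anchor u~ for variance functions.

        ``pairwise_mean``: (ȳ_i1 + ȳ_i2)/2; ``reference_mean``: ȳ_i1.
        """
        means = self.subject_method_means()
        if kind == "pairwise_mean":
            return means.mean(axis=1)
        if kind == "reference_mean":
            return means[self.reference]
        raise ValueError(f"unknown anchor kind {kind!r}")

    def replace_test_values(self, new_values: np.ndarray) -> "MCSDataset":
        """Return a copy with the test method's value column replaced."""
        df = self.df.copy()
        mask = df["method"] == self.test
        if mask.sum() != len(new_values):
            raise ValueError("replacement length mismatch")
        df.loc[mask, "value"] = np.asarray(new_values, dtype=float)
        return MCSDataset(df, self.linkage, self.method_labels)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"MCSDataset({self.n_subjects} subjects, {len(self)} records, "
                f"{self.linkage}, methods={self.method_labels})")


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

DEFAULT_SCHEMA = {"subject": "subject", "method": "method",
                  "occasion": "occasion", "value": "value"}


def read_long(path, schema: Mapping[str, str] | None = None,
              linkage: str = UNLINKED,
              method_labels: Sequence[str] | None = None) -> MCSDataset:
    """Read a long-format delimited file into a validated :class:`MCSDataset`.

    ``schema`` maps the roles ``subject``, ``method``, ``occasion``,
    ``value`` (and optionally ``covariates``: a list of column names) to
    the file's column names.  Rows with a missing value are dropped and
    counted in ``n_dropped``.  The first entry of ``method_labels`` (or,
    if omitted, the first method encountered in the file) becomes the
    reference.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    covariates = list(schema.pop("covariates", []))
    raw = pd.read_csv(path)
    missing = [col for col in schema.values() if col not in raw.columns]
    missing += [c for c in covariates if c not in raw.columns]
    if missing:
        raise SchemaError(f"columns {missing} not found in {path}")
    df = raw[[schema[r] for r in CORE_COLUMNS] + covariates].copy()
    df.columns = list(CORE_COLUMNS) + covariates

    n_before = len(df)
    df = df.dropna(subset=["value"])
    n_dropped = n_before - len(df)
    try:
        df["value"] = pd.to_numeric(df["value"], errors="raise")
    except (ValueError, TypeError) as exc:
        bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()]
        raise ParseError(f"non-numeric value in rows {list(bad[:5])}") from exc

    if df["method"].nunique() < 2 or df["subject"].nunique() < 2:
        raise DesignError("need at least two methods and two subjects")
    if method_labels is None:
        method_labels = list(pd.unique(df["method"]))
    return MCSDataset(df, linkage=linkage, method_labels=method_labels,
                      n_dropped=n_dropped)


def write_long(ds: MCSDataset, path) -> None:
    """Write the dataset back out as CSV (inverse of :func:`read_long`)."""
    ds.df.to_csv(path, index=False)


def to_wide(ds: MCSDataset) -> pd.DataFrame:
    """Reshape to one row per subject x occasion, one value column per method.

    Linked data pair rows by occasion.  Unlinked data are paired by
    within-subject rank order purely for presentation (models never use
    this pairing); trailing unmatched replicates get NaN in the shorter
    method's column and ``unmatched=True``.
    """
    ref, test = ds.method_labels
    if ds.linkage == LINKED:
        wide = ds.df.pivot_table(index=["subject", "occasion"], columns="method",
                                 values="value", aggfunc="first").reset_index()
        wide = wide[["subject", "occasion", ref, test]]
        wide["unmatched"] = False
        wide.columns.name = None
        return wide
    rows = []
    for subj, grp in ds.df.groupby("subject", sort=False):
        vals = {m: sorted(grp.loc[grp["method"] == m, "value"])
                for m in (ref, test)}
        k = max(len(vals[ref]), len(vals[test]))
        for i in range(k):
            rows.append({
                "subject": subj, "occasion": i + 1,
                ref: vals[ref][i] if i < len(vals[ref]) else np.nan,
                test: vals[test][i] if i < len(vals[test]) else np.nan,
            })
    wide = pd.DataFrame(rows)
    wide["unmatched"] = wide[[ref, test]].isna().any(axis=1)
    return wide


def from_wide(wide: pd.DataFrame, method_labels: Sequence[str],
              linkage: str = LINKED) -> MCSDataset:
    """Inverse of :func:`to_wide` for fully matched rows."""
    long = wide.melt(id_vars=["subject", "occasion"],
                     value_vars=list(method_labels),
                     var_name="method", value_name="value").dropna(subset=["value"])
    return MCSDataset(long, linkage=linkage, method_labels=method_labels)


def design_summary(ds: MCSDataset) -> DesignSummary:
    """Per-method six-number summaries and replicate accounting.

    Quartiles use the linear-interpolation definition (numpy default).
    """
    counts = ds.df.pivot_table(index="subject", columns="method",
                               values="value", aggfunc="size", fill_value=0)
    counts = counts[list(ds.method_labels)]
    balanced = counts.to_numpy().min() == counts.to_numpy().max()
    rows = {}
    for m in ds.method_labels:
        v = ds.method_values(m).to_numpy()
        v = v[np.isfinite(v)]
        rows[m] = {"min": v.min(),
                   "q1": np.percentile(v, 25),
                   "median": np.median(v),
                   "mean": v.mean(),
                   "q3": np.percentile(v, 75),
                   "max": v.max()}
    summary = pd.DataFrame(rows).T
    return DesignSummary(n_subjects=ds.n_subjects, replicates=counts,
                         balanced=bool(balanced),
                         per_method_summary=summary,
                         covariate_list=ds.covariate_names)
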