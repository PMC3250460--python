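"""Batch-effect diagnosis for methylation cohorts.

Three views of batch susceptibility:

* :func:`probe_batch_anova` — per-probe one-way ANOVA of Beta values on
  the batch (or laboratory) label, BH-adjusted, summarised as the
  fraction of probes significantly associated with batch at a given FDR.
* :func:`batch_purity_clustering` — average-linkage hierarchical
  clustering of samples on Euclidean distances between Beta profiles;
  reports whether cutting into one cluster per batch reproduces the
  batch labels exactly, plus an adjusted Rand agreement score.
* :func:`batch_vs_batch_dm_corruption` — calls differential methylation
  for two tumour batches against one shared normal group and measures
  the direction consistency of the shared DM genes, demonstrating how
  batch effects masquerade as biology.

The per-probe ANOVA is also available as the sklearn-style estimator
:class:`BatchANOVA` (fit on samples × probes with a batch label vector).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.metrics import adjusted_rand_score

from .differential import benjamini_hochberg, dm_ttest
from .exceptions import InputError
from .io import GROUP_NORMAL, GROUP_TUMOUR
from .reproducibility import direction_consistency


class BatchANOVA(BaseEstimator):
    """Per-feature one-way ANOVA against a categorical batch label.

    Parameters
    ----------
    fdr : float
        BH threshold defining the ``susceptible_fraction_``.

    Attributes
    ----------
    fstat_, pvalue_, qvalue_ : ndarray, NaN for untested features.
    tested_ : boolean mask of features with non-zero total variance.
    susceptible_fraction_ : fraction of tested features with q < fdr.
    """

    def __init__(self, fdr: float = 0.05):
        self.fdr = fdr

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise InputError("X must be samples × features with one label per sample")
        groups, counts = np.unique(y, return_counts=True)
        if len(groups) < 2:
            raise InputError(f"need >=2 groups, got {list(groups)}")
        small = groups[counts < 2]
        if small.size:
            raise InputError(f"group(s) with <2 samples: {list(small)}")
        n, m = X.shape
        k = len(groups)

        grand = X.mean(axis=0)
        ssb = np.zeros(m)
        ssw = np.zeros(m)
        for g, ng in zip(groups, counts):
            sub = X[y == g]
            gm = sub.mean(axis=0)
            ssb += ng * (gm - grand) ** 2
            ssw += ((sub - gm) ** 2).sum(axis=0)
        sst = ssb + ssw
        tested = sst > 0
        if not tested.any():
            raise InputError("all features are constant; nothing to test")

        fstat = np.full(m, np.nan)
        p = np.full(m, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb / (k - 1)) / (ssw / (n - k))
        # zero within-group variance with real between-group differences:
        # infinite F, p -> 0
        f = np.where((ssw == 0) & (ssb > 0), np.inf, f)
        fstat[tested] = f[tested]
        p[tested] = stats.f.sf(f[tested], k - 1, n - k)
        p[tested & (ssw == 0) & (ssb > 0)] = 0.0

        q = np.full(m, np.nan)
        q[tested] = benjamini_hochberg(p[tested])

        self.n_features_in_ = m
        self.groups_ = groups
        self.fstat_ = fstat
        self.pvalue_ = p
        self.qvalue_ = q
        self.tested_ = tested
        self.n_skipped_ = int((~tested).sum())
        self.susceptible_fraction_ = float((q[tested] < self.fdr).mean())
        return self


@dataclass
class BatchAssessment:
    """Per-probe batch ANOVA results plus the susceptibility summary."""

    table: pd.DataFrame  # columns F, p, q, tested
    susceptible_fraction: float
    fdr: float
    label: str
    n_skipped: int


def probe_batch_anova(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    label: str = "batch",
    fdr: float = 0.05,
) -> BatchAssessment:
    """One-way ANOVA of each probe's Beta values on a grouping label.

    ``label`` selects the sample-sheet column ("batch" or "laboratory").
    Probes with zero total variance are skipped and reported; probes with
    missing values are excluded beforehand.
    """
    if label not in sheet.columns:
        raise InputError(f"sample sheet has no column {label!r}")
    sheet = sheet.loc[matrix.columns]
    matrix = matrix.dropna(axis=0)
    est = BatchANOVA(fdr=fdr).fit(matrix.to_numpy().T, sheet[label].to_numpy())
    table = pd.DataFrame(
        {"F": est.fstat_, "p": est.pvalue_, "q": est.qvalue_, "tested": est.tested_},
        index=matrix.index,
    )
    return BatchAssessment(
        table=table,
        susceptible_fraction=est.susceptible_fraction_,
        fdr=fdr,
        label=label,
        n_skipped=est.n_skipped_,
    )


@dataclass
class ClusteringReport:
    """Sample-clustering agreement with batch labels."""

    labels: pd.Series  # cluster id per sample
    perfect_split: bool | None  # None when not applicable (single batch)
    agreement: float  # adjusted Rand index, NaN when not applicable
    n_batches: int
    linkage_method: str


def batch_purity_clustering(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    label: str = "batch",
    linkage_method: str = "average",
) -> ClusteringReport:
    """Hierarchically cluster samples and compare the cut to batch labels.

    Samples are clustered on Euclidean distances between their Beta
    profiles; the tree is cut into as many clusters as there are batch
    labels.  ``perfect_split`` is True when the cut reproduces the batch
    partition exactly; ``agreement`` is the adjusted Rand index.
    """
    sheet = sheet.loc[matrix.columns]
    batches = sheet[label].to_numpy()
    n_batches = len(pd.unique(batches))
    if matrix.shape[1] < 2:
        raise InputError("need >=2 samples to cluster")
    profiles = matrix.dropna(axis=0).to_numpy().T
    Z = linkage(pdist(profiles, metric="euclidean"), method=linkage_method)
    if n_batches < 2:
        labels = pd.Series(1, index=matrix.columns, name="cluster")
        return ClusteringReport(labels, None, float("nan"), n_batches, linkage_method)
    clusters = fcluster(Z, t=n_batches, criterion="maxclust")
    ari = float(adjusted_rand_score(batches, clusters))
    perfect = bool(
        len(pd.unique(clusters)) == n_batches
        and pd.crosstab(batches, clusters).gt(0).sum(axis=1).eq(1).all()
        and pd.crosstab(clusters, batches).gt(0).sum(axis=1).eq(1).all()
    )
    labels = pd.Series(clusters, index=matrix.columns, name="cluster")
    return ClusteringReport(labels, perfect, ari, n_batches, linkage_method)


@dataclass
class CorruptionReport:
    """Direction consistency of DM genes called from two tumour batches
    against one shared normal group."""

    k: int
    n_consistent: int
    consistency: float  # NaN when k == 0
    binomial_p: float
    n_dm_a: int
    n_dm_b: int


def batch_vs_batch_dm_corruption(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    tumour_batch_a: str,
    tumour_batch_b: str,
    fdr: float = 0.05,
    normal_samples: list[str] | None = None,
) -> CorruptionReport:
    """Compare DM calls from two tumour batches against shared normals.

    Tumour samples of each batch are tested (unpaired) against the same
    normal set; the report gives the direction consistency of the DM
    features shared by the two calls.  Low consistency with strong batch
    offsets shows differential methylation driven by batch, not biology.
    """
    sheet = sheet.loc[matrix.columns]
    tum_a = sheet[(sheet["group"] == GROUP_TUMOUR) & (sheet["batch"] == tumour_batch_a)].index
    tum_b = sheet[(sheet["group"] == GROUP_TUMOUR) & (sheet["batch"] == tumour_batch_b)].index
    if normal_samples is None:
        normals = sheet[sheet["group"] == GROUP_NORMAL].index
    else:
        normals = pd.Index(normal_samples)
    if tumour_batch_a != tumour_batch_b and (
        len(tum_a.intersection(tum_b)) or len(tum_a.intersection(normals))
        or len(tum_b.intersection(normals))
    ):
        raise InputError("tumour batches and the normal set must be disjoint")
    if len(tum_a) == 0 or len(tum_b) == 0 or len(normals) == 0:
        raise InputError("empty tumour batch or normal set")

    results = {}
    for name, tum in (("a", tum_a), ("b", tum_b)):
        cols = tum.append(normals)
        results[name] = dm_ttest(matrix[cols], sheet.loc[cols], fdr=fdr, paired=False)
    sig_a = results["a"][results["a"]["significant"]]
    sig_b = results["b"][results["b"]["significant"]]
    shared = sig_a.index.intersection(sig_b.index)
    if len(shared) == 0:
        return CorruptionReport(0, 0, float("nan"), float("nan"),
                                len(sig_a), len(sig_b))
    frac, p, n_cons = direction_consistency(
        sig_a.loc[shared, "direction"], sig_b.loc[shared, "direction"]
    )
    return CorruptionReport(len(shared), n_cons, frac, p, len(sig_a), len(sig_b))
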