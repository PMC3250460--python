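"""Differential methylation and expression calling.

Two estimators follow the scikit-learn protocol (``fit(X, y)`` on a
samples × features matrix with a two-level group label vector, fitted
attributes with trailing underscores):

* :class:`GroupTTest` — per-feature two-sided t test (Welch by default,
  paired optional) with Benjamini–Hochberg FDR control.  Used for
  differential methylation on Beta values.
* :class:`SAM` — Significance Analysis of Microarrays: the regularised
  statistic d = (mean₁ − mean₂)/(s + s₀) with a permutation-based FDR
  estimate and symmetric-threshold significance band.  Used for
  differential expression on log2 intensities.

The module-level operations :func:`dm_ttest` and :func:`sam_de` wrap the
estimators, taking the package's feature × sample matrices plus a sample
sheet and returning per-feature result tables (statistic, p, q,
direction, effect, significant), optionally collapsed to genes.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .io import GROUP_TUMOUR, check_pairing, collapse_probes_to_genes

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTTest",
    "SAM",
    "dm_ttest",
    "sam_de",
    "apply_effect_filters",
    "benjamini_hochberg",
]


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _validate_two_groups(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise InputError(f"X must be 2-dimensional (samples × features), got shape {X.shape}")
    if len(y) != X.shape[0]:
        raise InputError(f"y has {len(y)} labels for {X.shape[0]} samples")
    levels = pd.unique(y)
    if len(levels) != 2:
        raise InputError(f"exactly two group labels required, got {list(levels)}")
    return X, y, levels


class GroupTTest(BaseEstimator):
    """Per-feature two-sample t test with BH FDR control.

    Parameters
    ----------
    alpha : float
        FDR threshold for the ``significant_`` flag.
    paired : bool
        Paired t test; requires ``pairs`` in :meth:`fit` identifying
        which samples belong together.
    equal_var : bool
        Pooled-variance (Student) t instead of the default Welch t.
    positive_label :
        The group whose mean enters the effect with positive sign
        (effect = mean(positive) − mean(other)).  Defaults to the first
        label encountered.
    direction_labels : tuple of str
        Names attached to positive / negative effects, e.g.
        ``("hyper", "hypo")`` for methylation or ``("up", "down")`` for
        expression.

    Attributes
    ----------
    statistic_, pvalue_, qvalue_, effect_ : ndarray of shape (n_features,)
    direction_ : ndarray of str — positive/negative label, "none" at
        exactly zero effect.
    significant_ : ndarray of bool — q < alpha.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        paired: bool = False,
        equal_var: bool = False,
        positive_label=None,
        direction_labels: tuple[str, str] = ("hyper", "hypo"),
    ):
        self.alpha = alpha
        self.paired = paired
        self.equal_var = equal_var
        self.positive_label = positive_label
        self.direction_labels = direction_labels

    def fit(self, X, y, pairs=None):
        X, y, levels = _validate_two_groups(X, y)
        pos = self.positive_label if self.positive_label is not None else levels[0]
        if pos not in levels:
            raise InputError(f"positive_label {pos!r} not among group labels {list(levels)}")
        neg = [lab for lab in levels if lab != pos][0]
        a = X[y == pos]
        b = X[y == neg]

        if self.paired:
            if pairs is None:
                raise InputError("paired=True requires a pairs vector in fit")
            pairs = np.asarray(pairs)
            pa = pairs[y == pos]
            pb = pairs[y == neg]
            common, ia, ib = np.intersect1d(pa, pb, return_indices=True)
            if len(common) < 2 or len(pa) != len(set(pa)) or len(pb) != len(set(pb)):
                raise InputError("paired test requires >=2 unique complete pairs")
            a, b = a[ia], b[ib]
            with np.errstate(invalid="ignore", divide="ignore"):
                stat, p = stats.ttest_rel(a, b, axis=0)
        else:
            if a.shape[0] < 2 or b.shape[0] < 2:
                raise InputError(
                    f"each group needs >=2 samples (got {a.shape[0]} and {b.shape[0]})"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                stat, p = stats.ttest_ind(a, b, axis=0, equal_var=self.equal_var)

        effect = a.mean(axis=0) - b.mean(axis=0)
        stat = np.asarray(stat, dtype=float)
        p = np.asarray(p, dtype=float)
        # zero-variance contract: identical groups -> t=0, p=1; constant
        # groups with different means -> p -> 0
        undef = ~np.isfinite(stat)
        zero_eff = np.isclose(effect, 0.0)
        stat[undef & zero_eff] = 0.0
        p[undef & zero_eff] = 1.0
        stat[undef & ~zero_eff] = np.sign(effect[undef & ~zero_eff]) * np.inf
        p[undef & ~zero_eff] = 0.0

        self.n_features_in_ = X.shape[1]
        self.statistic_ = stat
        self.pvalue_ = p
        self.qvalue_ = benjamini_hochberg(p)
        self.effect_ = effect
        up, down = self.direction_labels
        self.direction_ = np.where(effect > 0, up, np.where(effect < 0, down, "none"))
        self.significant_ = self.qvalue_ < self.alpha
        return self


class SAM(BaseEstimator):
    """Significance Analysis of Microarrays (two-class, unpaired).

    Per feature, d = (mean₁ − mean₂) / (s + s₀), with s the pooled
    standard error and s₀ a fudge constant chosen by minimising the
    coefficient of variation of the spread of d across the range of s
    (the standard automatic choice; set ``s0="median"`` for the median
    of s, or pass a float).  Group-label permutations supply expected
    order statistics and the FDR estimate: for a symmetric band at
    threshold Δ on the deviations between observed and expected order
    statistics, the number of falsely called features is estimated from
    the per-permutation counts of permuted d values beyond the band's
    cut points — the mean count by default (``fdr_estimator`` selects
    the classic median or the conservative 90th percentile; the median
    variant is anti-conservative at extreme cuts, where over half of
    the permutations show nothing beyond the cut while the observed
    data does).  The smallest Δ whose estimated FDR is at or below
    ``fdr`` defines the significant set.  Per-feature q values are the
    estimated FDR at a symmetric cut placed at each feature's own |d|
    (monotonised).

    All randomness flows from ``random_state``; if the number of
    distinct label assignments does not exceed ``n_permutations`` they
    are enumerated exhaustively (a warning is logged if fewer exist than
    requested).
    """

    def __init__(
        self,
        fdr: float = 0.01,
        n_permutations: int = 300,
        s0="auto",
        positive_label=None,
        random_state: int = 0,
        direction_labels: tuple[str, str] = ("up", "down"),
        fdr_estimator: str = "mean",
    ):
        self.fdr = fdr
        self.n_permutations = n_permutations
        self.s0 = s0
        self.positive_label = positive_label
        self.random_state = random_state
        self.direction_labels = direction_labels
        self.fdr_estimator = fdr_estimator

    def _false_count(self, counts: np.ndarray) -> float:
        if self.fdr_estimator == "mean":
            return float(np.mean(counts))
        if self.fdr_estimator == "median":
            return float(np.median(counts))
        if self.fdr_estimator == "p90":
            return float(np.percentile(counts, 90))
        raise InputError(f"unknown fdr_estimator: {self.fdr_estimator!r}")

    # -- statistic ---------------------------------------------------------
    @staticmethod
    def _d_stat(X, mask1, s0):
        a, b = X[mask1], X[~mask1]
        n1, n2 = a.shape[0], b.shape[0]
        r = a.mean(axis=0) - b.mean(axis=0)
        ss = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
        return r, s, r / (s + s0)

    @staticmethod
    def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
        """Tusher-style s0: minimise the CV of the MAD of d across s bins."""
        if np.allclose(s, 0):
            return float(np.median(s)) if np.median(s) > 0 else 1e-8
        candidates = np.quantile(s, np.linspace(0.0, 1.0, 21))
        candidates = np.unique(np.maximum(candidates, 0.0))
        edges = np.quantile(s, np.linspace(0.0, 1.0, 11))
        bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 9)
        best, best_cv = None, np.inf
        for alpha in candidates:
            d = r / (s + alpha)
            mads = []
            for j in range(10):
                grp = d[bins == j]
                if grp.size >= 2:
                    mads.append(stats.median_abs_deviation(grp, scale="normal"))
            mads = np.asarray(mads)
            if len(mads) < 2 or np.mean(mads) == 0:
                continue
            cv = np.std(mads) / np.mean(mads)
            if cv < best_cv:
                best, best_cv = alpha, cv
        if best is None or best == 0.0:
            best = float(np.median(s))
        return float(best) if best > 0 else 1e-8

    def _permutation_masks(self, n: int, n1: int, rng: np.random.Generator) -> np.ndarray:
        total = math.comb(n, n1)
        if total <= self.n_permutations:
            if total < self.n_permutations:
                logger.warning(
                    "only %d distinct permutations exist (%d requested); enumerating all",
                    total, self.n_permutations,
                )
            masks = np.zeros((total, n), dtype=bool)
            for i, idx in enumerate(itertools.combinations(range(n), n1)):
                masks[i, list(idx)] = True
            return masks
        masks = np.zeros((self.n_permutations, n), dtype=bool)
        for i in range(self.n_permutations):
            masks[i, rng.choice(n, size=n1, replace=False)] = True
        return masks

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        if self.fdr_estimator not in ("mean", "median", "p90"):
            raise InputError(f"unknown fdr_estimator: {self.fdr_estimator!r}")
        X, y, levels = _validate_two_groups(X, y)
        pos = self.positive_label if self.positive_label is not None else levels[0]
        mask1 = y == pos
        n1, n2 = int(mask1.sum()), int((~mask1).sum())
        if n1 < 2 or n2 < 2:
            raise InputError(f"each group needs >=2 samples (got {n1} and {n2})")
        m = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        r, s, _ = self._d_stat(X, mask1, 0.0)
        if self.s0 == "auto":
            s0 = self._choose_s0(r, s)
        elif self.s0 == "median":
            s0 = float(np.median(s))
        else:
            s0 = float(self.s0)
        if s0 <= 0:
            s0 = 1e-8
        d = r / (s + s0)

        masks = self._permutation_masks(X.shape[0], n1, rng)
        perm_d = np.empty((len(masks), m))
        for i, pm in enumerate(masks):
            _, _, perm_d[i] = self._d_stat(X, pm, s0)
        perm_sorted = np.sort(perm_d, axis=1)
        d_bar = perm_sorted.mean(axis=0)

        order = np.argsort(d, kind="mergesort")
        d_sorted = d[order]
        dev = d_sorted - d_bar

        def band_counts(delta: float):
            up_idx = np.flatnonzero((dev >= delta) & (d_sorted >= 0))
            low_idx = np.flatnonzero((dev <= -delta) & (d_sorted <= 0))
            cut_up = d_sorted[up_idx[0]] if up_idx.size else np.inf
            cut_low = d_sorted[low_idx[-1]] if low_idx.size else -np.inf
            called = (d >= cut_up) | (d <= cut_low)
            false = self._false_count(((perm_d >= cut_up) | (perm_d <= cut_low)).sum(axis=1))
            return called, false, cut_up, cut_low

        # smallest Δ with estimated FDR <= requested level
        grid = np.unique(np.concatenate([[0.0], np.abs(dev)]))
        chosen = None
        for delta in grid:
            called, false, cut_up, cut_low = band_counts(delta)
            n_called = int(called.sum())
            est = false / n_called if n_called else 0.0
            if n_called == 0 or est <= self.fdr:
                chosen = (delta, called, est, cut_up, cut_low)
                break
        if chosen is None:  # pragma: no cover — grid always reaches the empty band
            chosen = (np.inf, np.zeros(m, bool), 0.0, np.inf, -np.inf)
        delta, called, est_fdr, cut_up, cut_low = chosen

        # per-feature q: estimated FDR at a symmetric cut at each |d|
        abs_d = np.abs(d)
        ord_abs = np.argsort(abs_d, kind="mergesort")
        abs_sorted = abs_d[ord_abs]
        # number of observed |d| >= each threshold (ties included)
        n_ge = m - np.searchsorted(abs_sorted, abs_sorted, side="left")
        perm_abs = np.sort(np.abs(perm_d), axis=1)
        false_ge = perm_abs.shape[1] - np.array(
            [np.searchsorted(row, abs_sorted, side="left") for row in perm_abs]
        )
        if self.fdr_estimator == "mean":
            false_est = false_ge.mean(axis=0)
        elif self.fdr_estimator == "median":
            false_est = np.median(false_ge, axis=0)
        else:
            false_est = np.percentile(false_ge, 90, axis=0)
        raw_q = np.minimum(1.0, false_est / np.maximum(n_ge, 1))
        # q(gene) = min estimated FDR over symmetric cuts that still call the
        # gene, i.e. cuts at or below its own |d|; cumulative min over
        # ascending |d| makes q non-increasing as |d| grows
        q_sorted = np.minimum.accumulate(raw_q)
        qvalue = np.empty(m)
        qvalue[ord_abs] = q_sorted

        self.n_features_in_ = m
        self.statistic_ = d
        self.effect_ = r
        self.s_ = s
        self.s0_ = s0
        self.delta_ = float(delta)
        self.cut_up_ = float(cut_up)
        self.cut_low_ = float(cut_low)
        self.estimated_fdr_ = float(est_fdr)
        self.qvalue_ = qvalue
        self.significant_ = called
        up, down = self.direction_labels
        self.direction_ = np.where(r > 0, up, np.where(r < 0, down, "none"))
        self.n_permutations_used_ = len(masks)
        self.expected_order_stats_ = d_bar
        return self


# ---------------------------------------------------------------------------
# matrix-level operations
# ---------------------------------------------------------------------------

def _drop_missing(matrix: pd.DataFrame, what: str) -> pd.DataFrame:
    n0 = len(matrix)
    out = matrix.dropna(axis=0)
    if len(out) < n0:
        logger.info("%s: dropped %d features with missing values", what, n0 - len(out))
    return out


def _results_frame(est, index: pd.Index, pvalues=None) -> pd.DataFrame:
    res = pd.DataFrame(
        {
            "statistic": est.statistic_,
            "p": est.pvalue_ if pvalues is None else pvalues,
            "q": est.qvalue_,
            "direction": est.direction_,
            "effect": est.effect_,
            "significant": est.significant_,
        },
        index=index,
    )
    return res


def dm_ttest(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    fdr: float = 0.05,
    paired: bool = False,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call differentially methylated features (tumour vs normal).

    Per-feature two-sided t test on Beta values (Welch unpaired, or
    paired by patient when ``paired=True``), BH-adjusted across tested
    features.  Direction "hyper" means higher mean methylation in the
    tumour group (Δβ = mean(tumour) − mean(normal) > 0).  If an
    annotation is supplied the probe-level table is collapsed to genes
    by the minimum-p representative.
    """
    sheet = sheet.loc[matrix.columns]
    matrix = _drop_missing(matrix, "dm_ttest")
    X = matrix.to_numpy().T
    y = sheet["group"].to_numpy()
    est = GroupTTest(
        alpha=fdr, paired=paired, positive_label=GROUP_TUMOUR,
        direction_labels=("hyper", "hypo"),
    )
    pairs = None
    if paired:
        check_pairing(sheet)
        pairs = sheet["patient_id"].to_numpy()
    est.fit(X, y, pairs=pairs)
    res = _results_frame(est, matrix.index)
    res.index.name = "probe_id"
    if annotation is not None:
        res = collapse_probes_to_genes(res, annotation, method="min-p")
    return res


def sam_de(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    fdr: float = 0.01,
    n_permutations: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Call differentially expressed genes with the SAM statistic.

    Direction "up" means higher mean log2 expression in tumours; the
    effect column is the log2 fold change (difference of group means on
    the log2 scale).  The ``p`` column is NA — SAM reports permutation
    FDR q values, not per-gene p values.
    """
    sheet = sheet.loc[matrix.columns]
    matrix = _drop_missing(matrix, "sam_de")
    est = SAM(
        fdr=fdr, n_permutations=n_permutations, random_state=seed,
        positive_label=GROUP_TUMOUR, direction_labels=("up", "down"),
    )
    est.fit(matrix.to_numpy().T, sheet["group"].to_numpy())
    res = _results_frame(est, matrix.index, pvalues=np.nan)
    res.index.name = "gene_id"
    res.attrs["s0"] = est.s0_
    res.attrs["delta"] = est.delta_
    res.attrs["n_permutations_used"] = est.n_permutations_used_
    return res


def apply_effect_filters(
    results: pd.DataFrame,
    min_abs_delta_beta: float | None = None,
    min_fold_change: float | None = None,
) -> pd.DataFrame:
    """Filter results by effect size (inclusive thresholds).

    ``min_abs_delta_beta`` keeps |Δβ| ≥ threshold; ``min_fold_change``
    is a linear-scale fold change, keeping |log2FC| ≥ log2(threshold).
    """
    if "effect" not in results.columns:
        raise InputError("results carry no 'effect' column")
    out = results
    if min_abs_delta_beta is not None:
        if min_abs_delta_beta < 0:
            raise InputError(f"min_abs_delta_beta must be >= 0, got {min_abs_delta_beta}")
        out = out[out["effect"].abs() >= min_abs_delta_beta]
    if min_fold_change is not None:
        if min_fold_change < 0:
            raise InputError(f"min_fold_change must be >= 0, got {min_fold_change}")
        if min_fold_change > 0:
            out = out[out["effect"].abs() >= np.log2(min_fold_change)]
    return out
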