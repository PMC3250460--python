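"""Cross-dataset reproducibility scoring of differential gene lists.

Two significant-gene lists from independent datasets are compared by

* POG — the percentage of overlapping genes, directional:
  POG₁₂ = k/L₁ and POG₂₁ = k/L₂ for an overlap of k genes between lists
  of lengths L₁ and L₂;
* direction consistency — the fraction of shared genes whose change
  direction (hyper/hypo or up/down) agrees, tested against an exact
  one-sided binomial null with agreement probability ½ (two directions
  equally likely by chance);
* solely-detected consistency — genes significant in only one list are
  checked for matching effect *sign* in the other dataset's full,
  unthresholded results (a power-loss diagnostic);
* a chi-squared comparison of hypermethylated proportions between two
  gene groups.

Counts are exact integers; percentages are derived at formatting time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .exceptions import InputError

__all__ = [
    "OverlapReport",
    "pog",
    "direction_consistency",
    "binomial_consistency_p",
    "solely_detected_consistency",
    "SolelyDetectedReport",
    "compare_hyper_proportions",
    "compare_results",
]


def binomial_consistency_p(k: int, n_consistent: int) -> tuple[float, float]:
    """Exact one-sided binomial tail P(X >= n_consistent), X ~ Bin(k, ½).

    Returns ``(p, log10_p)``; the log10 value stays informative when the
    tail underflows double precision (e.g. all 3443 of 3443 shared genes
    agreeing gives p = 0.5^3443).
    """
    if not 0 <= n_consistent <= k:
        raise InputError(f"need 0 <= n_consistent <= k, got {n_consistent}/{k}")
    # exact log-space tail sum; scipy's sf/logsf underflow to 0/-inf for
    # tails far below the double-precision floor
    terms = stats.binom.logpmf(np.arange(n_consistent, k + 1), k, 0.5)
    logp = float(logsumexp(terms)) if len(terms) else -np.inf
    logp = min(logp, 0.0)
    return float(np.exp(logp)), float(logp / math.log(10))


@dataclass
class OverlapReport:
    """Reproducibility verdict for a pair of differential gene lists."""

    l1: int
    l2: int
    k: int
    pog12: float | None  # k/L1, None when L1 == 0
    pog21: float | None
    n_consistent: int | None = None
    consistency: float | None = None  # None when k == 0
    binomial_p: float | None = None
    log10_binomial_p: float | None = None
    # solely-detected section (filled by compare_results)
    n_solely_1: int | None = None
    n_solely_1_consistent: int | None = None
    solely_1_consistency: float | None = None
    solely_1_binomial_p: float | None = None
    n_solely_2: int | None = None
    n_solely_2_consistent: int | None = None
    solely_2_consistency: float | None = None
    solely_2_binomial_p: float | None = None

    @classmethod
    def from_counts(
        cls, l1: int, l2: int, k: int, n_consistent: int | None = None
    ) -> "OverlapReport":
        """Build a report from printed counts (POG/consistency arithmetic)."""
        if k > min(l1, l2):
            raise InputError(f"overlap k={k} exceeds a list length ({l1}, {l2})")
        rep = cls(
            l1=l1,
            l2=l2,
            k=k,
            pog12=k / l1 if l1 else None,
            pog21=k / l2 if l2 else None,
        )
        if n_consistent is not None:
            if n_consistent > k:
                raise InputError("n_consistent cannot exceed k")
            rep.n_consistent = n_consistent
            rep.consistency = n_consistent / k if k else None
            if k:
                rep.binomial_p, rep.log10_binomial_p = binomial_consistency_p(k, n_consistent)
        return rep

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _as_direction_series(obj) -> pd.Series:
    if isinstance(obj, pd.DataFrame):
        obj = obj["direction"]
    s = pd.Series(obj)
    if s.index.duplicated().any():
        raise InputError("gene ids within a list must be unique")
    return s


def pog(list1, list2) -> OverlapReport:
    """Overlap report for two significant-gene lists with directions.

    Accepts direction Series (gene → direction) or result DataFrames
    with a ``direction`` column.  POG from an empty list is reported as
    None (not-applicable); k is always computed.
    """
    d1 = _as_direction_series(list1)
    d2 = _as_direction_series(list2)
    shared = d1.index.intersection(d2.index)
    rep = OverlapReport.from_counts(len(d1), len(d2), len(shared))
    if len(shared):
        frac, p, n_cons = direction_consistency(d1.loc[shared], d2.loc[shared])
        rep.n_consistent = n_cons
        rep.consistency = frac
        rep.binomial_p = p
        _, rep.log10_binomial_p = binomial_consistency_p(len(shared), n_cons)
    return rep


def direction_consistency(directions1, directions2) -> tuple[float, float, int]:
    """Fraction of shared genes with equal direction plus exact binomial p.

    Returns ``(consistency, binomial_p, n_consistent)``.  With k = 0 the
    fraction is undefined and reported as NaN; genes lacking a direction
    in either list raise an error.
    """
    d1 = _as_direction_series(directions1)
    d2 = _as_direction_series(directions2)
    if len(d1) == 0:
        return float("nan"), float("nan"), 0
    if not d1.index.equals(d2.index):
        d2 = d2.reindex(d1.index)
    if d2.isna().any() or d1.isna().any() or (d1 == "none").any() or (d2 == "none").any():
        raise InputError("every shared gene needs a direction in both lists")
    n_cons = int((d1.to_numpy() == d2.to_numpy()).sum())
    p, _ = binomial_consistency_p(len(d1), n_cons)
    return n_cons / len(d1), p, n_cons


@dataclass
class SolelyDetectedReport:
    n_solely: int
    n_evaluable: int  # measured with a non-zero effect in the other dataset
    n_excluded: int
    n_consistent: int
    consistency: float | None
    binomial_p: float | None


def solely_detected_consistency(
    solely_results: pd.DataFrame | pd.Series,
    other_full_results: pd.DataFrame,
) -> SolelyDetectedReport:
    """Direction recovery of one-list-only genes in the other dataset.

    ``solely_results`` carries directions of genes significant in A only;
    their effect *sign* in B's full (unthresholded) results is compared.
    Genes absent from B, or with an exactly zero effect there, are
    excluded and counted.
    """
    dirs = _as_direction_series(solely_results)
    if "effect" not in other_full_results.columns:
        raise InputError("other dataset's results carry no 'effect' column")
    eff = other_full_results["effect"].reindex(dirs.index)
    evaluable = eff.notna() & (eff != 0)
    n_excluded = int((~evaluable).sum())
    dirs_e, eff_e = dirs[evaluable], eff[evaluable]
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        return SolelyDetectedReport(len(dirs), 0, n_excluded, 0, None, None)
    positive = dirs_e.isin(["hyper", "up"])
    consistent = (positive & (eff_e > 0)) | (~positive & (eff_e < 0))
    n_cons = int(consistent.sum())
    p, _ = binomial_consistency_p(n_eval, n_cons)
    return SolelyDetectedReport(len(dirs), n_eval, n_excluded, n_cons, n_cons / n_eval, p)


def compare_hyper_proportions(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-squared test comparing two hypermethylated proportions.

    ``counts_a`` and ``counts_b`` are (hypermethylated, total) pairs; the
    2×2 table is tested without continuity correction.  Returns
    ``(statistic, p)``.
    """
    (h1, t1), (h2, t2) = counts_a, counts_b
    if t1 <= 0 or t2 <= 0 or h1 > t1 or h2 > t2 or min(h1, h2) < 0:
        raise InputError(f"invalid counts: {counts_a}, {counts_b}")
    table = np.array([[h1, t1 - h1], [h2, t2 - h2]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InputError("chi-squared test undefined for a zero-margin table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def compare_results(results1: pd.DataFrame, results2: pd.DataFrame) -> OverlapReport:
    """Full reproducibility report for two differential-result tables.

    Significant sets define the POG/consistency section; each side's
    solely-detected genes are checked against the other side's
    unthresholded effect signs.
    """
    for res in (results1, results2):
        if not {"direction", "effect", "significant"}.issubset(res.columns):
            raise InputError("results need direction, effect and significant columns")
    sig1 = results1[results1["significant"]]
    sig2 = results2[results2["significant"]]
    rep = pog(sig1["direction"], sig2["direction"])
    shared = sig1.index.intersection(sig2.index)
    only1 = sig1.drop(index=shared)
    only2 = sig2.drop(index=shared)
    if len(only1):
        s = solely_detected_consistency(only1["direction"], results2)
        rep.n_solely_1 = s.n_solely
        rep.n_solely_1_consistent = s.n_consistent
        rep.solely_1_consistency = s.consistency
        rep.solely_1_binomial_p = s.binomial_p
    if len(only2):
        s = solely_detected_consistency(only2["direction"], results1)
        rep.n_solely_2 = s.n_solely
        rep.n_solely_2_consistent = s.n_consistent
        rep.solely_2_consistency = s.consistency
        rep.solely_2_binomial_p = s.binomial_p
    return rep
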