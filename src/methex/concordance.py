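"""Methylation–expression concordance analysis.

For genes measured on both a methylation and an expression platform,
concordance links promoter hypermethylation to down-regulation and
hypomethylation to up-regulation.  The concordance rate for the hyper
side is the fraction of down-regulated genes among the hypermethylated
genes that are differentially expressed; significance of the excess is
an upper-tail hypergeometric test drawing the hypermethylated-DE genes
from the universe of jointly measured genes, with the universe's
down-regulated genes as successes (symmetrically for hypo/up).

The universe is all genes tested on both platforms (post probe→gene
collapse, before any significance thresholding), so the null reflects
what could have been drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .differential import apply_effect_filters
from .exceptions import InputError

__all__ = ["ConcordanceReport", "concordance_analysis", "concordance_by_threshold_sweep",
           "reproducible_results"]


@dataclass
class ConcordanceReport:
    """Counts, rates and hypergeometric p values for one filter setting."""

    n_universe: int
    n_down: int  # DE-down genes in the universe (after the FC filter)
    n_up: int
    k_hyper_de: int  # hypermethylated genes that are DE
    x_down: int  # down-regulated among them
    rate_hyper: float  # x_down / k_hyper_de, NaN when k == 0
    p_hyper: float  # upper-tail hypergeometric, NaN when k == 0
    k_hypo_de: int
    x_up: int
    rate_hypo: float
    p_hypo: float
    delta_beta_min: float
    fc_min: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _hypergeom_upper(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeom(population N, successes K, draws n)."""
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def reproducible_results(results1: pd.DataFrame, results2: pd.DataFrame) -> pd.DataFrame:
    """Restrict to genes significant in both datasets with equal direction.

    Effects are taken from the first dataset.  Used to base concordance
    on reproducibly detected genes when two datasets are available.
    """
    sig1 = results1[results1["significant"]]
    sig2 = results2[results2["significant"]]
    shared = sig1.index.intersection(sig2.index)
    agree = shared[
        sig1.loc[shared, "direction"].to_numpy() == sig2.loc[shared, "direction"].to_numpy()
    ]
    out = results1.loc[results1.index.intersection(results2.index)].copy()
    out["significant"] = out.index.isin(agree)
    return out


def concordance_analysis(
    dm_results: pd.DataFrame,
    de_results: pd.DataFrame,
    delta_beta_min: float = 0.0,
    fc_min: float = 1.0,
    dm_results2: pd.DataFrame | None = None,
    de_results2: pd.DataFrame | None = None,
) -> ConcordanceReport:
    """Concordance between DM direction and DE direction.

    Parameters
    ----------
    dm_results, de_results :
        Gene-level differential methylation / expression tables with
        ``direction``, ``effect`` and ``significant`` columns.
    delta_beta_min :
        Keep only DM genes with \\|Δβ\\| at or above this value.
    fc_min :
        Keep only DE genes with linear fold change at or above this
        value (1 = no filter).
    dm_results2, de_results2 :
        Optional second datasets; when given, significance is restricted
        to genes reproducibly significant with consistent direction.

    Raises
    ------
    InputError
        If the two gene universes do not intersect or a threshold is
        negative.
    """
    if delta_beta_min < 0 or fc_min < 0:
        raise InputError("effect thresholds must be non-negative")
    if dm_results2 is not None:
        dm_results = reproducible_results(dm_results, dm_results2)
    if de_results2 is not None:
        de_results = reproducible_results(de_results, de_results2)

    universe = dm_results.index.intersection(de_results.index)
    if len(universe) == 0:
        raise InputError("empty universe: no gene measured on both platforms")
    dm = dm_results.loc[universe]
    de = de_results.loc[universe]

    dm_sig = apply_effect_filters(dm[dm["significant"]], min_abs_delta_beta=delta_beta_min)
    de_sig = apply_effect_filters(de[de["significant"]], min_fold_change=fc_min)

    N = len(universe)
    n_down = int((de_sig["direction"] == "down").sum())
    n_up = int((de_sig["direction"] == "up").sum())

    def side(meth_dir: str, expr_dir: str, n_expr: int) -> tuple[int, int, float, float]:
        meth_genes = dm_sig.index[dm_sig["direction"] == meth_dir]
        de_hit = de_sig.loc[de_sig.index.intersection(meth_genes)]
        k = len(de_hit)
        x = int((de_hit["direction"] == expr_dir).sum())
        if k == 0:
            return 0, 0, float("nan"), float("nan")
        return k, x, x / k, _hypergeom_upper(x, N, n_expr, k)

    k_hyper, x_down, rate_hyper, p_hyper = side("hyper", "down", n_down)
    k_hypo, x_up, rate_hypo, p_hypo = side("hypo", "up", n_up)
    return ConcordanceReport(
        n_universe=N,
        n_down=n_down,
        n_up=n_up,
        k_hyper_de=k_hyper,
        x_down=x_down,
        rate_hyper=rate_hyper,
        p_hyper=p_hyper,
        k_hypo_de=k_hypo,
        x_up=x_up,
        rate_hypo=rate_hypo,
        p_hypo=p_hypo,
        delta_beta_min=delta_beta_min,
        fc_min=fc_min,
    )


def concordance_by_threshold_sweep(
    dm_results: pd.DataFrame,
    de_results: pd.DataFrame,
    delta_beta_grid=(0.0, 0.15, 0.3),
    fc_grid=(1.0, 2.0),
    **kwargs,
) -> pd.DataFrame:
    """One concordance report per (Δβ, FC) grid point, as a DataFrame."""
    delta_beta_grid = list(delta_beta_grid)
    fc_grid = list(fc_grid)
    if not delta_beta_grid or not fc_grid:
        raise InputError("threshold grids must be non-empty")
    rows = []
    for db in delta_beta_grid:
        for fc in fc_grid:
            rep = concordance_analysis(
                dm_results, de_results, delta_beta_min=db, fc_min=fc, **kwargs
            )
            rows.append(rep.as_dict())
    return pd.DataFrame(rows)
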