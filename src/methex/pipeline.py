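"""End-to-end orchestration of the analysis stages.

Stage order mirrors the study workflow: batch QC on each methylation
dataset → differential methylation per dataset → cross-dataset
reproducibility (POG, direction consistency, solely-detected recovery)
→ differential expression per dataset → reproducibility → concordance
between the (reproducible) DM and DE calls, swept over Δβ/FC filters →
optional gene-set enrichment of hyper- and hypomethylated genes.

Every stage writes a TSV into the output directory; a manifest records
versions, seeds and thresholds, and ``summary.tsv`` collects counts,
POGs, consistency and concordance rates.  A stage failure aborts with
the stage name; partial outputs are retained.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .batch import batch_purity_clustering, probe_batch_anova
from .concordance import concordance_by_threshold_sweep
from .differential import dm_ttest, sam_de
from .enrichment import enrich
from .exceptions import InputError, MethexError
from .io import (
    read_annotation,
    read_gmt,
    read_matrix,
    read_sample_sheet,
    write_results,
)
from .reproducibility import compare_results

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_analysis"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    The second methylation/expression dataset is optional; with a single
    dataset the reproducibility stages are skipped and concordance uses
    that dataset alone.
    """

    beta1: str
    samplesheet1: str
    outdir: str
    beta2: str | None = None
    samplesheet2: str | None = None
    expr1: str | None = None
    expr_sheet1: str | None = None
    expr2: str | None = None
    expr_sheet2: str | None = None
    annotation: str | None = None
    gmt: str | None = None
    fdr_batch: float = 0.05
    fdr_dm: float = 0.05
    fdr_de: float = 0.01
    delta_beta_grid: tuple[float, ...] = (0.0, 0.15, 0.3)
    fc_grid: tuple[float, ...] = (1.0, 2.0)
    paired: bool = True
    n_permutations: int = 300
    seed: int = 1

    def validate(self) -> None:
        for name in ("fdr_batch", "fdr_dm", "fdr_de"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InputError(f"{name} must lie in (0, 1), got {v}")
        for name in ("beta1", "samplesheet1", "beta2", "samplesheet2",
                     "expr1", "expr_sheet1", "expr2", "expr_sheet2",
                     "annotation", "gmt"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise InputError(f"{name} file not found: {path}")


class _Stage:
    """Context manager that renames any exception with its stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, MethexError):
            raise MethexError(f"stage {self.name!r} failed: {exc}") from exc
        if isinstance(exc, MethexError):
            raise MethexError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the summary rows as a dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {}
    annotation = read_annotation(config.annotation) if config.annotation else None

    with _Stage("batch-qc"):
        beta1 = read_matrix(config.beta1, index_name="probe_id")
        sheet1 = read_sample_sheet(config.samplesheet1)
        if sheet1["batch"].nunique() >= 2:
            qc = probe_batch_anova(beta1, sheet1, fdr=config.fdr_batch)
            qc.table.to_csv(outdir / "batch_qc1.tsv", sep="\t", na_rep="NA")
            summary["batch1_susceptible_fraction"] = qc.susceptible_fraction
            clu = batch_purity_clustering(beta1, sheet1)
            summary["batch1_perfect_split"] = clu.perfect_split
            summary["batch1_cluster_agreement"] = clu.agreement

    with _Stage("dm"):
        dm1 = dm_ttest(beta1, sheet1, fdr=config.fdr_dm, paired=config.paired,
                       annotation=annotation)
        write_results(dm1, outdir / "dm1.tsv")
        summary["n_dm1"] = int(dm1["significant"].sum())
        dm2 = None
        if config.beta2:
            beta2 = read_matrix(config.beta2, index_name="probe_id")
            sheet2 = read_sample_sheet(config.samplesheet2)
            dm2 = dm_ttest(beta2, sheet2, fdr=config.fdr_dm, paired=config.paired,
                           annotation=annotation)
            write_results(dm2, outdir / "dm2.tsv")
            summary["n_dm2"] = int(dm2["significant"].sum())

    if dm2 is not None:
        with _Stage("dm-reproducibility"):
            rep = compare_results(dm1, dm2)
            pd.DataFrame([rep.as_dict()]).to_csv(
                outdir / "dm_overlap.tsv", sep="\t", index=False, na_rep="NA"
            )
            for key in ("l1", "l2", "k", "pog12", "pog21", "consistency", "binomial_p"):
                summary[f"dm_{key}"] = getattr(rep, key)

    de1 = de2 = None
    if config.expr1:
        with _Stage("de"):
            expr1 = read_matrix(config.expr1, index_name="gene_id")
            esheet1 = read_sample_sheet(config.expr_sheet1)
            de1 = sam_de(expr1, esheet1, fdr=config.fdr_de,
                         n_permutations=config.n_permutations, seed=config.seed)
            write_results(de1, outdir / "de1.tsv")
            summary["n_de1"] = int(de1["significant"].sum())
            if config.expr2:
                expr2 = read_matrix(config.expr2, index_name="gene_id")
                esheet2 = read_sample_sheet(config.expr_sheet2)
                de2 = sam_de(expr2, esheet2, fdr=config.fdr_de,
                             n_permutations=config.n_permutations, seed=config.seed + 1)
                write_results(de2, outdir / "de2.tsv")
                summary["n_de2"] = int(de2["significant"].sum())

        if de2 is not None:
            with _Stage("de-reproducibility"):
                rep = compare_results(de1, de2)
                pd.DataFrame([rep.as_dict()]).to_csv(
                    outdir / "de_overlap.tsv", sep="\t", index=False, na_rep="NA"
                )
                for key in ("l1", "l2", "k", "pog12", "pog21", "consistency", "binomial_p"):
                    summary[f"de_{key}"] = getattr(rep, key)

        with _Stage("concordance"):
            sweep = concordance_by_threshold_sweep(
                dm1, de1,
                delta_beta_grid=config.delta_beta_grid,
                fc_grid=config.fc_grid,
                dm_results2=dm2, de_results2=de2,
            )
            sweep.to_csv(outdir / "concordance.tsv", sep="\t", index=False, na_rep="NA")
            base = sweep.iloc[0]
            summary["concordance_rate_hyper"] = base["rate_hyper"]
            summary["concordance_rate_hypo"] = base["rate_hypo"]
            summary["concordance_p_hyper"] = base["p_hyper"]

    if config.gmt:
        with _Stage("enrichment"):
            sets = read_gmt(config.gmt)
            universe = dm1.index
            sig = dm1[dm1["significant"]]
            for side in ("hyper", "hypo"):
                genes = sig.index[sig["direction"] == side]
                if len(genes) == 0:
                    continue
                table = enrich(genes, sets, universe, fdr=0.05)
                table.to_csv(outdir / f"enrichment_{side}.tsv", sep="\t", index=False)
                summary[f"n_enriched_{side}"] = int(table["significant"].sum())

    with _Stage("summary"):
        manifest = {
            "methex_version": __version__,
            **{f"config.{k}": v for k, v in dataclasses.asdict(config).items()},
        }
        with open(outdir / "manifest.txt", "w") as fh:
            for k, v in manifest.items():
                fh.write(f"{k} = {v}\n")
        pd.Series(summary, name="value").rename_axis("metric").to_csv(
            outdir / "summary.tsv", sep="\t", na_rep="NA"
        )
    return summary
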