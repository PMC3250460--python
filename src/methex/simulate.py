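"""Synthetic paired tumour/normal methylation and expression cohorts.

The generator emulates the structure of array-based cancer methylation
studies: probe-level Beta values for pair-matched tumour/normal samples
processed in experimental batches, and companion gene-expression cohorts
whose regulation directions are partially coupled to the methylation
directions (promoter hypermethylation → down-regulation, hypomethylation
→ up-regulation).

Model
-----
Per-probe baseline methylation is drawn from a bimodal distribution
(low ≈ 0.1 and high ≈ 0.8 modes) mimicking CpG-island bimodality.  All
effects — the tumour/normal differential shift, additive per-batch
offsets, and within-group noise — act on the logit(Beta) scale and are
mapped back through the logistic function, so Beta stays inside (0, 1).
The differential shift for a true-DM probe is calibrated so that the
noise-free tumour−normal Beta difference equals ±``delta_beta_effect``
exactly (after clipping near the boundaries).

Expression values are log2-scale with additive Gaussian noise; every
truly differentially methylated gene is differentially expressed, with
direction "down" (for hypermethylated genes) with probability
``concordance_hyper`` and "up" otherwise, and symmetrically for
hypomethylated genes; a background fraction of non-DM genes is
differentially expressed in a random direction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import ConfigError, InputError
from .io import GROUP_NORMAL, GROUP_TUMOUR

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_methylation_cohort",
    "generate_expression_cohort",
    "generate_two_batch_replicates",
    "signals_from_beta",
    "write_truth",
    "read_truth",
]

_BETA_CLIP = (1e-3, 0.999)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a well-powered paired within-batch design: two
    batches of 30 tumour/normal pairs, 2000 genes with one promoter probe
    each, 10% of probes truly differentially methylated with a 0.3 mean
    |Δβ|, strong hyper→down coupling (0.9) and weaker hypo→up coupling
    (0.6), moderate batch offsets and within-group noise.
    """

    n_probes: int = 2000
    n_genes: int = 2000
    probes_per_gene: int = 1
    n_pairs_per_batch: tuple[int, ...] = (30, 30)
    n_batches: int = 2
    frac_dm: float = 0.1
    frac_hyper_among_dm: float = 0.5
    delta_beta_effect: float = 0.3
    batch_sd: float = 0.2
    noise_sd: float = 0.3
    concordance_hyper: float = 0.9
    concordance_hypo: float = 0.6
    frac_de_background: float = 0.1
    lfc_effect: float = 1.5
    seed: int = 0
    # secondary knobs (baseline shape, expression scale)
    baseline_low_mode: float = 0.1
    baseline_high_mode: float = 0.8
    baseline_frac_high: float = 0.5
    baseline_logit_sd: float = 0.5
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 2.0
    expr_noise_sd: float = 0.5
    batch_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.n_pairs_per_batch = tuple(int(n) for n in np.atleast_1d(self.n_pairs_per_batch))
        self.validate()

    def validate(self) -> None:
        for name in ("n_probes", "n_genes", "probes_per_gene", "n_batches"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_probes != self.n_genes * self.probes_per_gene:
            raise ConfigError(
                "n_probes must equal n_genes * probes_per_gene "
                f"({self.n_probes} != {self.n_genes} * {self.probes_per_gene})"
            )
        if len(self.n_pairs_per_batch) != self.n_batches:
            raise ConfigError(
                f"n_pairs_per_batch has {len(self.n_pairs_per_batch)} entries "
                f"but n_batches = {self.n_batches}"
            )
        if any(n <= 0 for n in self.n_pairs_per_batch):
            raise ConfigError("n_pairs_per_batch entries must be positive")
        for name in (
            "frac_dm",
            "frac_hyper_among_dm",
            "concordance_hyper",
            "concordance_hypo",
            "frac_de_background",
            "baseline_frac_high",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("delta_beta_effect", "batch_sd", "noise_sd", "lfc_effect",
                     "baseline_logit_sd", "expr_noise_sd", "expr_baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.batch_offsets is not None and len(self.batch_offsets) != self.n_batches:
            raise ConfigError("batch_offsets length must equal n_batches")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth emitted by the generator.

    Attributes
    ----------
    probes :
        Indexed by probe_id; columns ``gene_id``, ``baseline_beta``,
        ``true_dm`` (bool), ``direction`` ∈ {hyper, hypo, none}.
    genes :
        Indexed by gene_id; columns ``dm_direction`` (the methylation
        direction inherited from the gene's probes), ``true_de`` (bool),
        ``de_direction`` ∈ {up, down, none}, ``log2_fc``.
    batch_offsets :
        Per-batch additive logit-scale offsets, indexed by batch label.
    """

    probes: pd.DataFrame
    genes: pd.DataFrame
    batch_offsets: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _make_probe_truth(config: SimulationConfig, rng: np.random.Generator) -> SimulationTruth:
    """Draw baselines and assign true-DM probes (gene-blockwise)."""
    probe_ids = [f"cg{i:06d}" for i in range(config.n_probes)]
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    probe_gene = np.repeat(np.arange(config.n_genes), config.probes_per_gene)

    high = rng.random(config.n_probes) < config.baseline_frac_high
    mode = np.where(high, config.baseline_high_mode, config.baseline_low_mode)
    base_logit = logit(mode) + rng.normal(0.0, config.baseline_logit_sd, config.n_probes)
    baseline = np.clip(expit(base_logit), *_BETA_CLIP)

    n_dm_probes = round(config.frac_dm * config.n_probes)
    true_dm = np.zeros(config.n_probes, dtype=bool)
    direction = np.full(config.n_probes, "none", dtype=object)
    gene_dm_direction = np.full(config.n_genes, "none", dtype=object)

    if n_dm_probes > 0:
        gene_order = rng.permutation(config.n_genes)
        # mark whole genes' probe blocks until the probe quota is reached
        dm_probe_idx: list[int] = []
        dm_gene_idx: list[int] = []
        for g in gene_order:
            if len(dm_probe_idx) >= n_dm_probes:
                break
            block = np.flatnonzero(probe_gene == g)
            take = block[: n_dm_probes - len(dm_probe_idx)]
            dm_probe_idx.extend(take.tolist())
            dm_gene_idx.append(g)
        dm_probe_idx = np.asarray(dm_probe_idx)
        true_dm[dm_probe_idx] = True
        n_hyper = round(config.frac_hyper_among_dm * len(dm_gene_idx))
        for j, g in enumerate(dm_gene_idx):
            d = "hyper" if j < n_hyper else "hypo"
            gene_dm_direction[g] = d
            direction[(probe_gene == g) & true_dm] = d

    probes = pd.DataFrame(
        {
            "gene_id": [gene_ids[g] for g in probe_gene],
            "baseline_beta": baseline,
            "true_dm": true_dm,
            "direction": direction,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    genes = pd.DataFrame(
        {
            "dm_direction": gene_dm_direction,
            "true_de": False,
            "de_direction": "none",
            "log2_fc": 0.0,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimulationTruth(probes=probes, genes=genes)


def _dm_logit_shift(baseline: np.ndarray, direction: np.ndarray, delta: float) -> np.ndarray:
    """Per-probe logit shift giving a noise-free Beta difference of ±delta."""
    sign = np.where(direction == "hyper", 1.0, np.where(direction == "hypo", -1.0, 0.0))
    target = np.clip(baseline + sign * delta, *_BETA_CLIP)
    shift = logit(target) - logit(baseline)
    return np.where(sign == 0.0, 0.0, shift)


def _draw_batch_offsets(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.batch_offsets is not None:
        return np.asarray(config.batch_offsets, dtype=float)
    return rng.normal(0.0, config.batch_sd, config.n_batches)


def _simulate_batches(
    config: SimulationConfig,
    truth: SimulationTruth,
    offsets: np.ndarray,
    rng: np.random.Generator,
    batches: range | list[int],
    id_prefix: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    base_logit = logit(truth.probes["baseline_beta"].to_numpy())
    shift = _dm_logit_shift(
        truth.probes["baseline_beta"].to_numpy(),
        truth.probes["direction"].to_numpy(),
        config.delta_beta_effect,
    )
    columns, rows, data = [], [], []
    for b in batches:
        for p in range(config.n_pairs_per_batch[b]):
            patient = f"{id_prefix}B{b}P{p:03d}"
            for group, suffix in ((GROUP_TUMOUR, "T"), (GROUP_NORMAL, "N")):
                mu = base_logit + offsets[b] + (shift if group == GROUP_TUMOUR else 0.0)
                noise = rng.normal(0.0, config.noise_sd, config.n_probes) if config.noise_sd > 0 else 0.0
                data.append(expit(mu + noise))
                columns.append(f"{patient}{suffix}")
                rows.append((f"{patient}{suffix}", group, f"batch{b}", f"lab{b}", patient))
    beta = pd.DataFrame(
        np.column_stack(data), index=truth.probes.index, columns=columns
    )
    sheet = pd.DataFrame(
        rows, columns=["sample_id", "group", "batch", "laboratory", "patient_id"]
    ).set_index("sample_id")
    return beta, sheet


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_methylation_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate a paired tumour/normal methylation cohort with batch structure.

    Returns ``(beta_matrix, sample_sheet, truth)``.  Each patient
    contributes one tumour and one normal sample in the same batch; all
    samples of a batch share that batch's additive logit-scale offset.
    Reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    truth = _make_probe_truth(config, rng)
    offsets = _draw_batch_offsets(config, rng)
    truth.batch_offsets = pd.Series(
        offsets, index=[f"batch{b}" for b in range(config.n_batches)], name="offset"
    )
    beta, sheet = _simulate_batches(config, truth, offsets, rng, range(config.n_batches))
    return beta, sheet, truth


def generate_expression_cohort(
    config: SimulationConfig, truth: SimulationTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a tumour/normal expression cohort coupled to methylation truth.

    Fills the per-gene DE labels of ``truth`` in place and returns
    ``(expression_matrix, sample_sheet)``.  Expression is log2-scale,
    genes × samples.
    """
    config.validate()
    if len(truth.genes) != config.n_genes:
        raise InputError(
            f"gene universe mismatch: truth has {len(truth.genes)} genes, "
            f"config says {config.n_genes}"
        )
    rng = np.random.default_rng([config.seed, 1])
    genes = truth.genes
    n_genes = len(genes)

    de_direction = np.full(n_genes, "none", dtype=object)
    dm_dir = genes["dm_direction"].to_numpy()
    u = rng.random(n_genes)
    hyper = dm_dir == "hyper"
    hypo = dm_dir == "hypo"
    de_direction[hyper] = np.where(u[hyper] < config.concordance_hyper, "down", "up")
    de_direction[hypo] = np.where(u[hypo] < config.concordance_hypo, "up", "down")
    background = (~hyper) & (~hypo) & (rng.random(n_genes) < config.frac_de_background)
    de_direction[background] = np.where(rng.random(n_genes)[background] < 0.5, "up", "down")
    if config.lfc_effect == 0:
        de_direction[:] = "none"
    true_de = de_direction != "none"
    lfc = np.where(de_direction == "up", config.lfc_effect,
                   np.where(de_direction == "down", -config.lfc_effect, 0.0))
    genes["true_de"] = true_de
    genes["de_direction"] = de_direction
    genes["log2_fc"] = lfc

    n_pairs = sum(config.n_pairs_per_batch)
    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, n_genes)
    columns, rows, data = [], [], []
    for p in range(n_pairs):
        patient = f"EP{p:03d}"
        for group, suffix in ((GROUP_TUMOUR, "T"), (GROUP_NORMAL, "N")):
            mu = baseline + (lfc if group == GROUP_TUMOUR else 0.0)
            noise = rng.normal(0.0, config.expr_noise_sd, n_genes) if config.expr_noise_sd > 0 else 0.0
            data.append(mu + noise)
            columns.append(f"{patient}{suffix}")
            rows.append((f"{patient}{suffix}", group, "expr0", "expr_lab", patient))
    expr = pd.DataFrame(np.column_stack(data), index=genes.index, columns=columns)
    sheet = pd.DataFrame(
        rows, columns=["sample_id", "group", "batch", "laboratory", "patient_id"]
    ).set_index("sample_id")
    return expr, sheet


def generate_two_batch_replicates(
    config: SimulationConfig,
) -> tuple[
    tuple[pd.DataFrame, pd.DataFrame],
    tuple[pd.DataFrame, pd.DataFrame],
    SimulationTruth,
]:
    """Generate two independent paired cohorts sharing one ground truth.

    Emulates treating a study's two largest experimental batches as
    independent datasets: both draw from the same baselines and true-DM
    assignments, with independent batch offsets and noise.  Dataset *i*
    uses ``n_pairs_per_batch[i]`` tumour/normal pairs.
    """
    config.validate()
    if config.n_batches < 2:
        raise ConfigError("generate_two_batch_replicates requires n_batches >= 2")
    rng = np.random.default_rng([config.seed, 2])
    truth = _make_probe_truth(config, rng)
    offsets = _draw_batch_offsets(config, rng)
    truth.batch_offsets = pd.Series(
        offsets[:2], index=["batch0", "batch1"], name="offset"
    )
    d1 = _simulate_batches(config, truth, offsets, rng, [0], id_prefix="D1")
    d2 = _simulate_batches(config, truth, offsets, rng, [1], id_prefix="D2")
    return d1, d2, truth


def signals_from_beta(
    beta: pd.DataFrame, total_intensity: float = 10_000.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit (M, U) signal pairs consistent with a target Beta matrix.

    Uses a fixed total ``M + U + 100 = total_intensity`` so that
    ``M / (U + M + 100)`` recovers the input exactly.  Requires
    ``beta <= 1 - 100/total_intensity`` so that U stays non-negative.
    """
    b = beta.to_numpy(dtype=float)
    if (b < 0).any() or (b > 1 - 100.0 / total_intensity).any():
        raise InputError(
            "beta values incompatible with non-negative signals at "
            f"total intensity {total_intensity}"
        )
    m = b * total_intensity
    u = total_intensity - 100.0 - m
    M = pd.DataFrame(m, index=beta.index, columns=beta.columns)
    U = pd.DataFrame(u, index=beta.index, columns=beta.columns)
    return M, U


# ---------------------------------------------------------------------------
# truth persistence
# ---------------------------------------------------------------------------

def write_truth(truth: SimulationTruth, outdir) -> None:
    """Write truth tables (probes, genes, batch offsets) as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.probes.to_csv(outdir / "truth_probes.tsv", sep="\t")
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    truth.batch_offsets.rename_axis("batch").to_csv(outdir / "truth_batches.tsv", sep="\t")


def read_truth(outdir) -> SimulationTruth:
    outdir = Path(outdir)
    probes = pd.read_csv(outdir / "truth_probes.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(outdir / "truth_genes.tsv", sep="\t", index_col=0)
    probes["true_dm"] = probes["true_dm"].astype(bool)
    genes["true_de"] = genes["true_de"].astype(bool)
    offs = pd.read_csv(outdir / "truth_batches.tsv", sep="\t", index_col=0)["offset"]
    return SimulationTruth(probes=probes, genes=genes, batch_offsets=offs)
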