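"""Tabular input/output, Beta-value computation and probe→gene collapsing.

All matrices are TSV files with a header row of sample identifiers and a
first column of feature (probe or gene) identifiers.  Missing values are
encoded ``NA``.  Gene sets use the standard GMT format (set name,
description, then member genes, tab-separated).

The in-memory containers are plain :class:`pandas.DataFrame` objects:

* methylation / expression matrix — features × samples, float values;
* sample sheet — indexed by ``sample_id`` with columns ``group``,
  ``batch``, ``laboratory`` (optional) and ``patient_id`` (optional);
* probe annotation — columns ``probe_id`` and ``gene_id``;
* differential results — indexed by feature with columns ``statistic``,
  ``p``, ``q``, ``direction``, ``effect``, ``significant``.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError

logger = logging.getLogger(__name__)

GROUP_TUMOUR = "tumour"
GROUP_NORMAL = "normal"
VALID_GROUPS = (GROUP_TUMOUR, GROUP_NORMAL)

#: Illumina's variance-stabilising offset in the Beta denominator.
BETA_OFFSET = 100.0

SAMPLESHEET_REQUIRED = ("sample_id", "group", "batch")


# ---------------------------------------------------------------------------
# Beta computation
# ---------------------------------------------------------------------------

def compute_beta(methylated: pd.DataFrame, unmethylated: pd.DataFrame) -> pd.DataFrame:
    """Compute Beta values from methylated/unmethylated signal intensities.

    Beta = M / (U + M + 100), the standard estimator for HumanMethylation
    arrays; the +100 offset stabilises low-intensity probes and bounds the
    result in [0, 1).

    Parameters
    ----------
    methylated, unmethylated :
        Probe × sample intensity matrices with identical index/columns.

    Returns
    -------
    pandas.DataFrame
        Beta values, same shape and labels as the inputs.

    Raises
    ------
    InputError
        If the two matrices are not aligned, or any signal is negative or
        non-finite (the message names the offending probe and sample).
    """
    if not methylated.index.equals(unmethylated.index) or not methylated.columns.equals(
        unmethylated.columns
    ):
        raise InputError("methylated and unmethylated matrices are not aligned")
    for name, mat in (("M", methylated), ("U", unmethylated)):
        values = mat.to_numpy(dtype=float)
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputError(
                f"invalid {name} signal at probe {mat.index[i]!r}, "
                f"sample {mat.columns[j]!r}: {values[i, j]!r}"
            )
    m = methylated.to_numpy(dtype=float)
    u = unmethylated.to_numpy(dtype=float)
    beta = m / (u + m + BETA_OFFSET)
    return pd.DataFrame(beta, index=methylated.index, columns=methylated.columns)


# ---------------------------------------------------------------------------
# Probe → gene collapsing
# ---------------------------------------------------------------------------

def collapse_probes_to_genes(
    obj: pd.DataFrame,
    annotation: pd.DataFrame,
    method: str = "min-p",
) -> pd.DataFrame:
    """Collapse probe-level rows to gene level using an annotation table.

    For differential results (``method="min-p"``) each gene is represented
    by its most significant probe; ties are broken by larger ``|effect|``,
    then lexicographically smaller probe id, so collapsing is fully
    deterministic.  A boolean ``discordant_probes`` column flags genes
    whose mapped probes disagree in direction.  For value matrices
    (``method="mean"``) gene rows are probe means.

    Unmapped probes are dropped and their count logged.

    Raises
    ------
    InputError
        If no probe of ``obj`` appears in the annotation.
    """
    if not {"probe_id", "gene_id"}.issubset(annotation.columns):
        raise InputError("annotation requires columns 'probe_id' and 'gene_id'")
    if annotation["probe_id"].duplicated().any():
        dup = annotation.loc[annotation["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise InputError(f"duplicate probe_id in annotation: {dup!r}")
    mapping = annotation.set_index("probe_id")["gene_id"]
    mapped = obj.index.intersection(mapping.index)
    n_dropped = len(obj.index) - len(mapped)
    if len(mapped) == 0:
        raise InputError("no probe of the input maps to a gene in the annotation")
    if n_dropped:
        logger.info("collapse: dropped %d unmapped probes", n_dropped)
    sub = obj.loc[mapped]
    genes = mapping.loc[mapped]

    if method == "mean":
        out = sub.groupby(genes).mean()
        out.index.name = "gene_id"
        return out
    if method != "min-p":
        raise InputError(f"unknown collapse method: {method!r}")

    if "p" not in sub.columns:
        raise InputError("min-p collapsing requires a 'p' column")
    tab = sub.copy()
    tab["gene_id"] = genes.to_numpy()
    tab["probe_id"] = tab.index.to_numpy()
    tab = tab.reset_index(drop=True)
    effect = tab["effect"] if "effect" in tab.columns else pd.Series(0.0, index=tab.index)
    tab["_abs_effect"] = effect.abs()
    # min-p representative; ties → larger |effect|, then lexicographic probe id
    tab = tab.sort_values(
        ["gene_id", "p", "_abs_effect", "probe_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    rep = tab.drop_duplicates("gene_id", keep="first").set_index("gene_id")
    if "direction" in tab.columns:
        def _discordant(dirs: pd.Series) -> bool:
            d = set(dirs.dropna()) - {"none", ""}
            return len(d) > 1

        disc = tab.groupby("gene_id")["direction"].apply(_discordant)
        rep["discordant_probes"] = disc
    rep = rep.drop(columns=["_abs_effect"])
    rep.index.name = "gene_id"
    return rep


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path, index_name: str = "feature_id") -> None:
    """Write a feature × sample matrix as TSV (missing values as ``NA``)."""
    out = matrix.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_matrix(path, index_name: str | None = None) -> pd.DataFrame:
    """Read a feature × sample TSV matrix; validates unique identifiers."""
    mat = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    if mat.index.duplicated().any():
        dup = mat.index[mat.index.duplicated()][0]
        raise InputError(f"duplicate feature id in {path}: {dup!r}")
    if mat.columns.duplicated().any():
        raise InputError(f"duplicate sample id in {path}")
    if index_name:
        mat.index.name = index_name
    return mat.astype(float)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet.

    Requires unique ``sample_id``, and ``group``/``batch`` for every
    sample; ``laboratory`` and ``patient_id`` are optional columns.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"])
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate (and index by sample_id) a sample sheet DataFrame."""
    sheet = sheet.reset_index() if sheet.index.name == "sample_id" else sheet.copy()
    missing = [c for c in SAMPLESHEET_REQUIRED if c not in sheet.columns]
    if missing:
        raise InputError(f"sample sheet missing required column(s): {', '.join(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise InputError(f"duplicate sample_id: {dup!r}")
    if sheet["group"].isna().any() or sheet["batch"].isna().any():
        raise InputError("every sample requires a group and a batch label")
    bad = set(sheet["group"]) - set(VALID_GROUPS)
    if bad:
        raise InputError(f"unknown group label(s): {sorted(bad)}; expected {VALID_GROUPS}")
    out = sheet.set_index("sample_id")
    if "laboratory" not in out.columns:
        out["laboratory"] = out["batch"]
    if "patient_id" not in out.columns:
        out["patient_id"] = pd.NA
    return out


def check_pairing(sheet: pd.DataFrame) -> pd.DataFrame:
    """Return tumour/normal sample pairs ordered by patient.

    Each patient_id must occur exactly once per group.  Returns a frame
    with columns ``patient_id``, ``tumour``, ``normal``.
    """
    if sheet["patient_id"].isna().any():
        raise InputError("paired analysis requires patient_id for every sample")
    pairs = {}
    for group in VALID_GROUPS:
        sub = sheet[sheet["group"] == group]
        if sub["patient_id"].duplicated().any():
            pid = sub.loc[sub["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise InputError(f"patient {pid!r} appears more than once in group {group!r}")
        pairs[group] = pd.Series(sub.index.to_numpy(), index=sub["patient_id"])
    common = pairs[GROUP_TUMOUR].index.intersection(pairs[GROUP_NORMAL].index)
    if len(common) == 0:
        raise InputError("no complete tumour/normal pairs found")
    return pd.DataFrame(
        {
            "patient_id": common,
            "tumour": pairs[GROUP_TUMOUR].loc[common].to_numpy(),
            "normal": pairs[GROUP_NORMAL].loc[common].to_numpy(),
        }
    )


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["probe_id", "gene_id"]].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"}.issubset(ann.columns):
        raise InputError(f"annotation {path} requires columns probe_id and gene_id")
    if ann["probe_id"].duplicated().any():
        dup = ann.loc[ann["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise InputError(f"duplicate probe_id in annotation {path}: {dup!r}")
    return ann


def write_gmt(gene_sets: Mapping[str, set], path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(map(str, members))]) + "\n")


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file into ``{set_name: {gene, ...}}``."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"malformed GMT line {lineno} in {path}: need name, "
                                 "description and at least one member")
            name = fields[0]
            if name in sets:
                raise InputError(f"duplicate gene-set name in {path}: {name!r}")
            sets[name] = set(fields[2:])
    return sets


def write_results(results: pd.DataFrame, path) -> None:
    """Write a differential-result table as TSV."""
    out = results.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    res = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    res.index = res.index.astype(str)
    if res.index.duplicated().any():
        raise InputError(f"duplicate feature id in results {path}")
    if "significant" in res.columns:
        res["significant"] = res["significant"].astype(bool)
    return res


def write_config(config: Mapping[str, object], path) -> None:
    """Write a flat ``key = value`` configuration file."""
    with open(path, "w") as fh:
        for key, value in config.items():
            if isinstance(value, (list, tuple)):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key} = {value}\n")


def read_config(path) -> dict[str, str]:
    """Read a flat ``key = value`` configuration file (values as strings)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"malformed config line {lineno} in {path}: {line!r}")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
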