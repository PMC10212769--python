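"""Tumor-microenvironment scoring from bulk and micro-region expression.

All expression statistics operate on log2(TPM + 1) values; matrices are
genes x samples DataFrames. Cell-type abundances follow the
signature-mean convention (mean log2 expression over the annotated genes
of a cell type), the inflammation score is the same mean over an
inflammation panel, optionally percentile-ranked against a reference
cohort. Tumor-versus-stroma contrasts use the two-group z-score

    z_i = (<A_i> - <B_i>) / sqrt(var(A_i) + var(B_i))

with sample variances (ddof=1) per group.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def log2_matrix(expr: pd.DataFrame, scale: str = "linear") -> pd.DataFrame:
    """Return log2(x+1)-scale values; a matrix already on log scale passes through."""
    if scale == "log2":
        return expr
    if scale == "linear":
        if (expr.to_numpy() < 0).any():
            raise ValueError("negative values in a linear-scale expression matrix")
        return np.log2(expr + 1.0)
    raise ValueError(f"unknown scale {scale!r}")


def inflammation_score(
    expr: pd.DataFrame,
    panel_genes: Sequence[str],
    scale: str = "linear",
    reference: pd.DataFrame | None = None,
    aggregate=None,
) -> pd.Series:
    """Inflammation score per sample: mean log2(x+1) over the panel genes.

    ``aggregate`` may replace the mean with any callable mapping a
    genes-x-samples frame to a per-sample Series (hook for alternative
    signature aggregations). With ``reference`` given, scores are
    reported as percentile ranks (in (0, 1]) against the reference
    cohort's score distribution.
    """
    present = [g for g in panel_genes if g in expr.index]
    if not present:
        missing = sorted(set(panel_genes))
        raise ValueError(f"no panel genes present in the matrix; missing: {missing}")
    log = log2_matrix(expr.loc[present], scale)
    agg = aggregate or (lambda m: m.mean(axis=0))
    scores = agg(log)
    if reference is not None:
        ref_scores = inflammation_score(reference, panel_genes, scale=scale, aggregate=aggregate)
        ref = np.sort(ref_scores.to_numpy())
        scores = scores.map(lambda s: float(np.searchsorted(ref, s, side="right")) / len(ref))
    return scores


def cell_type_abundance(
    expr: pd.DataFrame, panels: Mapping[str, Sequence[str]], scale: str = "linear"
) -> pd.DataFrame:
    """Cell-type abundance per (sample, cell type).

    Abundance is the mean of log2(x+1) expression over the measured genes
    of each cell type's panel; cell types with no measured gene are
    dropped with a warning. Returns samples x cell types.
    """
    log = log2_matrix(expr, scale)
    cols = {}
    for cell_type, genes in panels.items():
        present = [g for g in genes if g in log.index]
        if not present:
            logger.warning("cell type %s has no measured genes; dropped", cell_type)
            continue
        cols[cell_type] = log.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


def group_zscore(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    scale: str = "linear",
) -> pd.Series:
    """Per-gene z = (mean_A - mean_B)/sqrt(var_A + var_B) on log2 values.

    Sample variances use ddof=1. Genes constant within both groups give
    z = 0 when the means agree and signed infinity otherwise (flagged in
    the log); downstream selections treat infinities as extreme z.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    log = log2_matrix(expr, scale)
    a, b = log[list(group_a)], log[list(group_b)]
    diff = a.mean(axis=1) - b.mean(axis=1)
    denom = np.sqrt(a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / denom
    degenerate = denom == 0
    z[degenerate & (diff == 0)] = 0.0
    inf_mask = degenerate & (diff != 0)
    if inf_mask.any():
        logger.warning("%d genes with zero variance but unequal means (z = +/-inf)", inf_mask.sum())
        z[inf_mask] = np.sign(diff[inf_mask]) * np.inf
    return z


def quartile_gene_split(z: pd.Series) -> tuple[list[str], list[str]]:
    """Split genes into upper-quartile (z >= 75th pct) and lower-quartile
    (z <= 25th pct) sets — tumor- and stroma-associated respectively.

    Percentiles use linear interpolation; boundary membership is
    inclusive, so exact ties at a quartile are kept. With fewer than 4
    genes the quartiles are not meaningful and an error is raised. The
    two sets are disjoint except in the fully degenerate all-equal case,
    which is resolved by returning two empty sets.
    """
    finite = z[np.isfinite(z)]
    if len(z) < 4:
        raise ValueError("need >= 4 genes for a quartile split")
    lo, hi = np.percentile(finite.to_numpy(), [25.0, 75.0])
    if lo == hi:  # all-equal degenerate: nothing distinguishes the tails
        return [], []
    upper = list(z.index[(z >= hi)])
    lower = list(z.index[(z <= lo)])
    return upper, lower


def correlate_abundance_with_genes(
    expr: pd.DataFrame,
    abundance: pd.DataFrame,
    samples: Sequence[str] | None = None,
    scale: str = "linear",
) -> pd.DataFrame:
    """Pearson r between each gene's expression and each cell-type
    abundance across a group of micro-regions.

    Returns genes x cell types. Pairs are pairwise-complete; a
    zero-variance gene (or cell type) yields NaN, recorded as missing.
    """
    cols = list(samples) if samples is not None else list(expr.columns)
    if len(cols) < 3:
        raise ValueError("need >= 3 samples for correlation")
    log = log2_matrix(expr[cols], scale)
    ab = abundance.loc[cols]
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for ct in ab.columns:
            out[ct] = log.T.corrwith(ab[ct])
    return pd.DataFrame(out)


def summed_sampling_score(
    mean_scores: pd.Series,
    correlations: pd.DataFrame,
    r_threshold: float = 0.5,
) -> pd.Series:
    """S_c: per cell type, the sum of within-group mean presentation
    scores of all genes correlating with its abundance above r_threshold.

    ``mean_scores`` maps gene -> mean sampling score over the group's
    samples (genes never presented count 0); ``correlations`` is the
    genes x cell types output of :func:`correlate_abundance_with_genes`.
    Strictly greater-than comparison; no qualifying genes gives S_c = 0.
    """
    out = {}
    for ct in correlations.columns:
        genes = correlations.index[correlations[ct] > r_threshold]
        out[ct] = float(mean_scores.reindex(genes).fillna(0.0).sum())
    return pd.Series(out, name="S_c")


def micro_macro_correlation_variance(
    micro_expr: pd.DataFrame,
    macro_expr: pd.DataFrame,
    micro_patient: Mapping[str, str],
    macro_patient: Mapping[str, str],
    micro_subset: Sequence[str] | None = None,
    scale: str = "linear",
) -> pd.Series:
    """Per patient, the variance of micro-vs-macro expression correlations.

    For every (micro-region, macro-region) pair of one patient, Pearson r
    is computed over the shared genes (log2 scale); per micro-region the
    variance (ddof=1) of r across that patient's macro-regions is taken,
    and these variances are averaged over the patient's micro-regions.
    ``micro_subset`` optionally restricts to e.g. tumor micro-regions.
    Patients with < 2 macro-regions are dropped.
    """
    shared = micro_expr.index.intersection(macro_expr.index)
    if shared.empty:
        raise ValueError("no shared genes between micro and macro matrices")
    mi = log2_matrix(micro_expr.loc[shared], scale)
    ma = log2_matrix(macro_expr.loc[shared], scale)
    out = {}
    for patient in sorted(set(macro_patient.values())):
        macros = [s for s in ma.columns if macro_patient.get(s) == patient]
        micros = [
            s for s in mi.columns
            if micro_patient.get(s) == patient
            and (micro_subset is None or s in set(micro_subset))
        ]
        if len(macros) < 2 or not micros:
            logger.warning("patient %s dropped (needs >=2 macro-regions and >=1 micro-region)", patient)
            continue
        variances = []
        for m in micros:
            rs = [mi[m].corr(ma[M]) for M in macros]
            variances.append(float(np.var(rs, ddof=1)))
        out[patient] = float(np.mean(variances))
    return pd.Series(out, name="correlation_variance")


def pca_fov(expr: pd.DataFrame | np.ndarray, center: bool = True) -> np.ndarray:
    """Fraction of variance FOV_i = d_i^2 / sum_j d_j^2 from the singular
    values of the (column-centered) matrix."""
    x = np.asarray(expr, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite values")
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if not x.any():
        raise ValueError("all-zero (or constant) matrix has no variance to explain")
    d = np.linalg.svd(x, compute_uv=False)
    return d**2 / np.sum(d**2)
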