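"""Tumor-associated-antigen selection and HLA-I presentation efficiency.

A TAA is a gene expressed above a TPM threshold in at least one tumor
macro-region while staying at or below the threshold in every adjacent
nonmalignant macro-region and in every normal tissue of a GTEx-style
reference (90th-percentile TPM per tissue; testis exempt by default,
admitting cancer/testis antigens).

For an expressed TAA i in a macro-region, the presentation efficiency

    P_eff(i) = P_i / (E_i * (1 - 1/(E_HLA + eps)))

relates its sampling density P_i to its expression E_i, normalized by
the mean tumor micro-region expression of HLA-A/B/C (E_HLA); eps is the
platform detection limit, the 0.1th percentile of detected values.
Expressed TAAs that are never presented (P_i = 0) enter the macro-region
mean <P_eff> with value 0.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HLA_I_GENES = ("HLA-A", "HLA-B", "HLA-C")


def select_taas(
    tumor_tpm: pd.DataFrame,
    healthy_tpm: pd.DataFrame,
    gtex_tpm: pd.DataFrame,
    threshold: float = 1.0,
    testis_exempt: bool = True,
    strict_healthy: bool = False,
) -> list[str]:
    """Genes passing the three-way tumor/healthy/GTEx expression filter.

    Retained iff max tumor TPM > threshold AND max healthy TPM <=
    threshold AND max GTEx 90th-percentile TPM (testis excluded when
    exempt) <= threshold. ``strict_healthy`` switches the healthy/GTEx
    comparisons to strict ``<`` (the alternative published reading).
    Genes absent from the GTEx table are dropped with a warning.
    """
    below = (lambda v: v < threshold) if strict_healthy else (lambda v: v <= threshold)
    gtex = gtex_tpm
    if testis_exempt:
        testis_cols = [c for c in gtex.columns if "testis" in c.lower()]
        gtex = gtex.drop(columns=testis_cols)
    out = []
    for gene in tumor_tpm.index:
        if gene not in gtex_tpm.index:
            logger.warning("gene %s missing from GTEx table; dropped", gene)
            continue
        tumor_ok = tumor_tpm.loc[gene].max() > threshold
        healthy_ok = gene not in healthy_tpm.index or below(healthy_tpm.loc[gene].max())
        gtex_ok = gtex.shape[1] == 0 or below(gtex.loc[gene].max())
        if tumor_ok and healthy_ok and gtex_ok:
            out.append(gene)
    return out


def classify_taa_presentation(
    taas: Sequence[str],
    peptide_hits: pd.DataFrame,
) -> pd.DataFrame:
    """Presented/nonpresented flag per (TAA gene, macro-region).

    ``peptide_hits`` is a table of HLA-I peptide detections with columns
    ``sample_id`` and ``gene`` (one row per detected peptide-to-gene
    mapping). A gene is presented in a macro-region iff at least one of
    its HLA-I peptides was detected there. Returns genes x macro-regions
    boolean frame covering every region appearing in the table.
    """
    regions = sorted(peptide_hits["sample_id"].unique())
    flags = pd.DataFrame(False, index=list(taas), columns=regions)
    detected = peptide_hits[peptide_hits["gene"].isin(set(taas))]
    for _, row in detected.iterrows():
        flags.loc[row["gene"], row["sample_id"]] = True
    return flags


def detection_limit(
    micro_expr: pd.DataFrame, percentile: float = 0.1, exclude_zeros: bool = True
) -> float:
    """eps: the 0.1th percentile of detected values in the micro-region
    matrix. "Detected" excludes exact zeros by default."""
    values = micro_expr.to_numpy().ravel()
    if exclude_zeros:
        values = values[values > 0]
    if values.size == 0:
        raise ValueError("no detected values to take a percentile of")
    return float(np.percentile(values, percentile))


def presentation_efficiency(
    sampling_score: float | np.ndarray | pd.Series,
    expression: float | np.ndarray | pd.Series,
    e_hla: float,
    epsilon: float,
) -> float | np.ndarray | pd.Series:
    """P_eff = P_i / (E_i * (1 - 1/(E_HLA + eps))).

    Requires E_i > 0 (only expressed TAAs are scored) and E_HLA + eps > 1
    (otherwise the normalization factor is zero or negative).
    """
    if e_hla + epsilon <= 1.0:
        raise ValueError(
            f"E_HLA + epsilon = {e_hla + epsilon} must exceed 1 for a positive denominator"
        )
    e = np.asarray(expression, dtype=float)
    if (e <= 0).any():
        raise ValueError("presentation efficiency requires expression > 0")
    result = np.asarray(sampling_score, dtype=float) / (e * (1.0 - 1.0 / (e_hla + epsilon)))
    if isinstance(expression, pd.Series):
        return pd.Series(result, index=expression.index, name="P_eff")
    if np.isscalar(sampling_score) and np.isscalar(expression):
        return float(result)
    return result


def mean_presentation_efficiency(
    tumor_tpm: pd.DataFrame,
    sampling_scores: pd.DataFrame,
    taas: Sequence[str],
    e_hla: float,
    epsilon: float,
    threshold: float = 1.0,
) -> pd.Series:
    """<P_eff> per macro-region: mean P_eff over its expressed TAAs.

    ``sampling_scores`` is the tidy (sample_id, gene, D) table; a TAA
    expressed (> threshold TPM) in a region but absent from its
    immunopeptidome contributes P_eff = 0 and still counts in N.
    """
    d_wide = (
        sampling_scores.pivot_table(index="gene", columns="sample_id", values="D", aggfunc="max")
        if len(sampling_scores)
        else pd.DataFrame()
    )
    out = {}
    for region in tumor_tpm.columns:
        expr = tumor_tpm.loc[[g for g in taas if g in tumor_tpm.index], region]
        expressed = expr[expr > threshold]
        if expressed.empty:
            out[region] = np.nan
            continue
        if region in getattr(d_wide, "columns", []):
            p = d_wide[region].reindex(expressed.index).fillna(0.0)
        else:
            p = pd.Series(0.0, index=expressed.index)
        out[region] = float(presentation_efficiency(p, expressed, e_hla, epsilon).mean())
    return pd.Series(out, name="mean_P_eff")
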