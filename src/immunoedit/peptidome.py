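"""Peptide-to-protein mapping and HLA sampling-density scoring.

The sampling density D of a protein measures how densely its sequence is
covered by HLA-presented peptides observed by mass spectrometry:

    D = K / (L - 8)   for HLA class I
    D = K / (L - 14)  for HLA class II

with L the protein length and K a weighted count over the distinct
observed peptides mapped to the protein. Each peptide x contributes a
weight P(x|N) that depends on N, the number of proteome entries sharing
its sequence, with a-priori parameter q (default 0.2):

    literal mode:     P(x|N) = 1 + (1 - q)^N
    saturating mode:  P(x|N) = 1 - (1 - q)^N

The literal form is the published one; the saturating form (which keeps
weights below 1 and down-weights widely shared peptides) is offered as a
documented alternative because the literal form rewards sharing. Neither
is asserted to be the intended formula; "literal" is the default.

Marker panels for immune cell types are the genes whose sampling score in
a reference immune-cell dataset exceeds the 99th (HLA-I) or 80th (HLA-II)
percentile of the all-gene score distribution; a sample's marker
presentation level is the mean sampling density over the panel genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: valid residues for peptide sequences
PEPTIDE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: HLA-class-specific peptide length ranges (inclusive)
LENGTH_RANGE = {"I": (8, 15), "II": (8, 25)}

#: denominator offset of the sampling density per HLA class
_DENOM_OFFSET = {"I": 8, "II": 14}

#: percentile of the all-gene score distribution used for marker panels
MARKER_PERCENTILE = {"I": 99.0, "II": 80.0}

#: predicted binding rank (%) at or below which a peptide is a binder
BINDER_RANK_THRESHOLD = 2.0


@dataclass
class MarkerPanel:
    """Genes whose presentation marks one immune cell type."""

    cell_type: str
    gene_ids: frozenset[str]
    hla_class: str
    percentile_used: float


def map_peptides_to_proteins(
    peptides: Iterable[str], proteome: Mapping[str, str]
) -> dict[str, list[tuple[str, int]]]:
    """Locate each peptide in the proteome by exact substring search.

    Returns ``{peptide: [(protein_id, start_1based), ...]}``; the share
    count N(x) is the number of *distinct* proteins hit. Peptides that hit
    nothing map to an empty list (flagged unmapped by the caller). Empty
    or invalid peptide strings are rejected with a logged reason.

    I and L are treated as distinct residues.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    hits: dict[str, list[tuple[str, int]]] = {}
    for pep in dict.fromkeys(peptides):  # preserve order, drop duplicates
        if not pep:
            logger.warning("rejected empty peptide string")
            continue
        if not set(pep) <= PEPTIDE_ALPHABET:
            logger.warning("rejected peptide with invalid characters: %r", pep)
            continue
        found: list[tuple[str, int]] = []
        for pid, seq in proteome.items():
            start = seq.find(pep)
            if start >= 0:
                found.append((pid, start + 1))
        hits[pep] = found
    return hits


def share_counts(hits: Mapping[str, Sequence[tuple[str, int]]]) -> dict[str, int]:
    """N(x): number of distinct proteome entries containing peptide x."""
    return {pep: len({pid for pid, _ in h}) for pep, h in hits.items()}


def peptide_weight(n_shared: int, q: float = 0.2, weight_mode: str = "literal") -> float:
    """P(x|N): the contribution of one distinct peptide to K."""
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0,1), got {q}")
    if n_shared < 1:
        raise ValueError("peptide weight requires N >= 1 (peptide must be mapped)")
    if weight_mode == "literal":
        return 1.0 + (1.0 - q) ** n_shared
    if weight_mode == "saturating":
        return 1.0 - (1.0 - q) ** n_shared
    raise ValueError(f"unknown weight_mode {weight_mode!r}")


def sampling_density(
    peptide_share_counts: Mapping[str, int] | Sequence[int],
    length: int,
    hla_class: str = "I",
    q: float = 0.2,
    weight_mode: str = "literal",
) -> float:
    """Sampling density D = K/(L-8) (class I) or K/(L-14) (class II).

    ``peptide_share_counts`` maps each distinct observed peptide of the
    protein to its share count N; a bare sequence of N values is accepted
    since identities do not enter the score. No peptides gives D = 0.
    """
    offset = _DENOM_OFFSET[hla_class]
    if length <= offset:
        raise ValueError(
            f"protein length {length} at or below denominator bound {offset} "
            f"for HLA class {hla_class}; protein excluded"
        )
    ns = (
        list(peptide_share_counts.values())
        if isinstance(peptide_share_counts, Mapping)
        else list(peptide_share_counts)
    )
    # fixed summation order keeps D bit-identical across processes
    k = sum(peptide_weight(n, q=q, weight_mode=weight_mode) for n in sorted(ns))
    return k / (length - offset)


def sampling_score_table(
    peptides: pd.DataFrame,
    proteome: Mapping[str, str],
    hla_class: str = "I",
    q: float = 0.2,
    weight_mode: str = "literal",
    protein_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-(sample, gene) sampling densities from a peptide observation table.

    ``peptides`` needs columns ``sample_id``, ``peptide`` and ``hla_class``.
    Peptides are mapped against ``proteome``; share counts N are computed
    over the whole proteome, and per-protein scores are collapsed to genes
    by taking the maximum D (one protein per gene unless a mapping is
    given). Returns a tidy frame with columns
    ``sample_id, gene, hla_class, D, K, L``.
    """
    sub = peptides[peptides["hla_class"] == hla_class]
    offset = _DENOM_OFFSET[hla_class]
    hits = map_peptides_to_proteins(sub["peptide"], proteome)
    n_of = share_counts(hits)
    gene_of = protein_to_gene or {}

    rows = []
    for sample_id, grp in sub.groupby("sample_id", sort=True):
        # distinct peptides per protein for this sample
        per_protein: dict[str, set[str]] = {}
        for pep in set(grp["peptide"]):
            for pid, _ in hits.get(pep, ()):
                per_protein.setdefault(pid, set()).add(pep)
        per_gene: dict[str, tuple[float, float, int]] = {}
        for pid, peps in per_protein.items():
            length = len(proteome[pid])
            if length <= offset:
                logger.warning("protein %s too short for class %s; excluded", pid, hla_class)
                continue
            d = sampling_density(
                {p: n_of[p] for p in peps}, length, hla_class, q=q, weight_mode=weight_mode
            )
            k = d * (length - offset)
            gene = gene_of.get(pid, pid)
            if gene not in per_gene or d > per_gene[gene][0]:
                per_gene[gene] = (d, k, length)
        for gene, (d, k, length) in sorted(per_gene.items()):
            rows.append(
                {"sample_id": sample_id, "gene": gene, "hla_class": hla_class,
                 "D": d, "K": k, "L": length}
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "hla_class", "D", "K", "L"])


def select_marker_panel(
    reference_scores: pd.DataFrame | pd.Series,
    hla_class: str,
    cell_type: str | None = None,
    percentile: float | None = None,
) -> MarkerPanel | dict[str, MarkerPanel]:
    """Genes strictly above the class-specific percentile of the score
    distribution across all genes, per cell type.

    ``reference_scores`` is either a Series (genes -> score, one cell
    type, ``cell_type`` required) or a DataFrame genes x cell types
    (returns one panel per column). Ties at the percentile are excluded
    (strict inequality), so a constant table yields empty panels.
    """
    pct = MARKER_PERCENTILE[hla_class] if percentile is None else percentile
    if isinstance(reference_scores, pd.DataFrame):
        return {
            ct: select_marker_panel(reference_scores[ct], hla_class, ct, pct)
            for ct in reference_scores.columns
        }
    scores = reference_scores.dropna()
    if scores.empty:
        raise ValueError("empty reference score table")
    cutoff = np.percentile(scores.to_numpy(), pct)
    genes = frozenset(scores.index[scores > cutoff])
    return MarkerPanel(cell_type or "unknown", genes, hla_class, pct)


def marker_presentation_level(
    sample_scores: pd.DataFrame, panel: MarkerPanel
) -> pd.Series:
    """Mean sampling density over the panel genes, per sample.

    A panel gene with no presented peptide in a sample contributes 0.
    ``sample_scores`` is the output of :func:`sampling_score_table`.
    """
    if not panel.gene_ids:
        raise ValueError("marker panel is empty")
    genes = sorted(panel.gene_ids)
    wide = (
        sample_scores[sample_scores["gene"].isin(panel.gene_ids)]
        .pivot_table(index="sample_id", columns="gene", values="D", aggfunc="max")
        .reindex(columns=genes)
    )
    all_samples = pd.Index(sorted(sample_scores["sample_id"].unique()), name="sample_id")
    wide = wide.reindex(index=all_samples).fillna(0.0)
    return wide.mean(axis=1)


def binder_fraction(
    best_ranks: Sequence[float] | pd.Series, threshold: float = BINDER_RANK_THRESHOLD
) -> float:
    """Fraction of peptides with predicted binding rank <= threshold (%)."""
    ranks = pd.Series(best_ranks, dtype=float).dropna()
    if ranks.empty:
        raise ValueError("no binding ranks available")
    return float((ranks <= threshold).mean())
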