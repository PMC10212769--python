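"""Rank-based 1D/2D annotation enrichment and marker-gene selection.

Given per-gene scores (a fold-change, a z-score, a sampling score), each
annotation term (a flat gene set) receives a rank score

    s = 2 (R_g - R_o) / n

with R_g the mean rank (ascending, average ties) of the term's genes,
R_o the mean rank of all other genes and n the number of scored genes.
|s| <= 1 always: the extreme configurations put the term's genes at the
very top (s -> +1) or the very bottom (s -> -1) of the ranking, and
s is invariant under strictly monotone transforms of the scores.

For two comparisons, terms are plotted at (s_x, s_y) and retained when
their Euclidean distance from the origin exceeds a threshold (0.3 for
expression fold-changes, 0.2 for sampling-score contrasts).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .tme import group_zscore


def rank_annotation_score(
    gene_scores: pd.Series, term_genes: Sequence[str]
) -> float:
    """s = 2(R_g - R_o)/n for one term; NaN if the term is disjoint from
    the scored universe or covers it entirely (no complement to rank
    against)."""
    scores = gene_scores.dropna()
    n = len(scores)
    in_term = scores.index.isin(set(term_genes))
    if not in_term.any() or in_term.all():
        return np.nan
    ranks = rankdata(scores.to_numpy(), method="average")
    r_g = ranks[in_term].mean()
    r_o = ranks[~in_term].mean()
    return 2.0 * (r_g - r_o) / n


def term_scores(
    gene_scores: pd.Series, gene_sets: Mapping[str, Sequence[str]]
) -> pd.Series:
    """Rank annotation score for every term of a GMT-style collection."""
    return pd.Series(
        {term: rank_annotation_score(gene_scores, genes) for term, genes in gene_sets.items()},
        name="s",
    )


def two_d_selection(
    s_x: pd.Series, s_y: pd.Series, distance_threshold: float = 0.3
) -> pd.DataFrame:
    """Terms whose (s_x, s_y) point lies strictly farther than the
    threshold from the origin. Returns term, s_x, s_y, distance."""
    df = pd.DataFrame({"s_x": s_x, "s_y": s_y}).dropna()
    df["distance"] = np.hypot(df["s_x"], df["s_y"])
    return df[df["distance"] > distance_threshold].reset_index(names="term")


def zscore_gene_selection(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    z_threshold: float = 2.0,
    scale: str = "linear",
) -> tuple[list[str], list[str]]:
    """Genes differing between two groups by two-group z-score: A-high
    genes have z > threshold, B-high genes z < -threshold (disjoint by
    construction)."""
    z = group_zscore(expr, group_a, group_b, scale=scale)
    return list(z.index[z > z_threshold]), list(z.index[z < -z_threshold])


def select_hlaII_markers(
    sample_scores: pd.DataFrame,
    group_labels: Mapping[str, str],
    candidate_genes: Sequence[str],
    presented_fraction: float = 0.5,
) -> list[str]:
    """HLA-II marker genes: candidates presented in at least half the
    replicates of some annotation group.

    ``sample_scores`` is the tidy (sample_id, gene, D) sampling-score
    table; a gene is presented in a sample when its score is > 0.
    ``group_labels`` maps sample -> group along one annotation axis
    (e.g. infiltrated/excluded or immune-high/low); a gene is retained
    when presented in >= ``presented_fraction`` (inclusive) of the
    samples of at least one group. Groups need >= 2 samples each.
    """
    groups: dict[str, list[str]] = {}
    for sample, g in group_labels.items():
        groups.setdefault(g, []).append(sample)
    if any(len(m) < 2 for m in groups.values()):
        raise ValueError("each annotation group needs >= 2 samples")
    presented = (
        sample_scores[sample_scores["D"] > 0]
        .groupby(["gene", "sample_id"])
        .size()
        .reset_index()[["gene", "sample_id"]]
    )
    retained = []
    for gene in candidate_genes:
        samples_with = set(presented.loc[presented["gene"] == gene, "sample_id"])
        for members in groups.values():
            frac = sum(s in samples_with for s in members) / len(members)
            if frac >= presented_fraction:
                retained.append(gene)
                break
    return retained


def hypergeom_enrichment_p(
    n_universe: int, n_term: int, n_selected: int, n_overlap: int
) -> float:
    """Upper-tail hypergeometric p for an overlap between a selected gene
    list and a term (thin Fisher-test core)."""
    if min(n_universe, n_term, n_selected) < 0 or n_overlap < 0:
        raise ValueError("counts must be nonnegative")
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_term, n_selected))
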