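"""Immune-editing statistics over multi-region mutation cohorts.

The central quantity is the fraction of "exact" hotspot matches among
predicted neoantigen binders. A predicted mutated peptide is an exact
match when its wild-type counterpart sequence is itself present verbatim
in a presentation-hotspot peptide database; per analysis unit
(macro-region or patient),

    F_ex = N_ex / N_total            over nonsynonymous binders
    F_ex,syn = N_ex,syn / N_total,syn  over synonymous binders
    enrichment = F_ex / F_ex,syn

where the synonymous fraction corrects for HLA-allele representation
bias in the database (synonymous mutations are assumed free of immune
pressure). Reduced F_ex or enrichment in immune-infiltrated tumors is
the editing signal.

The immunogenicity model learns per-mutation probabilities f_ex and
f_nonex of inducing a T-cell response from externally labeled mutations,
and the relative immunogenicity of a unit is the probability that a
randomly sampled mutation is immunogenic:

    RI = (N_ex * f_ex + N_other * f_nonex) / N_total
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BINDER_RANK_THRESHOLD = 2.0
NEOANTIGEN_LENGTHS = (9, 10, 11, 12)


@dataclass(frozen=True)
class ImmunogenicityModel:
    """Empirical per-mutation immunogenicity probabilities."""

    f_ex: float
    f_nonex: float

    @property
    def ratio(self) -> float:
        return self.f_ex / self.f_nonex


def consensus_mutations(
    caller_tables: Mapping[str, pd.DataFrame],
    key_cols: Sequence[str] = ("patient", "protein", "position", "ref", "alt"),
    min_callers: int = 2,
) -> pd.DataFrame:
    """High-confidence variants: called by >= ``min_callers`` callers.

    Each caller table carries the shared variant key plus attribute
    columns. Within a caller, duplicate keys are deduplicated (first kept,
    warning logged). Attribute values disagreeing across callers are
    resolved by strict majority; a variant with any unresolvable (tied)
    attribute is rejected and logged. Adds a ``caller_support`` column.
    """
    key_cols = list(key_cols)
    deduped = {}
    for caller, table in caller_tables.items():
        if table.duplicated(subset=key_cols).any():
            logger.warning("caller %s has duplicate variant keys; deduplicated", caller)
            table = table.drop_duplicates(subset=key_cols, keep="first")
        deduped[caller] = table.set_index(key_cols)

    support = Counter()
    for table in deduped.values():
        support.update(table.index)
    rows = []
    attr_cols: list[str] = sorted(
        {c for t in deduped.values() for c in t.columns}
    )
    for key, n in sorted(support.items(), key=lambda kv: tuple(map(str, kv[0]))):
        if n < min_callers:
            continue
        record = dict(zip(key_cols, key))
        rejected = False
        for col in attr_cols:
            votes = [
                t.loc[key, col]
                for t in deduped.values()
                if key in t.index and col in t.columns and pd.notna(t.loc[key, col])
            ]
            if not votes:
                record[col] = np.nan
                continue
            counts = Counter(votes).most_common()
            if len(counts) > 1 and counts[0][1] == counts[1][1]:
                logger.warning("variant %s rejected: no strict majority on %r", key, col)
                rejected = True
                break
            record[col] = counts[0][0]
        if rejected:
            continue
        record["caller_support"] = n
        rows.append(record)
    return pd.DataFrame(rows, columns=key_cols + attr_cols + ["caller_support"])


def classify_clonality(
    presence: pd.DataFrame | np.ndarray,
    n_regions: int | None = None,
    truncal_offset: int = 1,
) -> pd.Series:
    """Clonality per mutation from its region-presence vector.

    truncal: present in >= n_regions - truncal_offset regions (default
    offset 1; low-mutational-load patients may use offsets 2 or 3);
    private: present in <= 2 regions; shared: the rest. Truncal takes
    precedence where both conditions hold. A presence count of 0 is an
    error — the mutation must exist somewhere.
    """
    mat = pd.DataFrame(presence).astype(bool)
    n = n_regions if n_regions is not None else mat.shape[1]
    if n < 2:
        raise ValueError("clonality needs >= 2 regions")
    counts = mat.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("mutation with empty presence vector")
    labels = pd.Series("shared", index=mat.index, name="clonality")
    labels[counts <= 2] = "private"
    labels[counts >= n - truncal_offset] = "truncal"  # precedence over private
    return labels


def truncal_fraction(clonality: pd.Series) -> float:
    """Fraction of a patient's mutations classified truncal."""
    if clonality.empty:
        raise ValueError("no mutations")
    return float((clonality == "truncal").mean())


def classify_smoking(
    tobacco_contribution: float,
    pack_years: float | None = None,
    scheme: str = "binary",
) -> str:
    """Smoking label from the tobacco mutational-signature contribution.

    binary: "smoker" iff the SBS4-style contribution exceeds 0.5, else
    "nonsmoker". three_level: "light" iff contribution <= 0.30; "heavy"
    iff contribution >= 0.70 AND pack_years >= 70; else "intermediate"
    (missing pack-years make heavy unassignable).
    """
    c = float(tobacco_contribution)
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"signature contribution must be in [0,1], got {c}")
    if scheme == "binary":
        return "smoker" if c > 0.5 else "nonsmoker"
    if scheme == "three_level":
        if c <= 0.30:
            return "light"
        if c >= 0.70:
            if pack_years is None or (isinstance(pack_years, float) and np.isnan(pack_years)):
                logger.warning("pack-years missing: heavy unassignable, labeled intermediate")
                return "intermediate"
            if pack_years >= 70:
                return "heavy"
        return "intermediate"
    raise ValueError(f"unknown scheme {scheme!r}")


def enumerate_mutant_peptides(
    protein_seq: str,
    position: int,
    ref: str,
    alt: str,
    lengths: Sequence[int] = NEOANTIGEN_LENGTHS,
    reference_peptides: Iterable[str] | None = None,
) -> pd.DataFrame:
    """All 9–12-mer windows covering a mutated residue.

    ``position`` is 1-based; the protein must carry ``ref`` there. Returns
    a frame with columns ``mutant, wildtype, start, length``. For a
    nonsynonymous mutation (ref != alt), mutant peptides identical to any
    sequence in ``reference_peptides`` (a wild-type proteome peptide set)
    are filtered out; for synonymous mutations mutant == wildtype by
    construction and the filter is not applied.
    """
    n = len(protein_seq)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} out of bounds for protein of length {n}")
    if protein_seq[position - 1] != ref:
        raise ValueError(
            f"reference residue mismatch at {position}: protein has "
            f"{protein_seq[position - 1]!r}, mutation says {ref!r}"
        )
    mutated = protein_seq[: position - 1] + alt + protein_seq[position:]
    synonymous = ref == alt
    rows = []
    for length in lengths:
        lo = max(1, position - length + 1)
        hi = min(position, n - length + 1)
        for start in range(lo, hi + 1):
            mut = mutated[start - 1 : start - 1 + length]
            wt = protein_seq[start - 1 : start - 1 + length]
            if (
                not synonymous
                and reference_peptides is not None
                and mut in reference_peptides
            ):
                continue
            rows.append({"mutant": mut, "wildtype": wt, "start": start, "length": length})
    return pd.DataFrame(rows, columns=["mutant", "wildtype", "start", "length"])


def match_hotspot_exact(
    neoantigens: pd.DataFrame,
    hotspot_peptides: Iterable[str],
    rank_threshold: float = BINDER_RANK_THRESHOLD,
) -> pd.DataFrame:
    """Flag each predicted neoantigen whose wild-type counterpart is a
    verbatim member of the hotspot database, and roll up to mutations.

    ``neoantigens`` needs columns ``mutation_id, wildtype, best_rank``.
    Returns a copy with added boolean columns ``exact`` (peptide level)
    and ``mutation_exact`` (the mutation is exact iff at least one of its
    binders — rank <= threshold — is exact). Matching is allele-agnostic
    exact string membership.
    """
    db = hotspot_peptides if isinstance(hotspot_peptides, (set, frozenset)) else set(hotspot_peptides)
    out = neoantigens.copy()
    out["exact"] = out["wildtype"].isin(db)
    binders = out["best_rank"] <= rank_threshold
    exact_mutations = set(out.loc[binders & out["exact"], "mutation_id"])
    out["mutation_exact"] = out["mutation_id"].isin(exact_mutations)
    return out


def exact_fraction(
    exact_flags: Sequence[bool] | pd.Series,
) -> float:
    """F_ex = N_ex / N_total over a set of binder neoantigens; NaN if empty."""
    flags = pd.Series(exact_flags, dtype=bool)
    return float(flags.mean()) if len(flags) else np.nan


def exact_fraction_and_enrichment(
    neoantigens: pd.DataFrame,
    group_by: str = "region",
    annotation_group: Mapping[str, str] | None = None,
    rank_threshold: float = BINDER_RANK_THRESHOLD,
    impute: bool = True,
    drop_units_without_syn: bool = False,
) -> pd.DataFrame:
    """Per-unit editing statistics from a flagged neoantigen table.

    ``neoantigens`` needs columns ``region`` (or ``patient``),
    ``synonymous``, ``exact``, ``best_rank``. Only binders (rank <=
    threshold) are counted. Returns one row per unit with N_ex, N_total,
    F_ex, N_ex_syn, N_total_syn, F_ex_syn and enrichment = F_ex/F_ex_syn.

    Units where a fraction is undefined (no binders of that class) are
    imputed with the minimum defined value of their annotation group
    (``annotation_group`` maps unit -> group label; one pooled group when
    omitted); units lacking synonymous binders can instead be dropped,
    mirroring the exclusion of regions without synonymous mutations.
    """
    binders = neoantigens[neoantigens["best_rank"] <= rank_threshold]
    units = sorted(neoantigens[group_by].unique())
    rows = []
    for unit in units:
        sub = binders[binders[group_by] == unit]
        nonsyn = sub[~sub["synonymous"].astype(bool)]
        syn = sub[sub["synonymous"].astype(bool)]
        rows.append(
            {
                group_by: unit,
                "N_ex": int(nonsyn["exact"].sum()),
                "N_total": len(nonsyn),
                "F_ex": exact_fraction(nonsyn["exact"]) if len(nonsyn) else np.nan,
                "N_ex_syn": int(syn["exact"].sum()),
                "N_total_syn": len(syn),
                "F_ex_syn": exact_fraction(syn["exact"]) if len(syn) else np.nan,
            }
        )
    stats_df = pd.DataFrame(rows).set_index(group_by)
    if drop_units_without_syn:
        dropped = stats_df.index[stats_df["N_total_syn"] == 0]
        if len(dropped):
            logger.warning("units without synonymous binders dropped: %s", list(dropped))
        stats_df = stats_df[stats_df["N_total_syn"] > 0]
    if impute:
        groups = (
            pd.Series({u: annotation_group.get(u, "all") for u in stats_df.index})
            if annotation_group
            else pd.Series("all", index=stats_df.index)
        )
        for col in ("F_ex", "F_ex_syn"):
            for g in groups.unique():
                members = stats_df.index[groups == g]
                vals = stats_df.loc[members, col]
                if vals.isna().any():
                    if vals.notna().any():
                        stats_df.loc[members, col] = vals.fillna(vals.min())
                    else:
                        logger.warning(
                            "group %s has no defined %s to impute from; left missing", g, col
                        )
    with np.errstate(divide="ignore", invalid="ignore"):
        stats_df["enrichment"] = stats_df["F_ex"] / stats_df["F_ex_syn"]
    return stats_df.reset_index()


def learn_immunogenicity_probs(
    mutations: pd.DataFrame,
    include_not_tested: bool = False,
) -> ImmunogenicityModel:
    """f_ex and f_nonex as empirical immunogenic fractions per exactness class.

    ``mutations`` needs boolean ``exact`` and a label column
    ``immunogenicity`` in {"immunogenic", "nonimmunogenic", "not_tested"}.
    "not_tested" mutations are excluded from the denominators by default;
    with ``include_not_tested`` they count as nonimmunogenic.
    """
    df = mutations
    if not include_not_tested:
        df = df[df["immunogenicity"] != "not_tested"]
    exact = df[df["exact"].astype(bool)]
    nonexact = df[~df["exact"].astype(bool)]
    if exact.empty or nonexact.empty:
        raise ValueError("need labeled mutations in both the exact and nonexact class")
    f_ex = float((exact["immunogenicity"] == "immunogenic").mean())
    f_nonex = float((nonexact["immunogenicity"] == "immunogenic").mean())
    return ImmunogenicityModel(f_ex=f_ex, f_nonex=f_nonex)


def relative_immunogenicity(
    n_exact: int, n_other: int, model: ImmunogenicityModel
) -> float:
    """RI = (N_ex * f_ex + N_other * f_nonex) / N_total."""
    n_total = n_exact + n_other
    if n_total <= 0:
        return np.nan
    return (n_exact * model.f_ex + n_other * model.f_nonex) / n_total


def quality_ratio(
    quality: pd.Series,
    clonality: pd.Series,
) -> float:
    """q = <Q_truncal> / <Q_private> for one analysis unit.

    ``quality`` holds externally computed neoantigen-quality values Q per
    mutation; ``clonality`` the matching truncal/shared/private labels.
    Missing (NaN) when either group is empty.
    """
    truncal = quality[clonality == "truncal"]
    private = quality[clonality == "private"]
    if truncal.empty or private.empty:
        logger.warning("quality ratio undefined: empty truncal or private group")
        return np.nan
    return float(truncal.mean() / private.mean())


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "less",
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum (Mann-Whitney U) between two groups.

    Exact null distribution for small samples without ties, normal
    approximation with tie correction otherwise (scipy's automatic
    policy). Constant pooled values are degenerate: p = 1 is reported.
    Returns (statistic, p_value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs >= 1 value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("constant pooled values: degenerate comparison, p = 1")
        return float(len(a) * len(b) / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
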