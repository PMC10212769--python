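"""Synthetic multi-region immunopeptidome cohorts with implanted effects.

This module builds fully artificial cohorts that carry the statistical
structure the downstream analyses assume: a random proteome with
presentation-hotspot intervals and a hotspot peptide database drawn from
them; multi-region somatic mutation tables with truncal/shared/private
structure and predicted neoantigen binders whose wild-type counterparts
land in hotspots with a group-specific probability (the implanted
immune-editing effect is the gap between the "excluded" and
"infiltrated" probabilities); immunogenicity labels drawn from the
per-class probabilities f_ex / f_nonex; bulk and micro-region expression
matrices with implanted immune-infiltration and tumor-associated-antigen
patterns; and per-sample HLA-I/II peptide tables.

Everything is driven by a single integer seed; one independent RNG
stream per output table (seeded from the master seed by a fixed offset)
keeps each table reproducible on its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import AMINO_ACIDS, write_fasta, write_tsv

# fixed RNG stream offsets, one per generated table
_STREAMS = {"proteome": 0, "mutations": 1, "expression": 2, "peptidome": 3, "gtex": 4}

#: compact immune cell-type gene panels (signature-style marker sets)
IMMUNE_CELL_PANELS: dict[str, list[str]] = {
    "CD8_T": ["CD8A", "CD8B", "GZMA", "GZMB", "PRF1"],
    "CD4_T": ["CD4", "IL7R", "CD40LG"],
    "B_cells": ["CD19", "MS4A1", "CD79A", "CD79B"],
    "Macrophages": ["CD68", "CD14", "CD163", "CSF1R"],
    "Dendritic": ["ITGAX", "CD1C", "BATF3"],
    "NK": ["NCR1", "KLRD1", "NKG7"],
}

#: inflammation signature: immune markers plus interferon-response genes
INFLAMMATION_PANEL: list[str] = sorted(
    {g for genes in IMMUNE_CELL_PANELS.values() for g in genes}
    | {"CXCL9", "CXCL10", "IFNG", "STAT1", "IDO1", "HLA-DRA"}
)

HLA_I_GENES = ["HLA-A", "HLA-B", "HLA-C"]
MICRO_COMPARTMENTS = ["tumor", "stroma", "TLS", "CD45+", "necrosis"]


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    The defaults describe a small multi-region lung-tumor-like cohort:
    8 patients with 4 tumor macro-regions each, an editing effect of
    0.10 vs 0.04 on the probability that a nonsynonymous binder's
    wild-type counterpart lies in a presentation hotspot, and
    immunogenicity probabilities f_ex = 0.0195 / f_nonex = 0.00392.
    """

    n_patients: int = 8
    regions_per_patient: int = 4
    n_proteins: int = 120
    protein_length_range: tuple[int, int] = (80, 300)
    hotspot_fraction: float = 0.2
    hotspot_leak_prob: float = 0.02
    mutations_per_region: int = 60
    truncal_fraction: float = 0.5
    syn_fraction: float = 0.25
    exact_prob_excluded: float = 0.10
    exact_prob_infiltrated: float = 0.04
    binder_prob: float = 0.5
    windows_per_mutation: int = 3
    f_ex: float = 0.0195
    f_nonex: float = 0.00392
    n_taa_genes: int = 10
    micro_per_patient: int = 6
    peptides_per_sample: int = 300
    immune_log2_effect: float = 2.0
    taa_log2_boost_excluded: float = 0.0
    marker_peptide_weight: float = 3.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.protein_length_range
        if lo <= 15 or hi < lo:
            raise ValueError(
                f"invalid protein length range {self.protein_length_range}: minimum must exceed 15"
            )
        for name in (
            "hotspot_fraction", "hotspot_leak_prob", "truncal_fraction", "syn_fraction",
            "exact_prob_excluded", "exact_prob_infiltrated", "binder_prob",
            "f_ex", "f_nonex",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.exact_prob_infiltrated > self.exact_prob_excluded:
            raise ValueError(
                "exact_prob_infiltrated must not exceed exact_prob_excluded "
                "(the editing effect is their gap)"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])

    def gene_universe(self) -> list[str]:
        """Protein/gene ids: immune markers, HLA-I genes, TAA genes, background."""
        named = list(INFLAMMATION_PANEL) + HLA_I_GENES + self.taa_genes()
        n_bg = max(0, self.n_proteins - len(named))
        return named + [f"GENE{i:04d}" for i in range(1, n_bg + 1)]

    def taa_genes(self) -> list[str]:
        return [f"TAA{i:02d}" for i in range(1, self.n_taa_genes + 1)]


@dataclass(frozen=True)
class HotspotDB:
    """Presentation-hotspot peptide database over a proteome.

    ``peptides`` supports exact-sequence membership queries; ``n_shared``
    records N(x), the number of proteome entries containing each database
    peptide; ``intervals`` holds the per-protein hotspot intervals
    (1-based, inclusive) the peptides were drawn from.
    """

    peptides: frozenset[str]
    by_protein: Mapping[str, frozenset[str]]
    intervals: Mapping[str, tuple[tuple[int, int], ...]]
    n_shared: Mapping[str, int]

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides

    def __len__(self) -> int:
        return len(self.peptides)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein": pid, "peptide": pep, "n_shared": self.n_shared[pep]}
            for pid in sorted(self.by_protein)
            for pep in sorted(self.by_protein[pid])
        ]
        return pd.DataFrame(rows, columns=["protein", "peptide", "n_shared"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HotspotDB":
        by_protein = {
            pid: frozenset(grp["peptide"]) for pid, grp in df.groupby("protein")
        }
        n_shared = dict(zip(df["peptide"], df["n_shared"]))
        return cls(frozenset(df["peptide"]), by_protein, {}, n_shared)


@dataclass
class SyntheticCohort:
    """One generated cohort: all tables cross-reference each other."""

    config: CohortConfig
    proteome: dict[str, str]
    hotspot_db: HotspotDB
    mutations: pd.DataFrame
    neoantigens: pd.DataFrame
    peptidome: pd.DataFrame
    bulk_expr: pd.DataFrame
    micro_expr: pd.DataFrame
    annotations: pd.DataFrame
    gtex: pd.DataFrame


def patient_attributes(config: CohortConfig) -> pd.DataFrame:
    """Deterministic per-patient phenotype labels.

    Even-indexed patients are "excluded" nonsmokers with high tobacco-free
    mutational background; odd-indexed are "infiltrated" smokers —
    pairing the implanted editing effect with the smoking axis the way
    immune-pressured tumors behave. Inflammation alternates in blocks of
    two so it is not confounded with infiltration.
    """
    rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        infiltration = "excluded" if i % 2 == 0 else "infiltrated"
        smoker = infiltration == "infiltrated"
        rows.append(
            {
                "patient": pid,
                "infiltration": infiltration,
                "inflammation": "high" if i % 4 < 2 else "low",
                "sbs4_contribution": 0.75 if smoker else 0.15,
                "pack_years": 40.0 + 5.0 * i if smoker else 2.0,
                "hla2_status": "positive" if i % 2 == 1 else "negative",
            }
        )
    return pd.DataFrame(rows)


def _window_index(proteome: Mapping[str, str], lengths=range(8, 13)) -> dict[str, set[str]]:
    """peptide -> set of proteins containing it, over all 8–12-mer windows."""
    index: dict[str, set[str]] = {}
    for pid, seq in proteome.items():
        for k in lengths:
            for start in range(len(seq) - k + 1):
                index.setdefault(seq[start : start + k], set()).add(pid)
    return index


def generate_proteome_and_hotspots(config: CohortConfig) -> tuple[dict[str, str], HotspotDB]:
    """Random proteome with contiguous hotspot intervals and a hotspot DB.

    Each protein receives contiguous intervals covering about
    ``hotspot_fraction`` of its residues; the database holds every
    8–12-mer window lying fully inside an interval, plus a small leak of
    windows drawn anywhere (rate ``hotspot_leak_prob``), emulating a
    presentation-hotspot compendium without modeling MS physics.
    """
    rng = config.rng("proteome")
    lo, hi = config.protein_length_range
    genes = config.gene_universe()
    aa = np.array(list(AMINO_ACIDS))
    proteome: dict[str, str] = {}
    intervals: dict[str, tuple[tuple[int, int], ...]] = {}
    for gene in genes:
        length = int(rng.integers(lo, hi + 1))
        proteome[gene] = "".join(rng.choice(aa, size=length))
        target = int(round(config.hotspot_fraction * length))
        ivals: list[tuple[int, int]] = []
        if target >= 12:
            n_ivals = max(1, min(3, target // 30))
            # split the hotspot budget into contiguous non-overlapping chunks
            sizes = np.full(n_ivals, target // n_ivals)
            sizes[: target % n_ivals] += 1
            free = length - target
            gaps = rng.multinomial(free, np.ones(n_ivals + 1) / (n_ivals + 1))
            pos = 1
            for size, gap in zip(sizes, gaps):
                start = pos + int(gap)
                ivals.append((start, start + int(size) - 1))
                pos = start + int(size)
        intervals[gene] = tuple(ivals)

    index = _window_index(proteome)
    by_protein: dict[str, frozenset[str]] = {}
    all_peps: set[str] = set()
    for gene, seq in proteome.items():
        peps: set[str] = set()
        for start, end in intervals[gene]:
            for k in range(8, 13):
                for w in range(start, end - k + 2):
                    peps.add(seq[w - 1 : w - 1 + k])
        # leak: occasional windows from outside the hotspot intervals
        n_leak = rng.binomial(len(seq), config.hotspot_leak_prob)
        for _ in range(n_leak):
            k = int(rng.integers(8, 13))
            if len(seq) >= k:
                w = int(rng.integers(0, len(seq) - k + 1))
                peps.add(seq[w : w + k])
        by_protein[gene] = frozenset(peps)
        all_peps |= peps
    n_shared = {pep: len(index[pep]) for pep in all_peps}
    return proteome, HotspotDB(frozenset(all_peps), by_protein, intervals, n_shared)


def _random_window(rng, length_protein: int, position: int, lengths=(9, 10, 11, 12)):
    """A random window length/start covering ``position`` (1-based)."""
    k = int(rng.choice([l for l in lengths if l <= length_protein]))
    lo = max(1, position - k + 1)
    hi = min(position, length_protein - k + 1)
    return k, int(rng.integers(lo, hi + 1))


def generate_mutation_cohort(
    config: CohortConfig, proteome: Mapping[str, str], db: HotspotDB
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Somatic mutation and predicted-neoantigen tables with the implanted
    editing effect.

    Per patient, ``mutations_per_region * regions_per_patient`` distinct
    mutations are drawn; a ``truncal_fraction`` of them is present in all
    regions, the rest in a random proper subset. Each nonsynonymous
    mutation is placed inside a hotspot interval with the group-specific
    probability (excluded vs infiltrated patients), which puts its
    wild-type neoantigen counterparts into the database; synonymous
    mutations are placed uniformly and serve as the bias control.
    Binder ranks carry a point mass below the 2% threshold.
    """
    rng = config.rng("mutations")
    attrs = patient_attributes(config).set_index("patient")
    genes = list(proteome)
    mut_rows, neo_rows = [], []
    mut_id = 0
    for patient in attrs.index:
        p_exact = (
            config.exact_prob_excluded
            if attrs.loc[patient, "infiltration"] == "excluded"
            else config.exact_prob_infiltrated
        )
        regions = [f"{patient}_R{j + 1}" for j in range(config.regions_per_patient)]
        n_mut = config.mutations_per_region * config.regions_per_patient
        for _ in range(n_mut):
            mut_id += 1
            synonymous = rng.random() < config.syn_fraction
            in_hotspot = (not synonymous) and rng.random() < p_exact
            gene, position = _place_mutation(rng, proteome, db, in_hotspot)
            seq = proteome[gene]
            ref = seq[position - 1]
            alt = ref if synonymous else _other_residue(rng, ref)
            if rng.random() < config.truncal_fraction:
                present = list(regions)
            else:
                n_present = 1 + int(rng.binomial(len(regions) - 2, 0.3)) if len(regions) > 2 else 1
                present = sorted(rng.choice(regions, size=n_present, replace=False))
            mutated = seq[: position - 1] + alt + seq[position:]
            windows = []
            if in_hotspot:
                # guaranteed hotspot window: the 9-mer context is in the DB
                k, start = 9, _hotspot_window_start(rng, db.intervals[gene], position)
                windows.append((k, start, True))
            while len(windows) < config.windows_per_mutation:
                k, start = _random_window(rng, len(seq), position)
                windows.append((k, start, False))
            mutation_exact = False
            for k, start, forced_binder in windows:
                wt = seq[start - 1 : start - 1 + k]
                mut_pep = mutated[start - 1 : start - 1 + k]
                is_binder = forced_binder or rng.random() < config.binder_prob
                rank = (
                    float(rng.uniform(0.01, 2.0))
                    if is_binder
                    else float(rng.uniform(2.0, 100.0))
                )
                exact = wt in db
                if exact and rank <= 2.0:
                    mutation_exact = True
                for region in present:
                    neo_rows.append(
                        {
                            "mutation_id": mut_id, "patient": patient, "region": region,
                            "protein": gene, "mutant": mut_pep, "wildtype": wt,
                            "start": start, "length": k, "best_rank": rank,
                            "synonymous": synonymous, "exact": exact,
                        }
                    )
            f = config.f_ex if mutation_exact else config.f_nonex
            label = "immunogenic" if rng.random() < f else "nonimmunogenic"
            mut_rows.append(
                {
                    "mutation_id": mut_id, "patient": patient, "protein": gene,
                    "position": position, "ref": ref, "alt": alt,
                    "synonymous": synonymous,
                    "caller_support": int(rng.integers(2, 5)),
                    "regions": ";".join(present),
                    "immunogenicity": label,
                }
            )
    mutations = pd.DataFrame(mut_rows)
    neoantigens = pd.DataFrame(neo_rows)
    return mutations, neoantigens


def _other_residue(rng, ref: str) -> str:
    choices = [a for a in AMINO_ACIDS if a != ref]
    return str(rng.choice(choices))


def _place_mutation(rng, proteome, db: HotspotDB, in_hotspot: bool, max_tries: int = 200):
    """Pick (gene, position): inside a hotspot interval wide enough for a
    9-mer window, or anywhere for uniform placement."""
    genes = list(proteome)
    for _ in range(max_tries):
        gene = str(rng.choice(genes))
        seq = proteome[gene]
        if in_hotspot:
            wide = [iv for iv in db.intervals.get(gene, ()) if iv[1] - iv[0] + 1 >= 9]
            if not wide:
                continue
            start, end = wide[int(rng.integers(0, len(wide)))]
            position = int(rng.integers(start, end + 1))
        else:
            if len(seq) < 12:
                continue
            position = int(rng.integers(1, len(seq) + 1))
        return gene, position
    raise RuntimeError("could not place mutation; hotspot intervals too narrow")


def _hotspot_window_start(rng, intervals, position: int) -> int:
    """Start of a 9-mer window covering ``position`` fully inside one of
    the protein's hotspot intervals (such a window exists by placement)."""
    for start, end in intervals:
        if start <= position <= end and end - start + 1 >= 9:
            lo = max(start, position - 8)
            hi = min(position, end - 8)
            if lo <= hi:
                return int(rng.integers(lo, hi + 1))
    # fall back to any window covering the position (near interval edges)
    return max(1, position - int(rng.integers(0, 9)))


def generate_expression_profiles(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Bulk (macro-region) and micro-region TPM matrices plus annotations.

    Implanted structure: immune-panel genes are elevated (by
    ``immune_log2_effect`` on log2 scale) in the stroma of excluded
    patients and in the tumor micro-regions of infiltrated patients;
    the same elevation marks bulk tumor regions of inflammation-high
    patients. Designated TAA genes exceed 1 TPM only in their designated
    tumor macro-regions; HLA-A/B/C are highly expressed everywhere.
    """
    rng = config.rng("expression")
    attrs = patient_attributes(config).set_index("patient")
    genes = config.gene_universe()
    taas = set(config.taa_genes())
    immune = set(INFLAMMATION_PANEL)
    immune_present = sorted(immune & set(genes))  # sorted: draw order is fixed
    base_log2 = pd.Series(rng.normal(3.0, 1.0, size=len(genes)), index=genes)
    base_log2[immune_present] = rng.normal(2.0, 0.5, size=len(immune_present))
    base_log2[HLA_I_GENES] = rng.normal(6.5, 0.3, size=3)

    ann_rows, bulk_cols, micro_cols = [], {}, {}
    # each TAA gene is expressed in a random half of the tumor macro-regions
    all_tumor_macros = [
        f"{p}_R{j + 1}" for p in attrs.index for j in range(config.regions_per_patient)
    ]
    taa_sites = {
        g: set(rng.choice(all_tumor_macros, size=max(1, len(all_tumor_macros) // 2), replace=False))
        for g in sorted(taas)
    }

    def expr_column(sample, patient, compartment, level):
        shift = pd.Series(0.0, index=genes)
        infil = attrs.loc[patient, "infiltration"]
        inflam = attrs.loc[patient, "inflammation"]
        immune_here = (
            (level == "micro" and infil == "excluded" and compartment in ("stroma", "TLS", "CD45+"))
            or (level == "micro" and infil == "infiltrated" and compartment == "tumor")
            or (level == "macro" and compartment == "tumor" and inflam == "high")
        )
        if immune_here:
            shift[immune_present] += config.immune_log2_effect
        log2_vals = base_log2 + shift + rng.normal(0.0, config.noise_sd, size=len(genes))
        tpm = (2.0**log2_vals - 1.0).clip(lower=0.0)
        # TAA genes: high only in designated tumor macro-regions, silent elsewhere
        boost = 2.0**config.taa_log2_boost_excluded if infil == "excluded" else 1.0
        for g in sorted(taas):
            if level == "macro" and compartment == "tumor" and sample in taa_sites[g]:
                tpm[g] = float(rng.uniform(5.0, 50.0)) * boost
            else:
                tpm[g] = float(rng.uniform(0.0, 0.5))
        return tpm

    for patient in attrs.index:
        a = attrs.loc[patient]
        common = {
            "patient": patient, "infiltration": a["infiltration"],
            "inflammation": a["inflammation"],
            "sbs4_contribution": a["sbs4_contribution"],
            "pack_years": a["pack_years"], "hla2_status": a["hla2_status"],
        }
        for j in range(config.regions_per_patient):
            sample = f"{patient}_R{j + 1}"
            bulk_cols[sample] = expr_column(sample, patient, "tumor", "macro")
            ann_rows.append({"sample_id": sample, "level": "macro", "compartment": "tumor", **common})
        sample = f"{patient}_H1"
        bulk_cols[sample] = expr_column(sample, patient, "healthy", "macro")
        ann_rows.append({"sample_id": sample, "level": "macro", "compartment": "healthy", **common})
        for j in range(config.micro_per_patient):
            compartment = MICRO_COMPARTMENTS[j % len(MICRO_COMPARTMENTS)]
            sample = f"{patient}_M{j + 1}"
            micro_cols[sample] = expr_column(sample, patient, compartment, "micro")
            ann_rows.append(
                {"sample_id": sample, "level": "micro", "compartment": compartment, **common}
            )
    bulk = pd.DataFrame(bulk_cols, index=genes)
    micro = pd.DataFrame(micro_cols, index=genes)
    annotations = pd.DataFrame(ann_rows)
    return bulk, micro, annotations


def generate_gtex_reference(config: CohortConfig) -> pd.DataFrame:
    """GTEx-style 90th-percentile TPM table (genes x normal tissues).

    TAA genes stay below 1 TPM in every tissue except testis (where they
    are high, the cancer/testis pattern); other genes get broad moderate
    expression.
    """
    rng = config.rng("gtex")
    tissues = ["lung", "liver", "brain", "heart", "kidney", "skin", "colon", "testis"]
    genes = config.gene_universe()
    taas = set(config.taa_genes())
    data = {}
    for tissue in tissues:
        col = pd.Series(rng.uniform(2.0, 80.0, size=len(genes)), index=genes)
        for g in sorted(taas):
            col[g] = float(rng.uniform(10.0, 60.0)) if tissue == "testis" else float(
                rng.uniform(0.0, 0.5)
            )
        data[tissue] = col
    return pd.DataFrame(data)


def generate_peptidome(
    config: CohortConfig,
    proteome: Mapping[str, str],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample HLA-I/II peptide tables drawn from the proteome.

    Peptide lengths are 8–15 for HLA-I and 8–25 for HLA-II; every peptide
    is a verbatim substring of its source protein. In samples of
    infiltrated patients, T-cell marker genes are sampled with
    ``marker_peptide_weight``-fold weight for HLA-II, implanting the
    immune-cell footprint in the class II peptidome.
    """
    rng = config.rng("peptidome")
    genes = list(proteome)
    lengths_ok = {g: len(proteome[g]) for g in genes}
    t_cell_markers = set(IMMUNE_CELL_PANELS["CD8_T"]) | set(IMMUNE_CELL_PANELS["CD4_T"])
    macro = annotations[(annotations["level"] == "macro")]
    rows = []
    for _, samp in macro.iterrows():
        sample = samp["sample_id"]
        boosted = samp["infiltration"] == "infiltrated"
        for hla_class, (kmin, kmax) in (("I", (8, 15)), ("II", (8, 25))):
            weights = np.ones(len(genes))
            if hla_class == "II" and boosted:
                for i, g in enumerate(genes):
                    if g in t_cell_markers:
                        weights[i] *= config.marker_peptide_weight
            weights /= weights.sum()
            choice = rng.choice(len(genes), size=config.peptides_per_sample, p=weights)
            for gi in choice:
                gene = genes[gi]
                k = int(rng.integers(kmin, min(kmax, lengths_ok[gene]) + 1))
                start = int(rng.integers(1, lengths_ok[gene] - k + 2))
                rank = (
                    float(rng.uniform(0.01, 2.0))
                    if rng.random() < 0.85
                    else float(rng.uniform(2.0, 100.0))
                )
                rows.append(
                    {
                        "sample_id": sample, "peptide": proteome[gene][start - 1 : start - 1 + k],
                        "hla_class": hla_class, "intensity": float(rng.lognormal(10.0, 1.0)),
                        "best_rank": rank, "source_gene": gene, "start": start,
                    }
                )
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one complete cohort (all tables, cross-linked)."""
    proteome, db = generate_proteome_and_hotspots(config)
    mutations, neoantigens = generate_mutation_cohort(config, proteome, db)
    bulk, micro, annotations = generate_expression_profiles(config)
    gtex = generate_gtex_reference(config)
    peptidome = generate_peptidome(config, proteome, annotations)
    return SyntheticCohort(
        config=config, proteome=proteome, hotspot_db=db, mutations=mutations,
        neoantigens=neoantigens, peptidome=peptidome, bulk_expr=bulk,
        micro_expr=micro, annotations=annotations, gtex=gtex,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort as FASTA + TSV tables + a YAML config echo."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.proteome, out / "proteome.fasta")
    write_tsv(cohort.hotspot_db.to_frame(), out / "hotspot_db.tsv")
    write_tsv(cohort.mutations, out / "mutations.tsv")
    write_tsv(cohort.neoantigens, out / "neoantigens.tsv")
    write_tsv(cohort.peptidome, out / "peptidome.tsv")
    write_tsv(cohort.bulk_expr.rename_axis("gene").reset_index(), out / "bulk_expression.tsv")
    write_tsv(cohort.micro_expr.rename_axis("gene").reset_index(), out / "micro_expression.tsv")
    write_tsv(cohort.gtex.rename_axis("gene").reset_index(), out / "gtex_reference.tsv")
    write_tsv(cohort.annotations, out / "annotations.tsv")
    cfg = dataclasses.asdict(cohort.config)
    cfg["protein_length_range"] = list(cfg["protein_length_range"])
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
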