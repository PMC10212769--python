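"""End-to-end orchestration: simulate -> score -> select -> compare.

The pipeline generates (or loads) a cohort, computes sampling scores and
marker presentation, TME scores, TAA selection and presentation
efficiency, the immune-editing statistics and the rank-based enrichment,
and emits per-stage TSVs plus a machine-readable JSON summary. Given the
same configuration and seed the summary is byte-identical (floats are
rounded to 6 significant digits before serialization).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import editing, enrichment, peptidome, taa, tme
from .io import read_tsv, round_sig, write_tsv
from .peptidome import PEPTIDE_ALPHABET
from .synthetic import (
    HLA_I_GENES,
    IMMUNE_CELL_PANELS,
    INFLAMMATION_PANEL,
    CohortConfig,
    SyntheticCohort,
    generate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

ALL_STAGES = ("peptidome", "tme", "taa", "editing", "enrichment")


@dataclass
class PipelineConfig:
    """Everything the pipeline run needs: cohort, stages, thresholds."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cohort: dict[str, Any] = field(default_factory=dict)
    binder_rank_threshold: float = 2.0
    taa_tpm_threshold: float = 1.0
    r_threshold: float = 0.5
    z_threshold: float = 2.0
    distance_threshold: float = 0.2
    q: float = 0.2
    weight_mode: str = "literal"
    smoking_scheme: str = "binary"
    write_tables: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(self.cohort)
        if "protein_length_range" in kwargs:
            kwargs["protein_length_range"] = tuple(kwargs["protein_length_range"])
        kwargs.setdefault("seed", self.seed)
        return CohortConfig(**kwargs)


# ---------------------------------------------------------------------------
# input validation

_SCHEMAS: dict[str, dict[str, Any]] = {
    "peptides": {"required": ["sample_id", "peptide", "hla_class", "intensity", "best_rank"]},
    "expression": {"required": ["gene"]},
    "mutations": {
        "required": ["mutation_id", "patient", "protein", "position", "ref", "alt", "synonymous"]
    },
    "neoantigens": {
        "required": ["mutation_id", "region", "mutant", "wildtype", "best_rank", "synonymous"]
    },
    "annotations": {"required": ["sample_id", "patient", "level", "compartment"]},
}


def validate_inputs(paths: Mapping[str, str | Path]) -> list[str]:
    """Schema-check input TSVs; returns a list of error strings (empty = ok).

    ``paths`` maps a schema name (peptides, expression, mutations,
    neoantigens, annotations) to a TSV path. Checks required columns,
    value ranges (nonnegative TPM/intensity) and the peptide alphabet,
    with file/row diagnostics.
    """
    errors: list[str] = []
    for kind, path in paths.items():
        path = Path(path)
        if kind not in _SCHEMAS:
            errors.append(f"{path}: unknown input kind {kind!r}")
            continue
        if not path.exists():
            errors.append(f"{path}: file not found")
            continue
        try:
            df = read_tsv(path)
        except Exception as exc:  # malformed TSV
            errors.append(f"{path}: unreadable TSV ({exc})")
            continue
        missing = [c for c in _SCHEMAS[kind]["required"] if c not in df.columns]
        if missing:
            errors.append(f"{path}: missing required columns {missing}")
            continue
        if kind == "peptides":
            bad_rows = df.index[df["intensity"] < 0]
            for i in bad_rows:
                errors.append(f"{path}: row {i}: negative intensity {df.loc[i, 'intensity']}")
            for i, pep in df["peptide"].items():
                if not isinstance(pep, str) or not pep or not set(pep) <= PEPTIDE_ALPHABET:
                    errors.append(f"{path}: row {i}: invalid peptide {pep!r}")
        if kind == "expression":
            num = df.drop(columns=["gene"]).select_dtypes(include="number")
            neg = num.lt(0).any(axis=1)
            for i in df.index[neg]:
                errors.append(f"{path}: row {i}: negative expression value")
    return errors


# ---------------------------------------------------------------------------
# the run itself

def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if not np.isfinite(v) else round_sig(v)
    if isinstance(x, (np.integer, int)):
        return int(x)
    return x


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the enabled stages on a freshly simulated cohort.

    Returns the result bundle: a dict with the JSON summary under
    ``"summary"`` and the per-stage tables under ``"tables"``. With
    ``outdir`` given, per-stage TSVs, the summary JSON and a log of the
    effective configuration are written there.
    """
    cohort = generate_cohort(config.cohort_config())
    bundle: dict[str, Any] = {"tables": {}, "cohort": cohort}
    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": {
            "binder_rank": config.binder_rank_threshold,
            "taa_tpm": config.taa_tpm_threshold,
            "r": config.r_threshold,
            "z": config.z_threshold,
            "distance": config.distance_threshold,
            "q": config.q,
            "weight_mode": config.weight_mode,
        },
    }

    ann = cohort.annotations
    macro_tumor = ann[(ann["level"] == "macro") & (ann["compartment"] == "tumor")]
    patients = ann.drop_duplicates("patient").set_index("patient")
    region_patient = dict(zip(macro_tumor["sample_id"], macro_tumor["patient"]))
    region_group = {
        r: patients.loc[p, "infiltration"] for r, p in region_patient.items()
    }
    smoking = {
        p: editing.classify_smoking(
            patients.loc[p, "sbs4_contribution"], patients.loc[p, "pack_years"],
            scheme=config.smoking_scheme,
        )
        for p in patients.index
    }

    scores1 = scores2 = None
    if "peptidome" in config.stages:
        try:
            scores1 = peptidome.sampling_score_table(
                cohort.peptidome, cohort.proteome, "I", q=config.q,
                weight_mode=config.weight_mode,
            )
            scores2 = peptidome.sampling_score_table(
                cohort.peptidome, cohort.proteome, "II", q=config.q,
                weight_mode=config.weight_mode,
            )
            bundle["tables"]["sampling_scores_hla1"] = scores1
            bundle["tables"]["sampling_scores_hla2"] = scores2
            summary["peptidome"] = {
                "n_peptides_hla1": int((cohort.peptidome["hla_class"] == "I").sum()),
                "n_peptides_hla2": int((cohort.peptidome["hla_class"] == "II").sum()),
                "binder_fraction_hla1": peptidome.binder_fraction(
                    cohort.peptidome.loc[cohort.peptidome["hla_class"] == "I", "best_rank"],
                    config.binder_rank_threshold,
                ),
                "median_density_hla1": float(scores1["D"].median()),
                "median_density_hla2": float(scores2["D"].median()),
            }
        except Exception as exc:
            raise RuntimeError(f"stage peptidome failed: {exc}") from exc

    if "tme" in config.stages:
        try:
            tumor_bulk = cohort.bulk_expr[macro_tumor["sample_id"]]
            inflam = tme.inflammation_score(tumor_bulk, INFLAMMATION_PANEL)
            abundance = tme.cell_type_abundance(cohort.micro_expr, IMMUNE_CELL_PANELS)
            fov = tme.pca_fov(np.log2(tumor_bulk.T + 1.0))
            bundle["tables"]["inflammation_scores"] = inflam.rename("score").rename_axis(
                "sample_id").reset_index()
            bundle["tables"]["cell_type_abundance"] = abundance.rename_axis(
                "sample_id").reset_index()
            groups = macro_tumor.set_index("sample_id")["inflammation"]
            summary["tme"] = {
                "inflammation_mean_high": float(inflam[groups == "high"].mean()),
                "inflammation_mean_low": float(inflam[groups == "low"].mean()),
                "fov_first_component": float(fov[0]),
            }
            if scores2 is not None:
                mean_scores = scores2.groupby("gene")["D"].mean()
                micro_ann = ann[ann["level"] == "micro"].set_index("sample_id")
                corr = tme.correlate_abundance_with_genes(
                    cohort.micro_expr, abundance, list(micro_ann.index)
                )
                s_c = tme.summed_sampling_score(mean_scores, corr, config.r_threshold)
                bundle["tables"]["summed_sampling_scores"] = s_c.rename_axis(
                    "cell_type").reset_index()
                summary["tme"]["s_c"] = {k: float(v) for k, v in s_c.items()}
        except Exception as exc:
            raise RuntimeError(f"stage tme failed: {exc}") from exc

    if "taa" in config.stages:
        try:
            tumor_cols = list(macro_tumor["sample_id"])
            healthy_cols = list(
                ann.loc[(ann["level"] == "macro") & (ann["compartment"] == "healthy"), "sample_id"]
            )
            taas = taa.select_taas(
                cohort.bulk_expr[tumor_cols], cohort.bulk_expr[healthy_cols],
                cohort.gtex, threshold=config.taa_tpm_threshold,
            )
            e_hla = float(
                cohort.micro_expr.loc[
                    HLA_I_GENES,
                    [s for s in cohort.micro_expr.columns
                     if ann.set_index("sample_id").loc[s, "compartment"] == "tumor"],
                ].mean().mean()
            )
            eps = taa.detection_limit(cohort.micro_expr)
            p_eff = taa.mean_presentation_efficiency(
                cohort.bulk_expr[tumor_cols],
                scores1 if scores1 is not None else pd.DataFrame(columns=["sample_id", "gene", "D"]),
                taas, e_hla, eps, threshold=config.taa_tpm_threshold,
            )
            bundle["tables"]["taa_presentation_efficiency"] = p_eff.rename_axis(
                "sample_id").reset_index()
            by_group = {
                g: p_eff[[r for r in p_eff.index if region_group[r] == g]].dropna()
                for g in ("excluded", "infiltrated")
            }
            summary["taa"] = {
                "n_taas": len(taas),
                "mean_p_eff_excluded": float(by_group["excluded"].median())
                if len(by_group["excluded"]) else None,
                "mean_p_eff_infiltrated": float(by_group["infiltrated"].median())
                if len(by_group["infiltrated"]) else None,
            }
        except Exception as exc:
            raise RuntimeError(f"stage taa failed: {exc}") from exc

    if "editing" in config.stages:
        try:
            flagged = editing.match_hotspot_exact(
                cohort.neoantigens.drop(columns=["exact"]),
                cohort.hotspot_db.peptides, config.binder_rank_threshold,
            )
            stats_df = editing.exact_fraction_and_enrichment(
                flagged, group_by="region", annotation_group=region_group,
                rank_threshold=config.binder_rank_threshold,
            )
            stats_df["group"] = stats_df["region"].map(region_group)
            bundle["tables"]["editing_stats"] = stats_df
            f_ex_by = {
                g: stats_df.loc[stats_df["group"] == g, "F_ex"].dropna()
                for g in ("excluded", "infiltrated")
            }
            _, p_fex = editing.compare_groups(
                f_ex_by["infiltrated"], f_ex_by["excluded"], alternative="less"
            )
            model = editing.learn_immunogenicity_probs(
                cohort.mutations.assign(
                    exact=cohort.mutations["mutation_id"].isin(
                        set(flagged.loc[flagged["mutation_exact"], "mutation_id"])
                    )
                )
            )
            mut_exact = flagged.groupby("mutation_id")["mutation_exact"].any()
            ri_rows = []
            for region in sorted(set(flagged["region"])):
                muts = flagged.loc[flagged["region"] == region, "mutation_id"].unique()
                n_ex = int(mut_exact.reindex(muts).fillna(False).sum())
                ri_rows.append(
                    {
                        "region": region,
                        "patient": region_patient[region],
                        "smoking": smoking[region_patient[region]],
                        "RI": editing.relative_immunogenicity(n_ex, len(muts) - n_ex, model),
                    }
                )
            ri = pd.DataFrame(ri_rows)
            bundle["tables"]["relative_immunogenicity"] = ri
            _, p_ri = editing.compare_groups(
                ri.loc[ri["smoking"] == "smoker", "RI"],
                ri.loc[ri["smoking"] == "nonsmoker", "RI"],
                alternative="less",
            )
            summary["editing"] = {
                "f_ex_median_excluded": float(f_ex_by["excluded"].median()),
                "f_ex_median_infiltrated": float(f_ex_by["infiltrated"].median()),
                "enrichment_median": float(stats_df["enrichment"].median(skipna=True)),
                "p_value_f_ex_infiltrated_lt_excluded": p_fex,
                "f_ex_hat": model.f_ex,
                "f_nonex_hat": model.f_nonex,
                "ri_mean_smoker": float(ri.loc[ri["smoking"] == "smoker", "RI"].mean()),
                "ri_mean_nonsmoker": float(ri.loc[ri["smoking"] == "nonsmoker", "RI"].mean()),
                "p_value_ri_smoker_lt_nonsmoker": p_ri,
            }
        except Exception as exc:
            raise RuntimeError(f"stage editing failed: {exc}") from exc

    if "enrichment" in config.stages:
        try:
            micro_ann = ann[ann["level"] == "micro"].set_index("sample_id")
            tumor_m = list(micro_ann.index[micro_ann["compartment"] == "tumor"])
            stroma_m = list(
                micro_ann.index[micro_ann["compartment"].isin(["stroma", "TLS", "CD45+"])]
            )
            z = tme.group_zscore(cohort.micro_expr, tumor_m, stroma_m)
            gene_sets = {f"celltype:{ct}": genes for ct, genes in IMMUNE_CELL_PANELS.items()}
            infil_m = [s for s in micro_ann.index
                       if patients.loc[micro_ann.loc[s, "patient"], "infiltration"] == "infiltrated"]
            excl_m = [s for s in micro_ann.index
                      if patients.loc[micro_ann.loc[s, "patient"], "infiltration"] == "excluded"]
            z2 = tme.group_zscore(cohort.micro_expr, infil_m, excl_m)
            s_x = enrichment.term_scores(z.replace([np.inf, -np.inf], np.nan), gene_sets)
            s_y = enrichment.term_scores(z2.replace([np.inf, -np.inf], np.nan), gene_sets)
            retained = enrichment.two_d_selection(s_x, s_y, config.distance_threshold)
            bundle["tables"]["enrichment_2d"] = retained
            summary["enrichment"] = {
                "n_terms_scored": int(s_x.notna().sum()),
                "n_terms_retained": len(retained),
            }
        except Exception as exc:
            raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    bundle["summary"] = _jsonable(summary)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in bundle["tables"].items():
            write_tsv(table, out / f"{name}.tsv")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(bundle["summary"], fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "report.txt", "w", encoding="utf-8") as fh:
            fh.write(write_report(bundle))
    return bundle


def write_report(bundle: dict) -> str:
    """Human-readable summary of the headline comparisons."""
    s = bundle["summary"]
    lines = ["Pipeline report", "=" * 15, f"seed: {s['seed']}", ""]
    for stage in ALL_STAGES:
        if stage not in s:
            continue
        lines.append(f"[{stage}]")
        for key, value in sorted(s[stage].items()):
            if isinstance(value, dict):
                for k2, v2 in sorted(value.items()):
                    lines.append(f"  {key}.{k2}: {v2}")
            elif value is None:
                lines.append(f"  {key}: degenerate (empty group)")
            else:
                lines.append(f"  {key}: {value}")
        lines.append("")
    return "\n".join(lines)
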