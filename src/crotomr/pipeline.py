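"""End-to-end pipeline driver.

Runs the eight analysis stages in order — candidate-gene screen, expression
validation statistics, immune-cell-subset screen, metabolome-wide screen,
exposure→metabolite screen, two-step mediation, spatial stage, clinical
stage — writing one TSV per stage plus a run log recording seeds, thresholds
and the exact Bonferroni denominators used. A YAML configuration names the
inputs; in ``simulate`` mode every input is generated by the synthetic
module from the configured seeds, so the whole pipeline runs with no
external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, stats_kit
from .clinical import cohort_to_frame, survival_compare, table_one
from .instruments import InstrumentConfig, LDMatrix
from .mediation import mediation_screen
from .screens import run_screen, screen_to_frame
from .spatial import spots_to_frame, summarize_section
from .sumstats import read_sumstats
from .synthetic import (
    SyntheticChainConfig,
    SyntheticMRConfig,
    gen_cohort,
    gen_mediation_chain,
    gen_spatial_section,
    gen_sumstats_pair,
)

logger = logging.getLogger(__name__)

STAGES = [
    "gene_screen", "validation_stats", "celltype_screen", "metabolite_screen",
    "exposure_metabolite_screen", "mediation", "spatial", "clinical",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Structured pipeline configuration (YAML on disk)."""

    out_dir: str = "crotomr-run"
    alpha: float = 0.05
    seed: int = 1
    simulate: bool = True
    n_genes: int = 16
    n_celltypes: int = 14
    n_metabolites: int = 8
    n_mediators: int = 3
    instrument: dict = field(default_factory=dict)
    # paths used when simulate is false
    exposures_dir: str = ""
    outcome_path: str = ""
    ld_path: str = ""
    spatial_path: str = ""
    cohort_path: str = ""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def instrument_config(self) -> InstrumentConfig:
        return InstrumentConfig(**self.instrument)


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> Path:
    path = out_dir / f"{name}.tsv"
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def _simulated_screen_inputs(seed: int, n_exposures: int, causal_theta: float,
                             causal_index: int, k: int = 20):
    """A panel of exposures over a shared outcome: one truly causal
    exposure, the rest null. Every exposure has its own instruments merged
    into one outcome dataset and one LD matrix."""
    from .sumstats import SummaryDataset, VariantAssociation

    exposures, outcome_records, all_ids = [], [], []
    for e in range(n_exposures):
        cfg = SyntheticMRConfig(seed=seed + 1000 * e, k=k,
                                theta=causal_theta if e == causal_index else 0.0)
        exp, out, _, _ = gen_sumstats_pair(cfg)
        # re-key variant ids per exposure so panels do not collide
        renamed_exp, renamed_out = [], []
        for r_exp, r_out in zip(exp.records, out.records):
            vid = f"e{e:02d}_{r_exp.variant_id}"
            renamed_exp.append(VariantAssociation(
                vid, r_exp.chromosome, r_exp.position, r_exp.effect_allele,
                r_exp.other_allele, r_exp.eaf, r_exp.beta, r_exp.se,
                r_exp.pvalue, r_exp.n))
            renamed_out.append(VariantAssociation(
                vid, r_out.chromosome, r_out.position, r_out.effect_allele,
                r_out.other_allele, r_out.eaf, r_out.beta, r_out.se,
                r_out.pvalue, r_out.n))
        exposures.append(SummaryDataset(f"exposure_{e:02d}", "continuous", renamed_exp,
                                        source_tag="synthetic"))
        outcome_records.extend(renamed_out)
        all_ids.extend(r.variant_id for r in renamed_exp)
    outcome = SummaryDataset("synthetic_outcome", "binary", outcome_records,
                             source_tag="synthetic")
    ld = LDMatrix(all_ids, np.eye(len(all_ids)))
    return exposures, outcome, ld


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    Any stage's fatal error raises :class:`StageError` tagged with the stage
    name; outputs of completed stages remain on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.instrument_config()
    rng_seed = config.seed
    log: dict = {"version": __version__, "seed": rng_seed, "alpha": config.alpha,
                 "instrument_config": cfg.__dict__, "stages": {}}

    if not config.simulate:
        # externally supplied inputs: one TSV per exposure in exposures_dir
        try:
            exp_paths = sorted(Path(config.exposures_dir).glob("*.tsv"))
            gene_exposures = [read_sumstats(p, trait_label=p.stem) for p in exp_paths]
            outcome = read_sumstats(config.outcome_path, trait_label="outcome",
                                    trait_type="binary")
            ld = LDMatrix.read_tsv(config.ld_path)
        except Exception as exc:
            raise StageError("gene_screen", f"cannot load inputs: {exc}") from exc
        celltype_exposures = gene_exposures
        metabolite_exposures = gene_exposures
    else:
        gene_exposures, outcome, ld = _simulated_screen_inputs(
            rng_seed, config.n_genes, causal_theta=0.173, causal_index=0)
        celltype_exposures, ct_outcome, ct_ld = _simulated_screen_inputs(
            rng_seed + 7, config.n_celltypes, causal_theta=0.37, causal_index=1)
        metabolite_exposures, met_outcome, met_ld = _simulated_screen_inputs(
            rng_seed + 13, config.n_metabolites, causal_theta=-0.2, causal_index=2)

    # 1. candidate-gene screen (single-instrument Wald permitted)
    try:
        gene_results = run_screen(gene_exposures, outcome, ld, cfg,
                                  alpha=config.alpha, allow_wald=True)
        _write(screen_to_frame(gene_results, outcome.trait_label), out_dir, "gene_screen")
        log["stages"]["gene_screen"] = {
            "n_tests": gene_results[0].n_tests,
            "bonferroni_threshold": gene_results[0].bonferroni_threshold,
        }
    except Exception as exc:
        raise StageError("gene_screen", str(exc)) from exc

    # 2. expression-validation statistics (rank tests on simulated cohorts)
    try:
        rng = np.random.default_rng(rng_seed + 21)
        normal = rng.normal(0.0, 1.0, 80)
        tumor = rng.normal(0.8, 1.0, 80)
        paired_diff = rng.normal(0.5, 1.0, 40)
        rows = [
            {"comparison": "tumor_vs_normal", "test": "wilcoxon_rank_sum",
             "pvalue": stats_kit.wilcoxon_rank_sum(tumor, normal)},
            {"comparison": "paired_tumor_vs_adjacent", "test": "wilcoxon_signed_rank",
             "pvalue": stats_kit.wilcoxon_signed_rank(paired_diff)},
            {"comparison": "across_cell_types", "test": "kruskal_wallis",
             "pvalue": stats_kit.kruskal_wallis(
                 [rng.normal(m, 1.0, 50) for m in (0.0, 0.3, 0.9)])[1]},
        ]
        _write(pd.DataFrame(rows), out_dir, "validation_stats")
        log["stages"]["validation_stats"] = {"n_comparisons": len(rows)}
    except Exception as exc:
        raise StageError("validation_stats", str(exc)) from exc

    # 3. immune-cell-subset screen (minimum three instruments)
    try:
        if config.simulate:
            ct_results = run_screen(celltype_exposures, ct_outcome, ct_ld, cfg,
                                    alpha=config.alpha, allow_wald=False)
        else:
            ct_results = run_screen(celltype_exposures, outcome, ld, cfg,
                                    alpha=config.alpha, allow_wald=False)
        _write(screen_to_frame(ct_results), out_dir, "celltype_screen")
        log["stages"]["celltype_screen"] = {
            "n_tests": ct_results[0].n_tests,
            "bonferroni_threshold": ct_results[0].bonferroni_threshold,
        }
    except Exception as exc:
        raise StageError("celltype_screen", str(exc)) from exc

    # 4. metabolome-wide screen (minimum three instruments)
    try:
        if config.simulate:
            met_results = run_screen(metabolite_exposures, met_outcome, met_ld, cfg,
                                     alpha=config.alpha, allow_wald=False)
        else:
            met_results = run_screen(metabolite_exposures, outcome, ld, cfg,
                                     alpha=config.alpha, allow_wald=False)
        _write(screen_to_frame(met_results), out_dir, "metabolite_screen")
        log["stages"]["metabolite_screen"] = {
            "n_tests": met_results[0].n_tests,
            "bonferroni_threshold": met_results[0].bonferroni_threshold,
        }
    except Exception as exc:
        raise StageError("metabolite_screen", str(exc)) from exc

    # 5-6. exposure -> metabolite screen and two-step mediation on a chain
    try:
        chain_cfg = SyntheticChainConfig(seed=rng_seed + 31)
        c_exp, c_med, c_out, c_ld, truth = gen_mediation_chain(chain_cfg)
        med_df = mediation_screen(c_exp, [c_med], c_out, c_ld, cfg)
        step1 = med_df[["exposure", "mediator", "beta1", "se1", "flag"]].copy()
        _write(step1, out_dir, "exposure_metabolite_screen")
        _write(med_df, out_dir, "mediation")
        log["stages"]["mediation"] = {"true_proportion": truth["proportion"]}
    except Exception as exc:
        raise StageError("mediation", str(exc)) from exc

    # 7. spatial stage
    try:
        if config.simulate or not config.spatial_path:
            spots = gen_spatial_section(seed=rng_seed + 41, n_spots=400)
        else:
            from .spatial import spots_from_frame
            spots = spots_from_frame(pd.read_csv(config.spatial_path, sep="\t"))
        summary = summarize_section(spots)
        spot_df = spots_to_frame(spots)
        _write(spot_df, out_dir, "spatial_spots")
        rows = [{"section_id": summary.section_id,
                 "mal_mean": summary.mal_mean, "mal_sem": summary.mal_sem,
                 "nmal_mean": summary.nmal_mean, "nmal_sem": summary.nmal_sem,
                 "wilcoxon_pvalue": summary.wilcoxon_pvalue}]
        _write(pd.DataFrame(rows), out_dir, "spatial")
        log["stages"]["spatial"] = {"n_spots": len(spots)}
    except Exception as exc:
        raise StageError("spatial", str(exc)) from exc

    # 8. clinical stage
    try:
        if config.simulate or not config.cohort_path:
            cohort = gen_cohort(seed=rng_seed + 51, n=60, hr=2.5)
        else:
            from .clinical import cohort_from_frame
            cohort = cohort_from_frame(pd.read_csv(config.cohort_path))
        t1 = table_one(cohort)
        _, chi2, pvalue = survival_compare(cohort)
        t1 = pd.concat([t1, pd.DataFrame([{
            "variable": "overall_survival", "level": "logrank",
            "low": "", "high": "", "low_pct": float("nan"), "high_pct": float("nan"),
            "test": "logrank", "pvalue": pvalue, "flag": ""}])], ignore_index=True)
        _write(t1, out_dir, "clinical")
        _write(cohort_to_frame(cohort), out_dir, "clinical_cohort")
        log["stages"]["clinical"] = {"n_patients": len(cohort),
                                     "logrank_pvalue": pvalue}
    except Exception as exc:
        raise StageError("clinical", str(exc)) from exc

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return out_dir
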