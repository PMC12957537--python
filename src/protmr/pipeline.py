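"""End-to-end orchestration: instruments -> MR -> sensitivity -> coloc -> report.

The in-memory entry point is :func:`run_study`, which consumes the dict
produced by :func:`protmr.simulate.simulate_study` (or equivalently loaded
tables) and returns every stage's table. :func:`run_pipeline` wraps it with
file IO and a JSON run manifest so identical configs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import io as io_mod
from . import mr as mr_mod
from . import sensitivity as sens_mod
from .annotate import map_druggability
from .instruments import InstrumentSelectionConfig, select_instruments
from .io import SUMMARY_COLUMNS

logger = logging.getLogger(__name__)

ANALYSIS_MODES = ("cis_only", "cis_plus_trans", "both")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to/from YAML."""

    seed: int = 0
    analysis_mode: str = "both"
    n_boot: int = 1000
    alpha: float = 0.05  # heterogeneity / pleiotropy detection level
    n_proteins_tested: int | None = None  # Bonferroni denominator; default: observed
    coloc_window_bp: int = 1_000_000
    instruments: InstrumentSelectionConfig = field(default_factory=InstrumentSelectionConfig)
    coloc_priors: coloc_mod.ColocPriors = field(default_factory=coloc_mod.ColocPriors)
    paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.analysis_mode not in ANALYSIS_MODES:
            raise ValueError(f"analysis_mode must be one of {ANALYSIS_MODES}")
        self.instruments.validate()
        self.coloc_priors.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "instruments":
                cfg.instruments = InstrumentSelectionConfig(**value)
            elif key == "coloc_priors":
                cfg.coloc_priors = coloc_mod.ColocPriors(**value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise io_mod.ConfigError(f"unknown config key: {key}")
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _modes(cfg: RunConfig) -> list[str]:
    return ["cis_only", "cis_plus_trans"] if cfg.analysis_mode == "both" else [cfg.analysis_mode]


def run_study(study: dict, cfg: RunConfig | None = None) -> dict:
    """Run every pipeline stage on an in-memory study.

    ``study`` needs keys ``exposure`` (long frame with protein_id and
    study_id), ``outcome``, ``ld`` and ``genes``; optional ``druggability``
    and ``ttd`` annotation frames. Returns a dict with the instrument
    table, per-method MR results, verdicts, Steiger results,
    colocalization results, the final report, and summary counts.
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    instruments_df = select_instruments(study["exposure"], study["ld"], study["genes"], cfg.instruments)
    outcome = study["outcome"]

    mr_results: list[mr_mod.MRResult] = []
    verdicts: list[sens_mod.VerdictRecord] = []
    steiger_results: list[sens_mod.SteigerResult] = []
    coloc_results: list[coloc_mod.ColocResult] = []
    report_rows = []
    counts: dict = {"instruments": len(instruments_df)}

    for mode in _modes(cfg):
        inst = (
            instruments_df.loc[instruments_df["cis_trans"] == "cis"]
            if mode == "cis_only"
            else instruments_df
        )
        n_tested = cfg.n_proteins_tested or max(int(inst["protein_id"].nunique()), 1)
        mode_verdicts: list[sens_mod.VerdictRecord] = []
        pairs_by_key: dict = {}
        for (protein, study_id), grp in inst.groupby(["protein_id", "study_id"], sort=True):
            out_sub = outcome.loc[outcome["variant_id"].isin(grp["variant_id"])]
            pairs = mr_mod.harmonize(grp[SUMMARY_COLUMNS], out_sub)
            try:
                methods = mr_mod.run_all_methods(
                    pairs, protein_id=protein, analysis_mode=mode,
                    n_boot=cfg.n_boot, seed=cfg.seed,
                )
            except mr_mod.TooFewInstruments:
                logger.warning("%s/%s (%s): no usable instruments after harmonization",
                               protein, study_id, mode)
                continue
            mr_results.extend(methods.values())
            verdict = sens_mod.decision_ladder(methods, alpha=cfg.alpha)
            verdict.extra["study_id"] = study_id
            mode_verdicts.append(verdict)
            pairs_by_key[(protein, study_id)] = pairs

        sens_mod.bonferroni(mode_verdicts, n_tested)
        counts[f"{mode}_proteins_tested"] = n_tested
        counts[f"{mode}_associations"] = sum(v.passes_correction for v in mode_verdicts)
        verdicts.extend(mode_verdicts)

        for verdict in mode_verdicts:
            if not verdict.passes_correction:
                continue
            protein = verdict.protein_id
            study_id = verdict.extra["study_id"]
            pairs = pairs_by_key[(protein, study_id)]
            steiger = sens_mod.steiger_filter(pairs, protein_id=protein)
            steiger_results.append(steiger)

            # colocalize the region around the strongest instrument
            exp_protein = study["exposure"].loc[
                (study["exposure"]["protein_id"] == protein)
                & (study["exposure"]["study_id"] == study_id)
            ]
            usable = mr_mod.usable_pairs(pairs)
            grp = exp_protein.loc[exp_protein["variant_id"].isin(usable["variant_id"])]
            index_variant = grp.sort_values(["pvalue", "variant_id"]).iloc[0]["variant_id"]
            region = coloc_mod.define_region(
                index_variant, exp_protein, outcome, window_bp=cfg.coloc_window_bp
            )
            cres = None
            if len(region) >= 2:
                cres = coloc_mod.coloc_posteriors(
                    exp_protein.loc[exp_protein["variant_id"].isin(region)],
                    outcome.loc[outcome["variant_id"].isin(region)],
                    cfg.coloc_priors,
                    region_id=f"{protein}:{study_id}:{mode}:{index_variant}",
                )
                coloc_results.append(cres)

            report_rows.append(
                {
                    "protein_id": protein,
                    "study_id": study_id,
                    "analysis_mode": mode,
                    "method": verdict.primary_method,
                    "estimate": verdict.primary_estimate,
                    "se": verdict.primary_se,
                    "pvalue": verdict.primary_p,
                    "direction": "Positive" if verdict.primary_estimate > 0 else "Negative",
                    "steiger_category": steiger.category,
                    "pp_h4": cres.pp_h4 if cres is not None else float("nan"),
                    "strong_coloc": bool(cres is not None and cres.strong_coloc),
                }
            )

    report = build_report(
        pd.DataFrame(report_rows),
        druggability=study.get("druggability"),
        ttd=study.get("ttd"),
    )
    for mode in _modes(cfg):
        sub = report.loc[report["analysis_mode"] == mode] if not report.empty else report
        counts[f"{mode}_unique_proteins"] = (
            int(sub["uniprot_id"].nunique()) if not report.empty else 0
        )
    return {
        "instruments": instruments_df,
        "mr_results": mr_mod.results_to_frame(mr_results),
        "verdicts": sens_mod.verdicts_to_frame(verdicts),
        "steiger": sens_mod.steiger_to_frame(steiger_results),
        "coloc": coloc_mod.results_to_frame(coloc_results),
        "report": report,
        "counts": counts,
    }


def build_report(
    associations: pd.DataFrame,
    *,
    druggability: pd.DataFrame | None = None,
    ttd: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the final per-association report table.

    One row per protein x study x mode that passed correction, carrying the
    direction of effect, Steiger category, colocalization evidence and —
    when annotation tables are supplied — druggability tier and therapeutic
    target type. The protein identifier column is normalized to
    ``uniprot_id``.
    """
    report = associations.copy()
    if report.empty:
        cols = ["uniprot_id", "study_id", "analysis_mode", "direction", "tier", "ttd_target_type"]
        return pd.DataFrame(columns=cols)
    if "uniprot_id" not in report.columns:
        report = report.rename(columns={"protein_id": "uniprot_id"})
    annotated, _counts = map_druggability(report, druggability, ttd)
    return annotated


def report_counts(report: pd.DataFrame) -> dict:
    """Association-row and unique-protein counts (the two headline tallies)."""
    if report.empty:
        return {"association_rows": 0, "unique_proteins": 0}
    return {
        "association_rows": int(len(report)),
        "unique_proteins": int(report["uniprot_id"].nunique()),
    }


def run_pipeline(config: RunConfig, outdir) -> dict:
    """File-based pipeline: read inputs from config.paths, write all outputs.

    ``config.paths`` must name ``exposure``, ``outcome``, ``ld`` and
    ``genes`` files (TSV; the exposure file additionally needs protein_id
    and study_id columns); ``druggability`` and ``ttd`` are optional.
    Writes per-stage TSVs plus ``manifest.json`` under ``outdir`` and
    returns the in-memory result dict.
    """
    config.validate()
    paths = config.paths
    for key in ("exposure", "outcome", "ld", "genes"):
        if key not in paths:
            raise io_mod.ConfigError(f"config.paths missing '{key}'")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"{key} input not found: {paths[key]}")

    exposure = pd.read_csv(paths["exposure"], sep="\t", dtype={"chromosome": str})
    exposure["chromosome"] = exposure["chromosome"].astype(str)
    outcome = io_mod.read_summary_stats(paths["outcome"])
    study = {
        "exposure": exposure,
        "outcome": outcome,
        "ld": io_mod.read_ld_table(paths["ld"]),
        "genes": io_mod.read_gene_annotation(paths["genes"]),
    }
    if paths.get("druggability"):
        from .annotate import read_druggability_table

        study["druggability"] = read_druggability_table(paths["druggability"])

    result = run_study(study, config)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("instruments", "mr_results", "verdicts", "steiger", "coloc", "report"):
        result[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.15g")
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    io_mod.write_manifest(
        outdir / "manifest.json",
        config=config.to_dict(),
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        seed=config.seed,
        numpy_version=np.__version__,
        stage_counts=result["counts"],
    )
    return result
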