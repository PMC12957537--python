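"""Frozen simulation scenarios for estimator calibration and validation.

Each function runs many seeded replicates of a named data-generating
scenario through the real pipeline codepath (significance filter, LD
clumping, harmonization, estimator) and reports summary statistics. The
same scenarios back the test suite, the analysis drivers and the
acceptance script, so the numbers they produce are the package's
operational definition of "the estimators behave as claimed".

Scenario definitions (all per-replicate sub-seeded from one base seed):

* ``recovery`` — 10 independent valid instruments, true effect 0.2,
  n = 10,000 exposure / 100,000 outcome: IVW should recover the effect.
* ``null`` — same but true effect 0: IVW's test should hold its 5% level.
* ``directional`` — 50 instruments all carrying directional pleiotropy
  (mean 0.02 on the exposure-raising allele), exposure n = 50,000 and
  causal effects U(0.1, 0.5) so Egger's NOME assumption holds: IVW is
  biased, the Egger slope is not.
* ``contaminated`` — 10 instruments of which 4 carry large balanced
  pleiotropy (SD 0.12): the weighted median stays centred on the truth
  while per-replicate IVW estimates stray many fixed-effect SEs away.
* ``coloc`` — H0–H4 regions at n = 50,000 per trait.
* ``steiger`` — forward (protein -> glucose) and reverse (glucose ->
  protein, reverse effect 0.3) directionality scenarios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mr as mr_mod
from .coloc import ColocPriors, coloc_posteriors
from .instruments import InstrumentSelectionConfig, filter_significant, ld_clump
from .sensitivity import steiger_filter
from .simulate import SimulationConfig, simulate_coloc_region, simulate_two_sample

TRUE_EFFECT = 0.2

RECOVERY = dict(
    n_exposure=10_000, n_outcome=100_000, n_loci=10, snps_per_locus=1,
    true_protein_effect=TRUE_EFFECT,
)
NULL = dict(RECOVERY, true_protein_effect=0.0)
DIRECTIONAL = dict(
    n_exposure=50_000, n_outcome=100_000, n_loci=50, snps_per_locus=1,
    true_protein_effect=TRUE_EFFECT, pleiotropy_mean=0.02, pleiotropy_sd=0.005,
    causal_beta_range=(0.1, 0.5),
)
CONTAMINATED = dict(
    n_exposure=10_000, n_outcome=100_000, n_loci=10, snps_per_locus=1,
    true_protein_effect=TRUE_EFFECT, pleiotropy_mean=0.0, pleiotropy_sd=0.12,
    pleiotropy_frac=0.4,
)
REVERSE = dict(
    n_exposure=10_000, n_outcome=100_000, n_loci=10, snps_per_locus=1,
    true_protein_effect=0.0, reverse_effect=0.3,
)


def _sub_seed(base_seed: int, rep: int) -> int:
    # distinct per-replicate seeds, kept well below 2**31
    return (base_seed * 100_003 + rep) % (2**31 - 1)


def simulate_pairs(seed: int, scenario: dict, p_threshold: float = 5e-8) -> pd.DataFrame:
    """One replicate: simulate, select instruments, harmonize."""
    cfg = SimulationConfig(seed=seed, **scenario)
    exposure, outcome, ld, _truth = simulate_two_sample(cfg)
    sig = filter_significant(exposure, p_threshold)
    clumped = ld_clump(sig, ld, InstrumentSelectionConfig(p_threshold=p_threshold))
    pairs = mr_mod.harmonize(
        clumped, outcome.loc[outcome["variant_id"].isin(clumped["variant_id"])]
    )
    return mr_mod.usable_pairs(pairs)


def ivw_recovery(n_reps: int = 200, seed: int = 0, scenario: dict | None = None) -> dict:
    """IVW estimates across replicates of the valid-instrument scenario."""
    scenario = scenario or RECOVERY
    estimates, model_ses, q_pvalues, n_snps = [], [], [], []
    for rep in range(n_reps):
        pairs = simulate_pairs(_sub_seed(seed, rep), scenario)
        if len(pairs) < 2:
            continue
        res = mr_mod.ivw(pairs)
        estimates.append(res.estimate)
        model_ses.append(res.se)
        q_pvalues.append(res.q_pvalue)
        n_snps.append(res.n_snps)
    estimates = np.array(estimates)
    return {
        "true_effect": scenario.get("true_protein_effect", TRUE_EFFECT),
        "n_reps": len(estimates),
        "mean_estimate": float(estimates.mean()),
        "mcse": float(estimates.std(ddof=1) / np.sqrt(len(estimates))),
        "empirical_se": float(estimates.std(ddof=1)),
        "mean_model_se": float(np.mean(model_ses)),
        "q_pvalues": np.array(q_pvalues),
        "mean_n_snps": float(np.mean(n_snps)),
    }


def ivw_type1_error(n_reps: int = 2000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Empirical rejection rate of the IVW test under the null."""
    rejections = 0
    used = 0
    for rep in range(n_reps):
        pairs = simulate_pairs(_sub_seed(seed, rep), NULL)
        if len(pairs) < 2:
            continue
        used += 1
        if mr_mod.ivw(pairs).pvalue < alpha:
            rejections += 1
    return {"n_reps": used, "alpha": alpha, "type1_error": rejections / used}


def directional_pleiotropy(n_reps: int = 200, seed: int = 0) -> dict:
    """IVW vs Egger under pure directional pleiotropy (InSIDE + NOME hold)."""
    ivw_est, egger_est, intercepts = [], [], []
    for rep in range(n_reps):
        pairs = simulate_pairs(_sub_seed(seed, rep), DIRECTIONAL)
        ivw_est.append(mr_mod.ivw(pairs).estimate)
        egg = mr_mod.mr_egger(pairs)
        egger_est.append(egg.estimate)
        intercepts.append(egg.egger_intercept)
    ivw_est, egger_est = np.array(ivw_est), np.array(egger_est)
    return {
        "true_effect": TRUE_EFFECT,
        "n_reps": n_reps,
        "ivw_mean": float(ivw_est.mean()),
        "ivw_mcse": float(ivw_est.std(ddof=1) / np.sqrt(n_reps)),
        "egger_mean": float(egger_est.mean()),
        "egger_mcse": float(egger_est.std(ddof=1) / np.sqrt(n_reps)),
        "mean_intercept": float(np.mean(intercepts)),
    }


def weighted_median_contamination(n_reps: int = 200, seed: int = 0, n_boot: int = 200) -> dict:
    """Weighted median vs IVW with 40% invalid instruments (large balanced pleiotropy)."""
    wm_est, ivw_dev_fixed = [], []
    for rep in range(n_reps):
        rseed = _sub_seed(seed, rep)
        pairs = simulate_pairs(rseed, CONTAMINATED)
        if len(pairs) < 3:
            continue
        wm_est.append(mr_mod.weighted_median(pairs, n_boot=n_boot, seed=rseed).estimate)
        res = mr_mod.ivw(pairs)
        ivw_dev_fixed.append(abs(res.estimate - TRUE_EFFECT) / res.extra["se_fixed"])
    wm_est = np.array(wm_est)
    ivw_dev_fixed = np.array(ivw_dev_fixed)
    return {
        "true_effect": TRUE_EFFECT,
        "n_reps": len(wm_est),
        "wm_mean": float(wm_est.mean()),
        "wm_mcse": float(wm_est.std(ddof=1) / np.sqrt(len(wm_est))),
        "ivw_frac_deviating_3se": float((ivw_dev_fixed > 3).mean()),
        "ivw_median_deviation_se": float(np.median(ivw_dev_fixed)),
    }


def coloc_scenario_rates(
    scenario: str, n_reps: int = 100, seed: int = 0, n_snps: int = 50,
    priors: ColocPriors | None = None,
) -> dict:
    """How often each coloc hypothesis wins (and PPH4 > 0.8) per scenario."""
    best_hits = 0
    strong = 0
    for rep in range(n_reps):
        exp, out, _ = simulate_coloc_region(scenario, n_snps=n_snps, seed=_sub_seed(seed, rep))
        res = coloc_posteriors(exp, out, priors)
        if res.best_hypothesis == scenario:
            best_hits += 1
        if res.strong_coloc:
            strong += 1
    return {
        "scenario": scenario,
        "n_reps": n_reps,
        "best_hypothesis_rate": best_hits / n_reps,
        "pp_h4_gt_0.8_rate": strong / n_reps,
    }


def steiger_rates(
    n_reps: int = 200, seed: int = 0, *, reverse: bool = False,
    bonferroni_threshold: float = 5e-5,
) -> dict:
    """Steiger category frequencies under the forward or reverse scenario.

    In the forward scenario categories are tallied over replicates whose
    IVW p passes the Bonferroni-style threshold (mirroring the study,
    which Steiger-filters only multiple-testing survivors); in the reverse
    scenario all replicates are tallied.
    """
    scenario = REVERSE if reverse else RECOVERY
    categories = []
    for rep in range(n_reps):
        pairs = simulate_pairs(_sub_seed(seed, rep), scenario)
        if len(pairs) < 2:
            continue
        if not reverse and mr_mod.ivw(pairs).pvalue >= bonferroni_threshold:
            continue
        categories.append(steiger_filter(pairs).category)
    n = len(categories)
    return {
        "n_reps": n,
        "true_rate": categories.count("true") / n,
        "false_rate": categories.count("false") / n,
        "uncertain_rate": categories.count("uncertain") / n,
    }


def pipeline_detection(n_runs: int = 50, seed: int = 0, n_boot: int = 200) -> dict:
    """End-to-end: does the pipeline recover exactly the causal proteins?"""
    from .pipeline import RunConfig, run_study
    from .simulate import StudyConfig, simulate_study

    exact = 0
    for rep in range(n_runs):
        rseed = _sub_seed(seed, rep)
        study = simulate_study(StudyConfig(seed=rseed))
        causal = {
            p["protein_id"] for p in study["truth"]["proteins"] if p["true_effect"] != 0
        }
        result = run_study(
            study, RunConfig(seed=rseed, analysis_mode="cis_plus_trans", n_boot=n_boot)
        )
        report = result["report"]
        found = set(report["uniprot_id"]) if not report.empty else set()
        if found == causal:
            exact += 1
    return {"n_runs": n_runs, "exact_recovery_rate": exact / n_runs}
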