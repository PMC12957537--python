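"""Sensitivity ladder, Bonferroni correction, and Steiger directionality.

The ladder picks each protein's primary estimate: IVW (or the Wald ratio
for a single instrument) by default; the weighted median when Cochran's Q
signals heterogeneity; MR-Egger when its intercept signals directional
pleiotropy. Pleiotropy takes precedence when both fire, since a nonzero
Egger intercept invalidates both IVW and, potentially, the median's
majority-valid assumption (configurable).

Steiger filtering asks whether the instruments explain more variance in the
exposure than in the outcome. On standardized traits a variant's variance
explained is ``2 f (1 - f) beta^2``; summed over independent instruments
per trait this gives squared correlations whose difference is tested with a
two-sample Fisher z-test. Associations are labelled "true" (forward
direction, p < 0.05), "false" (reversed, p < 0.05) or "uncertain"
(p >= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mr import MRResult


@dataclass
class VerdictRecord:
    """Primary-method verdict for one protein after the sensitivity ladder."""

    protein_id: str
    primary_method: str
    primary_estimate: float
    primary_se: float
    primary_p: float
    heterogeneity_flag: bool
    pleiotropy_flag: bool
    bonferroni_threshold: float = float("nan")
    passes_correction: bool = False
    analysis_mode: str = "cis_plus_trans"
    n_snps: int = 0
    extra: dict = field(default_factory=dict)


def decision_ladder(
    results: dict[str, MRResult],
    *,
    alpha: float = 0.05,
    pleiotropy_precedence: bool = True,
) -> VerdictRecord:
    """Select the primary estimator from one protein's MR results.

    ``results`` maps method name to :class:`MRResult` as produced by
    :func:`protmr.mr.run_all_methods`. A lone Wald ratio passes through
    unflagged. Heterogeneity (Q p < alpha) promotes the weighted median;
    a pleiotropic Egger intercept (p < alpha) promotes Egger, taking
    precedence when both fire unless ``pleiotropy_precedence=False``.
    Flags are recorded even when the preferred fallback is unavailable.
    """
    if "wald_ratio" in results and "ivw" not in results:
        r = results["wald_ratio"]
        return VerdictRecord(
            r.protein_id, "wald_ratio", r.estimate, r.se, r.pvalue,
            False, False, analysis_mode=r.analysis_mode, n_snps=r.n_snps,
        )
    if "ivw" not in results:
        raise ValueError("decision ladder needs an ivw or wald_ratio result")
    base = results["ivw"]
    het = bool(np.isfinite(base.q_pvalue) and base.q_pvalue < alpha)
    egger = results.get("egger")
    pleio = bool(
        egger is not None
        and np.isfinite(egger.egger_intercept_p)
        and egger.egger_intercept_p < alpha
    )

    primary = base
    if pleiotropy_precedence:
        if pleio and egger is not None:
            primary = egger
        elif het and "weighted_median" in results:
            primary = results["weighted_median"]
    else:
        if het and "weighted_median" in results:
            primary = results["weighted_median"]
        elif pleio and egger is not None:
            primary = egger
    return VerdictRecord(
        base.protein_id, primary.method, primary.estimate, primary.se, primary.pvalue,
        het, pleio, analysis_mode=base.analysis_mode, n_snps=base.n_snps,
    )


def bonferroni(
    verdicts: list[VerdictRecord], n_proteins_tested: int
) -> list[VerdictRecord]:
    """Stamp each verdict with the 0.05 / n threshold and a strict-< pass flag."""
    if n_proteins_tested < 1:
        raise ValueError("n_proteins_tested must be >= 1")
    threshold = 0.05 / n_proteins_tested
    for v in verdicts:
        v.bonferroni_threshold = threshold
        v.passes_correction = bool(v.primary_p < threshold)
    return verdicts


@dataclass
class SteigerResult:
    protein_id: str
    r2_exposure: float
    r2_outcome: float
    direction: str  # exposure_to_outcome | outcome_to_exposure
    steiger_p: float
    category: str  # true | false | uncertain


def _snp_r2(beta: np.ndarray, eaf: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-variant variance explained on a standardized trait.

    Uses 2 f (1-f) beta^2 where EAF is available, falling back to the
    F-statistic form F / (F + n - 2) with F = (beta/se)^2 otherwise.
    """
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    missing = ~np.isfinite(r2)
    if missing.any():
        F = (beta[missing] / se[missing]) ** 2
        r2[missing] = F / (F + n[missing] - 2.0)
    return r2


def steiger_filter(
    pairs: pd.DataFrame,
    n_exp: int | None = None,
    n_out: int | None = None,
    *,
    protein_id: str = "",
    alpha: float = 0.05,
) -> SteigerResult:
    """Directionality test for one protein's harmonized instrument set.

    Variance explained is summed over instruments per trait (capped just
    below 1), converted to correlations, and compared with a Fisher
    z-test using the two studies' sample sizes. With equal variance
    explained and equal n the statistic is exactly 0 and p = 1.
    """
    from .mr import usable_pairs

    pairs = usable_pairs(pairs)
    if pairs.empty:
        raise ValueError("steiger_filter needs at least one usable pair")
    n_exp = int(n_exp if n_exp is not None else pairs["n_exp"].iloc[0])
    n_out = int(n_out if n_out is not None else pairs["n_out"].iloc[0])
    bx = pairs["beta_exp"].to_numpy(float)
    by = pairs["beta_out"].to_numpy(float)
    fx = pairs["eaf_exp"].to_numpy(float)
    fy = pairs["eaf_out"].to_numpy(float) if "eaf_out" in pairs else fx
    sx = pairs["se_exp"].to_numpy(float)
    sy = pairs["se_out"].to_numpy(float)
    narr_x = np.full(len(pairs), n_exp, dtype=float)
    narr_y = np.full(len(pairs), n_out, dtype=float)

    cap = 1.0 - 1e-9
    r2_exp = float(min(np.sum(_snp_r2(bx, fx, sx, narr_x)), cap))
    r2_out = float(min(np.sum(_snp_r2(by, fy, sy, narr_y)), cap))

    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_exp - z_out) / denom
    p = float(2.0 * stats.norm.sf(abs(z)))

    direction = "exposure_to_outcome" if r2_exp > r2_out else "outcome_to_exposure"
    if p < alpha:
        category = "true" if direction == "exposure_to_outcome" else "false"
    else:
        category = "uncertain"
    return SteigerResult(protein_id, r2_exp, r2_out, direction, p, category)


def verdicts_to_frame(verdicts: list[VerdictRecord]) -> pd.DataFrame:
    return pd.DataFrame([{k: v for k, v in r.__dict__.items() if k != "extra"} for r in verdicts])


def steiger_to_frame(results: list[SteigerResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
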