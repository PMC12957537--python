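"""Allele harmonization and two-sample MR estimators.

Estimators: Wald ratio (single instrument), inverse-variance-weighted
meta-analysis of per-variant ratios with Cochran's Q and multiplicative
random-effects SE scaling, MR-Egger weighted regression with an
unconstrained intercept (the intercept tests directional pleiotropy), and
the weighted median with a parametric-bootstrap SE.

All estimates are on the scale of outcome SD per exposure SD, assuming both
sets of summary statistics are in SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class TooFewInstruments(ValueError):
    """The requested estimator needs more variants than were supplied."""


class DegenerateDesign(ValueError):
    """The regression design is collinear (e.g. all exposure betas equal)."""


HARMONIZE_ACTIONS = ("aligned", "flipped", "dropped_palindromic", "dropped_mismatch")
PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclass
class MRResult:
    """One estimator's output for one protein (plus diagnostics)."""

    protein_id: str
    method: str  # wald_ratio | ivw | egger | weighted_median
    estimate: float
    se: float
    pvalue: float
    n_snps: int
    analysis_mode: str = "cis_plus_trans"
    cochran_q: float = float("nan")
    q_df: int = 0
    q_pvalue: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_p: float = float("nan")
    extra: dict = field(default_factory=dict)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    *,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Harmonize exposure and outcome records to a shared effect allele.

    Matching alleles -> ``aligned``. Swapped alleles -> ``flipped`` (the
    outcome beta's sign and EAF are flipped). Palindromic variants (A/T or
    C/G) whose EAF falls inside the ambiguity window in either trait (or is
    missing) -> ``dropped_palindromic``; palindromic variants with
    informative frequencies are treated like any other match. Irreconcilable
    allele pairs -> ``dropped_mismatch``. Variants absent from the outcome
    are excluded (the count is available from the frame lengths; no proxy
    search is attempted).

    Returns one row per shared variant with columns beta_exp/se_exp/eaf_exp,
    beta_out/se_out/eaf_out, and ``action``. Only ``aligned`` and
    ``flipped`` rows should feed the estimators.
    """
    lo, hi = palindromic_eaf_window
    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("_exp", "_out"), how="inner"
    )
    rows = []
    for _, r in merged.iterrows():
        ea_e, oa_e = r["effect_allele_exp"], r["other_allele_exp"]
        ea_o, oa_o = r["effect_allele_out"], r["other_allele_out"]
        beta_out, eaf_out = r["beta_out"], r["eaf_out"]
        is_palindromic = {ea_e, oa_e} in PALINDROMIC

        if (ea_e, oa_e) == (ea_o, oa_o):
            action = "aligned"
        elif (ea_e, oa_e) == (oa_o, ea_o):
            action = "flipped"
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if pd.notna(eaf_out) else eaf_out
        else:
            action = "dropped_mismatch"

        if is_palindromic and action in ("aligned", "flipped"):
            eafs = [r["eaf_exp"], eaf_out]
            ambiguous = any(pd.isna(f) or lo <= f <= hi for f in eafs)
            if ambiguous:
                action = "dropped_palindromic"

        rows.append(
            {
                "variant_id": r["variant_id"],
                "chromosome": r.get("chromosome_exp"),
                "position": r.get("position_exp"),
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "beta_exp": r["beta_exp"],
                "se_exp": r["se_exp"],
                "eaf_exp": r["eaf_exp"],
                "n_exp": r.get("n_exp"),
                "beta_out": beta_out,
                "se_out": r["se_out"],
                "eaf_out": eaf_out,
                "n_out": r.get("n_out"),
                "action": action,
            }
        )
    return pd.DataFrame(rows)


def usable_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Rows surviving harmonization (aligned or flipped)."""
    if "action" not in pairs.columns:
        return pairs
    return pairs.loc[pairs["action"].isin(["aligned", "flipped"])].reset_index(drop=True)


def _ratios(pairs: pd.DataFrame, second_order: bool = False):
    bx = pairs["beta_exp"].to_numpy(float)
    by = pairs["beta_out"].to_numpy(float)
    sy = pairs["se_out"].to_numpy(float)
    if np.any(bx == 0):
        raise ZeroDivisionError("beta_exp = 0: Wald ratio undefined")
    b = by / bx
    se = sy / np.abs(bx)
    if second_order:
        sx = pairs["se_exp"].to_numpy(float)
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return b, se


def wald_ratio(
    pair: pd.DataFrame | pd.Series, *, second_order: bool = False,
    protein_id: str = "", analysis_mode: str = "cis_plus_trans",
) -> MRResult:
    """Single-instrument causal estimate: ``beta_out / beta_exp``.

    The default SE is the first-order delta approximation
    ``se_out / |beta_exp|``; ``second_order=True`` adds the exposure
    uncertainty term.
    """
    df = pair.to_frame().T if isinstance(pair, pd.Series) else pair
    if len(df) != 1:
        raise ValueError("wald_ratio takes exactly one harmonized pair")
    b, se = _ratios(df, second_order)
    est, s = float(b[0]), float(se[0])
    p = float(2.0 * stats.norm.sf(abs(est) / s))
    return MRResult(protein_id, "wald_ratio", est, s, p, 1, analysis_mode)


def ivw(
    pairs: pd.DataFrame, *, second_order: bool = False, allow_single: bool = False,
    protein_id: str = "", analysis_mode: str = "cis_plus_trans",
) -> MRResult:
    """Inverse-variance-weighted meta-analysis of per-variant Wald ratios.

    Fixed-effect weights 1/se_i^2; the reported SE is inflated by the
    multiplicative random-effects factor ``max(1, sqrt(Q / (k - 1)))`` so it
    never deflates below the fixed-effect SE. Cochran's Q and its
    chi-squared p-value on k-1 degrees of freedom quantify heterogeneity.
    """
    k = len(pairs)
    if k < 2 and not allow_single:
        raise TooFewInstruments("IVW needs >= 2 instruments; use wald_ratio")
    b, se = _ratios(pairs, second_order)
    w = 1.0 / se**2
    est = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - est) ** 2))
    q_df = max(k - 1, 0)
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    scale = max(1.0, np.sqrt(q / q_df)) if q_df > 0 else 1.0
    s = se_fixed * scale
    p = float(2.0 * stats.norm.sf(abs(est) / s))
    res = MRResult(protein_id, "ivw", est, s, p, k, analysis_mode, q, q_df, q_p)
    res.extra["se_fixed"] = se_fixed
    return res


def mr_egger(
    pairs: pd.DataFrame, *, fit_intercept: bool = True,
    protein_id: str = "", analysis_mode: str = "cis_plus_trans",
) -> MRResult:
    """MR-Egger weighted regression of outcome betas on exposure betas.

    Pairs are first oriented so every exposure beta is non-negative (the
    outcome beta's sign flips with it), then ``beta_out ~ intercept +
    slope * beta_exp`` is fit by WLS with weights ``1/se_out^2``. The slope
    is the causal estimate; a nonzero intercept indicates directional
    pleiotropy. SEs are rescaled by ``max(1, sqrt(RSS_w / (k - 2)))`` so
    under-dispersion never shrinks them.
    """
    k = len(pairs)
    min_k = 3 if fit_intercept else 1
    if k < min_k:
        raise TooFewInstruments(f"MR-Egger needs >= {min_k} instruments")
    bx = pairs["beta_exp"].to_numpy(float).copy()
    by = pairs["beta_out"].to_numpy(float).copy()
    sy = pairs["se_out"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    if fit_intercept and np.ptp(bx) == 0:
        raise DegenerateDesign("all exposure betas equal: intercept and slope collinear")

    X = sm.add_constant(bx) if fit_intercept else bx[:, None]
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    dof = k - X.shape[1]
    # statsmodels always scales cov by RSS_w/dof; re-derive the unscaled
    # covariance and apply the never-deflate rule.
    resid_w = np.sum((by - fit.fittedvalues) ** 2 / sy**2)
    sigma2 = resid_w / dof if dof > 0 else 1.0
    cov_unscaled = fit.cov_params() / fit.scale
    scale = max(1.0, sigma2)
    cov = cov_unscaled * scale

    if fit_intercept:
        intercept, slope = fit.params
        se_int, se_slope = np.sqrt(np.diag(cov))
    else:
        slope = fit.params[0]
        se_slope = float(np.sqrt(cov[0, 0]))
        intercept, se_int = float("nan"), float("nan")
    p_slope = float(2.0 * stats.norm.sf(abs(slope) / se_slope))
    p_int = (
        float(2.0 * stats.norm.sf(abs(intercept) / se_int)) if fit_intercept else float("nan")
    )
    res = MRResult(
        protein_id, "egger", float(slope), float(se_slope), p_slope, k, analysis_mode,
        egger_intercept=float(intercept), egger_intercept_p=p_int,
    )
    res.extra["rss_weighted"] = float(resid_w)
    return res


def weighted_median_estimate(b: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by piecewise-linear interpolation of the CDF.

    Order the ratio estimates ascending; with normalized weights w_i the
    cumulative weight assigned to order statistic i is
    ``s_i = sum_{j<=i} w_j - w_i / 2``; the estimate is the value where the
    piecewise-linear interpolant through (s_i, b_(i)) crosses 1/2.
    """
    order = np.argsort(b, kind="stable")
    b = np.asarray(b, float)[order]
    w = np.asarray(w, float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    if 0.5 <= s[0]:
        return float(b[0])
    if 0.5 >= s[-1]:
        return float(b[-1])
    return float(np.interp(0.5, s, b))


def weighted_median(
    pairs: pd.DataFrame, *, n_boot: int = 1000, seed: int = 0,
    second_order: bool = False, protein_id: str = "",
    analysis_mode: str = "cis_plus_trans",
) -> MRResult:
    """Weighted-median estimator, consistent with up to 50% invalid weight.

    The SE comes from a seeded parametric bootstrap: ratios are resampled
    from ``Normal(b_i, se_i)`` ``n_boot`` times and the SD of the resampled
    medians is reported.
    """
    k = len(pairs)
    if k < 3:
        raise TooFewInstruments("weighted median needs >= 3 instruments")
    b, se = _ratios(pairs, second_order)
    w = 1.0 / se**2
    est = weighted_median_estimate(b, w)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    draws = rng.normal(b, se, size=(n_boot, k))
    boot = np.array([weighted_median_estimate(row, w) for row in draws])
    s = float(np.std(boot, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(est) / s)) if s > 0 else (1.0 if est == 0 else 0.0)
    res = MRResult(protein_id, "weighted_median", est, s, p, k, analysis_mode)
    res.extra["n_boot"] = n_boot
    return res


def run_all_methods(
    pairs: pd.DataFrame, *, protein_id: str = "", analysis_mode: str = "cis_plus_trans",
    n_boot: int = 1000, seed: int = 0,
) -> dict[str, MRResult]:
    """Run every applicable estimator on one protein's harmonized pairs.

    With a single pair only the Wald ratio is returned; with two pairs IVW
    joins it; with three or more, Egger and the weighted median as well.
    """
    pairs = usable_pairs(pairs)
    k = len(pairs)
    if k == 0:
        raise TooFewInstruments("no usable harmonized pairs")
    out: dict[str, MRResult] = {}
    if k == 1:
        out["wald_ratio"] = wald_ratio(
            pairs, protein_id=protein_id, analysis_mode=analysis_mode
        )
        return out
    out["ivw"] = ivw(pairs, protein_id=protein_id, analysis_mode=analysis_mode)
    if k >= 3:
        try:
            out["egger"] = mr_egger(pairs, protein_id=protein_id, analysis_mode=analysis_mode)
        except DegenerateDesign:
            pass
        out["weighted_median"] = weighted_median(
            pairs, n_boot=n_boot, seed=seed, protein_id=protein_id, analysis_mode=analysis_mode
        )
    return out


def results_to_frame(results: list[MRResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = {k: v for k, v in r.__dict__.items() if k != "extra"}
        rows.append(d)
    return pd.DataFrame(rows)
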