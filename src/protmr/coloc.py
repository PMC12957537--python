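"""Bayesian colocalization of two association signals in one LD region.

Per-SNP evidence is the Wakefield approximate Bayes factor. For a variant
with estimated effect ``beta``, variance ``V = se^2`` and prior effect
variance ``W``::

    log ABF = 1/2 log(V / (V + W)) + 1/2 z^2 W / (V + W),   z = beta / se

Under the single-causal-variant assumption the five hypotheses are H0 (no
causal variant for either trait), H1/H2 (one trait only), H3 (both traits,
distinct variants) and H4 (both traits, one shared variant). Their
unnormalized evidence combines the per-SNP ABFs with the priors p1, p2, p12
and is assembled entirely in log space for numerical stability. Strong
colocalization is a posterior for H4 above 0.8.

Caveat: a real locus may contain several causal variants per trait, which
this model does not represent; H4 support then reflects only the dominant
shared signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class ColocPriors:
    """Per-SNP causality priors and prior effect variances.

    Defaults are the published defaults of the ABF colocalization
    framework for quantitative traits: p1 = p2 = 1e-4, p12 = 1e-5, and a
    prior effect SD of 0.15 per trait (W = 0.0225).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = 0.15**2
    w2: float = 0.15**2

    def validate(self) -> None:
        if self.p1 <= 0 or self.p2 <= 0:
            raise ConfigError("priors p1 and p2 must be positive")
        if self.p12 < 0 or self.p12 > min(self.p1, self.p2):
            raise ConfigError("p12 must satisfy 0 <= p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ConfigError("p1 + p2 + p12 must be < 1")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ConfigError("prior effect variances must be positive")


@dataclass
class ColocResult:
    region_id: str
    n_snps: int
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float

    @property
    def strong_coloc(self) -> bool:
        return self.pp_h4 > 0.8

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])

    @property
    def best_hypothesis(self) -> str:
        return f"H{int(np.argmax(self.posteriors))}"


def log_abf(beta, se, W: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor (H1 vs H0) per variant."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    V = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + 0.5 * z2 * W / (V + W)


def define_region(
    index_variant: str,
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    *,
    window_bp: int = 1_000_000,
) -> list[str]:
    """Variants present in both traits within the window centred on the index.

    ``window_bp`` is the total span (default 1 Mb, i.e. +/- 500 kb around
    the index pQTL); pass 2_000_000 for a +/- 1 Mb reading.
    """
    idx = exposure.loc[exposure["variant_id"] == index_variant]
    if idx.empty:
        raise ValueError(f"index variant {index_variant} not in exposure stats")
    chrom = str(idx["chromosome"].iloc[0])
    pos = int(idx["position"].iloc[0])
    half = window_bp // 2
    keep_exp = exposure.loc[
        (exposure["chromosome"].astype(str) == chrom)
        & (exposure["position"] >= pos - half)
        & (exposure["position"] <= pos + half),
        "variant_id",
    ]
    shared = set(keep_exp) & set(outcome["variant_id"])
    region = exposure.loc[exposure["variant_id"].isin(shared)]
    region = region.sort_values("position")["variant_id"].tolist()
    if len(region) < 2:
        logger.warning(
            "region around %s has %d shared variant(s); colocalization skipped",
            index_variant, len(region),
        )
    return region


def coloc_posteriors(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    priors: ColocPriors | None = None,
    *,
    region_id: str = "",
) -> ColocResult:
    """Posterior probabilities of H0–H4 for one region.

    ``exposure`` and ``outcome`` must share at least one variant_id; with a
    single shared variant H3 is structurally impossible and its posterior
    is exactly 0. Evidence sums use log-sum-exp throughout.
    """
    priors = priors or ColocPriors()
    priors.validate()
    merged = exposure.merge(outcome, on="variant_id", suffixes=("_exp", "_out"))
    if merged.empty:
        raise ValueError("no shared variants between traits in region")
    la1 = log_abf(merged["beta_exp"], merged["se_exp"], priors.w1)
    la2 = log_abf(merged["beta_out"], merged["se_out"], priors.w2)

    ls1 = logsumexp(la1)  # log sum_j ABF1_j
    ls2 = logsumexp(la2)
    ls12 = logsumexp(la1 + la2)  # log sum_j ABF1_j ABF2_j

    log_s = np.full(5, -np.inf)
    log_s[0] = 0.0
    log_s[1] = np.log(priors.p1) + ls1
    log_s[2] = np.log(priors.p2) + ls2
    # H3: sum over ordered pairs i != j = (sum1)(sum2) - sum of products
    cross = ls1 + ls2
    diff = ls12 - cross
    if diff < 0:
        log_s[3] = np.log(priors.p1) + np.log(priors.p2) + cross + np.log1p(-np.exp(diff))
    if priors.p12 > 0:
        log_s[4] = np.log(priors.p12) + ls12

    pp = np.exp(log_s - logsumexp(log_s))
    pp = pp / pp.sum()
    return ColocResult(region_id, len(merged), *map(float, pp))


def results_to_frame(results: list[ColocResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = dict(r.__dict__)
        d["strong_coloc"] = r.strong_coloc
        d["best_hypothesis"] = r.best_hypothesis
        rows.append(d)
    return pd.DataFrame(rows)
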