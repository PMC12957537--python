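"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly on the summary-statistic scale — no
individual-level genotypes — because every downstream stage (instrument
selection, MR, colocalization, Steiger) consumes only summary data, and the
summary-level sampling model is exact for standardized traits:

* Both traits are standardized (variance 1), so a variant with effect
  ``beta`` (per allele) and effect-allele frequency ``f`` explains
  ``2 f (1 - f) beta^2`` of the trait variance, and the standard error of the
  marginal estimate is ``1 / sqrt(2 n f (1 - f))``.
* LD within a locus follows an AR(1) correlation: adjacent SNPs have
  correlation ``rho``, SNPs ``d`` apart have correlation ``rho^d`` and hence
  r-squared ``rho^(2 d)``. Marginal effects are the LD-propagated causal
  effects, ``beta_marginal_i = sum_j rho^|i-j| beta_causal_j``.
* Estimated betas are the marginal betas plus independent normal noise with
  the analytic SE; p-values are exact two-sided normal tails of beta/se.

Violation mechanisms mirror the threats the sensitivity ladder targets:
directional horizontal pleiotropy (direct SNP-to-outcome effects with
nonzero mean, defined relative to the exposure-raising allele so the bias
does not cancel across loci), balanced pleiotropy (mean zero), a
``pleiotropy_frac`` knob limiting the share of invalid instruments, and
reverse causation (the variant acts on the outcome, which in turn drives
the measured protein).
Colocalization scenarios H0–H4 place zero, one-trait-only, distinct, or
shared causal variants in a single LD region.

A single global seed plus a replicate index feeds a
:class:`numpy.random.SeedSequence` spawn-key substream, so any replicate is
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io import SUMMARY_COLUMNS, LDTable

COLOC_SCENARIOS = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class SimulationConfig:
    """Parameters of the two-sample summary-statistic generator.

    Defaults target a comfortably strong-instrument regime: per-allele causal
    effects of 0.15–0.25 SD at MAF 0.1–0.5 give exposure F-statistics well
    above 10 at ``n_exposure = 10,000``, matching the study-design premise
    that weak-instrument bias is negligible.
    """

    n_exposure: int = 10_000
    n_outcome: int = 100_000
    n_loci: int = 10
    snps_per_locus: int = 10
    ld_decay_rho: float = 0.7
    maf_range: tuple[float, float] = (0.10, 0.50)
    true_protein_effect: float = 0.2
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 1.0
    reverse_effect: float = 0.0
    coloc_scenario: Literal["H0", "H1", "H2", "H3", "H4"] = "H4"
    seed: int = 0
    # magnitude range of per-allele causal effects on the locus's driving trait
    causal_beta_range: tuple[float, float] = (0.15, 0.25)
    reverse_beta_range: tuple[float, float] = (0.30, 0.40)

    def validate(self) -> None:
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise ValueError("n_exposure and n_outcome must be >= 100")
        if self.snps_per_locus < 1 or self.n_loci < 1:
            raise ValueError("n_loci and snps_per_locus must be >= 1")
        if not (0.0 <= self.ld_decay_rho < 1.0):
            raise ValueError("ld_decay_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise ValueError("maf_range must lie within [0.01, 0.5]")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if self.coloc_scenario not in COLOC_SCENARIOS:
            raise ValueError(f"coloc_scenario must be one of {COLOC_SCENARIOS}")


def _rng(seed: int, *spawn) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(spawn)))


def analytic_se(n, maf) -> np.ndarray:
    """SE of a marginal per-allele effect on a standardized trait."""
    return 1.0 / np.sqrt(2.0 * np.asarray(n, dtype=float) * maf * (1.0 - maf))


def _pvalue(beta, se) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta / se))


def _stats_frame(variant_ids, chroms, positions, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": chroms,
            "position": positions,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": _pvalue(beta, se),
            "n": int(n),
        }
    )[SUMMARY_COLUMNS]


def ar1_corr(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_two_sample(config: SimulationConfig):
    """Generate exposure and outcome summary statistics for one protein.

    Returns ``(exposure, outcome, ld, truth)``: two canonical summary frames,
    the exact AR(1) LD table, and a truth record of all latent quantities.

    Each locus carries one causal variant. In the forward mode
    (``reverse_effect == 0``) the variant affects the protein directly and
    the outcome through the protein (plus any direct pleiotropic effect); in
    the reverse mode it affects the outcome directly and the measured
    protein only through the outcome, scaled by ``reverse_effect``.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    m = config.snps_per_locus
    R = ar1_corr(m, config.ld_decay_rho)

    frames_exp, frames_out, ld_rows, causal = [], [], [], []
    reverse = config.reverse_effect != 0.0
    for locus in range(config.n_loci):
        chrom = str(locus + 1)
        positions = 10_000_000 + 10_000 * np.arange(m)
        vids = [f"rs{locus + 1}_{i + 1}" for i in range(m)]
        maf = rng.uniform(*config.maf_range, size=m)
        c = int(rng.integers(m))  # causal SNP index
        sign = rng.choice([-1.0, 1.0])

        b_causal = np.zeros(m)
        g_causal = np.zeros(m)  # direct (not protein-mediated) outcome effects
        if reverse:
            g_causal[c] = sign * rng.uniform(*config.reverse_beta_range)
            b_causal[c] = config.reverse_effect * g_causal[c]
        else:
            b_causal[c] = sign * rng.uniform(*config.causal_beta_range)
            pleiotropic = (config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0) and (
                locus < round(config.pleiotropy_frac * config.n_loci)
            )
            if pleiotropic:
                # directional pleiotropy is defined w.r.t. the
                # exposure-raising allele, hence the sign alignment
                g_causal[c] = sign * rng.normal(config.pleiotropy_mean, config.pleiotropy_sd)

        beta_exp = R @ b_causal
        if reverse:
            beta_out = R @ g_causal
        else:
            beta_out = config.true_protein_effect * beta_exp + R @ g_causal

        se_exp = analytic_se(config.n_exposure, maf)
        se_out = analytic_se(config.n_outcome, maf)
        bhat_exp = beta_exp + rng.normal(0.0, se_exp)
        bhat_out = beta_out + rng.normal(0.0, se_out)

        frames_exp.append(
            _stats_frame(vids, chrom, positions, maf, bhat_exp, se_exp, config.n_exposure)
        )
        frames_out.append(
            _stats_frame(vids, chrom, positions, maf, bhat_out, se_out, config.n_outcome)
        )
        for i in range(m):
            for j in range(i + 1, m):
                ld_rows.append((vids[i], vids[j], config.ld_decay_rho ** (2 * (j - i))))
        causal.append(
            {
                "locus": locus,
                "variant_id": vids[c],
                "beta_exposure_causal": float(b_causal[c]),
                "beta_outcome_direct": float(g_causal[c]),
            }
        )

    truth = {
        "config": asdict(config),
        "mode": "reverse" if reverse else "forward",
        "true_protein_effect": config.true_protein_effect,
        "causal_variants": causal,
    }
    exposure = pd.concat(frames_exp, ignore_index=True)
    outcome = pd.concat(frames_out, ignore_index=True)
    return exposure, outcome, LDTable.from_pairs(ld_rows), truth


# ---------------------------------------------------------------------------
# Colocalization scenario regions


def simulate_coloc_region(
    scenario: str,
    n_snps: int = 50,
    seed: int = 0,
    *,
    n_samples: int = 50_000,
    ld_decay_rho: float = 0.6,
    causal_beta: float = 0.15,
    maf_range: tuple[float, float] = (0.10, 0.50),
):
    """Generate one LD region under a colocalization hypothesis H0–H4.

    H0: no causal variant for either trait. H1/H2: one causal variant for
    the exposure/outcome only. H3: two distinct causal variants placed at
    the region ends so their AR(1) r-squared is minimal (low LD). H4: one
    shared causal variant. Returns ``(exposure, outcome, truth)``.
    """
    if scenario not in COLOC_SCENARIOS:
        raise ValueError(f"scenario must be one of {COLOC_SCENARIOS}")
    if n_snps < 2 and scenario == "H3":
        raise ValueError("H3 requires at least 2 SNPs for distinct causal variants")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")

    rng = _rng(seed, 1)
    R = ar1_corr(n_snps, ld_decay_rho)
    maf = rng.uniform(*maf_range, size=n_snps)
    positions = 50_000_000 + 5_000 * np.arange(n_snps)
    vids = [f"rs_c{i + 1}" for i in range(n_snps)]

    mid = n_snps // 2
    b1 = np.zeros(n_snps)  # causal effects on exposure
    b2 = np.zeros(n_snps)  # causal effects on outcome
    if scenario == "H1":
        b1[mid] = causal_beta
        causal1, causal2 = [vids[mid]], []
    elif scenario == "H2":
        b2[mid] = causal_beta
        causal1, causal2 = [], [vids[mid]]
    elif scenario == "H3":
        b1[0] = causal_beta
        b2[n_snps - 1] = causal_beta
        causal1, causal2 = [vids[0]], [vids[n_snps - 1]]
    elif scenario == "H4":
        b1[mid] = causal_beta
        b2[mid] = causal_beta
        causal1, causal2 = [vids[mid]], [vids[mid]]
    else:  # H0
        causal1, causal2 = [], []

    se = analytic_se(n_samples, maf)
    bhat1 = R @ b1 + rng.normal(0.0, se)
    bhat2 = R @ b2 + rng.normal(0.0, se)
    exposure = _stats_frame(vids, "1", positions, maf, bhat1, se, n_samples)
    outcome = _stats_frame(vids, "1", positions, maf, bhat2, se, n_samples)
    truth = {
        "scenario": scenario,
        "causal_exposure": causal1,
        "causal_outcome": causal2,
        "pairwise_r2_causal": (
            float(ld_decay_rho ** (2 * (n_snps - 1))) if scenario == "H3" else None
        ),
    }
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# Multi-protein study for the end-to-end pipeline


@dataclass
class StudyConfig:
    """A synthetic proteomic study: many proteins, a handful causal.

    Each protein gets ``loci_per_protein`` independent pQTL loci; the first
    locus hosts the protein's coding gene (its pQTL is cis), the rest are
    trans. The first ``n_causal`` proteins have a true causal effect
    ``true_effect`` on the shared outcome; the rest are null.
    """

    n_proteins: int = 20
    n_causal: int = 3
    true_effect: float = 0.2
    n_exposure: int = 10_000
    n_outcome: int = 100_000
    # five independent loci per protein with a wide effect-size spread so
    # the ladder's fallbacks (weighted median, Egger) stay identifiable
    # whenever a heterogeneity or pleiotropy flag promotes them
    loci_per_protein: int = 10
    causal_beta_range: tuple[float, float] = (0.10, 0.40)
    snps_per_locus: int = 10
    ld_decay_rho: float = 0.7
    seed: int = 0
    study_id: str = "synthetic_study"
    extra: dict = field(default_factory=dict)


def simulate_study(config: StudyConfig):
    """Generate a complete multi-protein two-sample dataset.

    Returns a dict with keys ``exposure`` (long frame with a protein_id
    column), ``outcome``, ``ld`` (:class:`LDTable`), ``genes`` (annotation
    frame), and ``truth``.
    """
    exp_frames, out_frames, ld_rows, genes, truth_proteins = [], [], [], [], []
    m = config.snps_per_locus
    R = ar1_corr(m, config.ld_decay_rho)

    for p in range(config.n_proteins):
        protein = f"PROT{p + 1:03d}"
        effect = config.true_effect if p < config.n_causal else 0.0
        rng = _rng(config.seed, 2, p)
        causal_records = []
        for locus in range(config.loci_per_protein):
            gl = p * config.loci_per_protein + locus
            chrom = str(gl % 22 + 1)
            base = 5_000_000 + 20_000_000 * (gl // 22)
            positions = base + 10_000 * np.arange(m)
            vids = [f"rs_p{p + 1}_{locus + 1}_{i + 1}" for i in range(m)]
            maf = rng.uniform(0.10, 0.50, size=m)
            c = int(rng.integers(m))
            b_causal = np.zeros(m)
            b_causal[c] = rng.choice([-1.0, 1.0]) * rng.uniform(*config.causal_beta_range)
            beta_exp = R @ b_causal
            beta_out = effect * beta_exp
            se_exp = analytic_se(config.n_exposure, maf)
            se_out = analytic_se(config.n_outcome, maf)
            fe = _stats_frame(
                vids, chrom, positions, maf,
                beta_exp + rng.normal(0.0, se_exp), se_exp, config.n_exposure,
            )
            fe.insert(0, "protein_id", protein)
            fe.insert(1, "study_id", config.study_id)
            exp_frames.append(fe)
            out_frames.append(
                _stats_frame(
                    vids, chrom, positions, maf,
                    beta_out + rng.normal(0.0, se_out), se_out, config.n_outcome,
                )
            )
            for i in range(m):
                for j in range(i + 1, m):
                    ld_rows.append((vids[i], vids[j], config.ld_decay_rho ** (2 * (j - i))))
            if locus == 0:
                genes.append(
                    {
                        "gene_id": f"GENE{p + 1:03d}",
                        "uniprot_id": protein,
                        "chromosome": chrom,
                        "start": int(positions[0]),
                        "end": int(positions[-1]),
                    }
                )
            causal_records.append(
                {"locus": locus, "variant_id": vids[c], "beta_exposure": float(b_causal[c])}
            )
        truth_proteins.append(
            {"protein_id": protein, "true_effect": effect, "causal_variants": causal_records}
        )

    return {
        "exposure": pd.concat(exp_frames, ignore_index=True),
        "outcome": pd.concat(out_frames, ignore_index=True),
        "ld": LDTable.from_pairs(ld_rows),
        "genes": pd.DataFrame(genes),
        "truth": {"config": asdict(config), "proteins": truth_proteins},
    }
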