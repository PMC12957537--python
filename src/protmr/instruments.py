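"""Instrument (pQTL) selection: significance, MHC exclusion, LD clumping,
cross-protein pleiotropy filtering, and cis/trans classification.

The selection chain runs in a fixed, logged order — significance threshold,
MHC exclusion, per-protein LD clumping, then the cross-protein pleiotropy
filter — and each step only removes rows, so record counts are monotone
non-increasing through the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LDTable

logger = logging.getLogger(__name__)


@dataclass
class InstrumentSelectionConfig:
    """Thresholds and windows for pQTL instrument selection.

    The MHC region defaults to chromosome 6, 26–34 Mb (inclusive bounds);
    clumping prunes pairs with r2 > 0.01 within 500 kb; variants
    instrumenting five or more proteins are discarded as pleiotropic; a
    pQTL within 500 kb of its protein's coding gene is cis.
    """

    p_threshold: float = 5e-8
    mhc_chrom: str = "6"
    mhc_start_bp: int = 26_000_000
    mhc_end_bp: int = 34_000_000
    clump_r2: float = 0.01
    clump_window_bp: int = 500_000
    max_proteins_per_snp: int = 4  # exclude at >= max_proteins_per_snp + 1
    cis_window_bp: int = 500_000
    pleiotropy_filter_before_clumping: bool = False

    def validate(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0.0 < self.clump_r2 < 1.0):
            raise ValueError("clump_r2 must be in (0, 1)")
        for name in ("clump_window_bp", "cis_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mhc_start_bp > self.mhc_end_bp:
            raise ValueError("mhc_start_bp must be <= mhc_end_bp")


def filter_significant(records: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Retain records with ``pvalue <= p_threshold`` (inclusive boundary)."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    return records.loc[records["pvalue"] <= p_threshold].reset_index(drop=True)


def filter_mhc(records: pd.DataFrame, config: InstrumentSelectionConfig) -> pd.DataFrame:
    """Remove records inside the MHC region (inclusive bounds on both ends)."""
    in_mhc = (
        (records["chromosome"].astype(str) == str(config.mhc_chrom))
        & (records["position"] >= config.mhc_start_bp)
        & (records["position"] <= config.mhc_end_bp)
    )
    if in_mhc.any():
        logger.info("MHC exclusion removed %d variant(s)", int(in_mhc.sum()))
    return records.loc[~in_mhc].reset_index(drop=True)


def ld_clump(
    records: pd.DataFrame, ld: LDTable, config: InstrumentSelectionConfig
) -> pd.DataFrame:
    """Greedy index-SNP LD clumping for one protein within one study.

    Sort by ascending p-value (ties broken lexicographically on variant_id
    for determinism); accept the best remaining record; discard every
    remaining record on the same chromosome within ``clump_window_bp`` whose
    r2 with the accepted record exceeds ``clump_r2``; repeat. Any two
    survivors within the window therefore have r2 <= clump_r2. A pair
    missing from the LD table is treated as r2 = 0 (kept) with a warning,
    which is conservative for the instrument count but surfaces LD coverage
    gaps in the log.
    """
    if records.empty:
        return records.reset_index(drop=True)
    ordered = records.sort_values(
        ["pvalue", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    vid = ordered["variant_id"].to_numpy()
    chrom = ordered["chromosome"].to_numpy()
    pos = ordered["position"].to_numpy(dtype=np.int64)
    n = len(ordered)
    alive = np.ones(n, dtype=bool)
    accepted: list[int] = []
    warned_missing = 0
    for i in range(n):
        if not alive[i]:
            continue
        accepted.append(i)
        for j in range(i + 1, n):
            if not alive[j] or chrom[j] != chrom[i]:
                continue
            if abs(int(pos[j]) - int(pos[i])) > config.clump_window_bp:
                continue
            r2 = ld.r2(vid[i], vid[j])
            if r2 == 0.0 and frozenset((vid[i], vid[j])) not in ld._pairs:
                warned_missing += 1
            if r2 > config.clump_r2:
                alive[j] = False
    if warned_missing:
        logger.warning(
            "ld_clump: %d in-window pair(s) missing from the LD table; "
            "treated as r2 = 0 (both kept)",
            warned_missing,
        )
    out = ordered.loc[accepted]
    return out.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)


def filter_pleiotropic_snps(
    candidates: pd.DataFrame, config: InstrumentSelectionConfig
) -> pd.DataFrame:
    """Drop variants instrumenting more than ``max_proteins_per_snp`` proteins.

    ``candidates`` is the pooled per-study candidate table with a
    ``protein_id`` column; a variant linked to at least
    ``max_proteins_per_snp + 1`` distinct proteins (default: five or more)
    is removed from every protein's set.
    """
    counts = candidates.groupby("variant_id")["protein_id"].nunique()
    bad = set(counts.index[counts > config.max_proteins_per_snp])
    if bad:
        logger.info(
            "pleiotropy filter removed %d variant(s) shared by >= %d proteins",
            len(bad),
            config.max_proteins_per_snp + 1,
        )
    return candidates.loc[~candidates["variant_id"].isin(bad)].reset_index(drop=True)


def classify_cis_trans(
    chromosome: str, position: int, gene: pd.Series | dict | None,
    config: InstrumentSelectionConfig,
) -> str:
    """Classify one pQTL as ``cis``, ``trans`` or ``unknown``.

    Cis means same chromosome and position within
    ``[gene start - cis_window_bp, gene end + cis_window_bp]`` (the window is
    measured from the gene body, not the TSS). No annotation means
    ``unknown`` — excluded from cis-only analyses.
    """
    if gene is None:
        return "unknown"
    if str(chromosome) != str(gene["chromosome"]):
        return "trans"
    lo = int(gene["start"]) - config.cis_window_bp
    hi = int(gene["end"]) + config.cis_window_bp
    return "cis" if lo <= int(position) <= hi else "trans"


def select_instruments(
    exposure: pd.DataFrame,
    ld: LDTable,
    genes: pd.DataFrame,
    config: InstrumentSelectionConfig | None = None,
) -> pd.DataFrame:
    """Run the full selection chain on a long exposure frame.

    ``exposure`` must carry ``protein_id`` and ``study_id`` columns in
    addition to the canonical summary-statistic columns. Returns the
    instrument table with a ``cis_trans`` column, one row per retained pQTL.
    """
    config = config or InstrumentSelectionConfig()
    config.validate()
    gene_by_protein = (
        {row["uniprot_id"]: row for _, row in genes.iterrows()} if genes is not None else {}
    )

    stage = filter_significant(exposure, config.p_threshold)
    logger.info("significance filter: %d -> %d", len(exposure), len(stage))
    stage = filter_mhc(stage, config)

    if config.pleiotropy_filter_before_clumping:
        stage = filter_pleiotropic_snps(stage, config)

    clumped = []
    for (protein, study), grp in stage.groupby(["protein_id", "study_id"], sort=True):
        clumped.append(ld_clump(grp, ld, config))
    stage = (
        pd.concat(clumped, ignore_index=True)
        if clumped
        else stage.iloc[0:0].reset_index(drop=True)
    )

    if not config.pleiotropy_filter_before_clumping:
        stage = filter_pleiotropic_snps(stage, config)

    cis_trans = [
        classify_cis_trans(
            row["chromosome"], row["position"], gene_by_protein.get(row["protein_id"]), config
        )
        for _, row in stage.iterrows()
    ]
    stage = stage.assign(cis_trans=cis_trans)
    n_unknown = sum(1 for c in cis_trans if c == "unknown")
    if n_unknown:
        logger.warning("%d instrument(s) without gene annotation -> cis_trans unknown", n_unknown)
    return stage
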