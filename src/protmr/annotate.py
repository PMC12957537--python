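"""Post-MR annotation: protein-altering variants, eQTL overlap, druggability.

These layers are pure classifications over user-provided lookup tables —
variant consequence annotations, tissue eQTL summaries, druggable-genome
tiers and therapeutic-target registrations — joined onto the prioritized
proteins without ever dropping or duplicating them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .io import LDTable, ValidationError, _require_columns

#: Variant consequences counted as protein-altering: coding-sequence,
#: frameshift, in-frame indel, missense, splice-site, and start/stop changes.
PAV_CONSEQUENCES = frozenset(
    {
        "coding_sequence_variant",
        "frameshift",
        "inframe_deletion",
        "inframe_insertion",
        "missense",
        "splice_acceptor",
        "splice_donor",
        "splice_region",
        "start_lost",
        "stop_lost",
        "stop_gained",
        "start_gained",
    }
)

DRUGGABILITY_TIERS = ("Tier1", "Tier2", "Tier3A", "Tier3B", "none")
TTD_TARGET_TYPES = (
    "successful",
    "clinical_trial",
    "literature_reported",
    "patented_recorded",
    "none",
)


def read_consequence_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["variant_id", "consequence"], str(path))
    unknown = set(df["consequence"]) - PAV_CONSEQUENCES
    if unknown:
        raise ValidationError(f"{path}: unknown consequence terms: {sorted(unknown)}")
    return df


def flag_pav(
    variant_id: str,
    consequences: pd.DataFrame,
    ld: LDTable,
    *,
    r2_proxy: float = 0.8,
) -> tuple[bool, list[str]]:
    """Is this cis-pQTL a PAV, or in LD (r2 >= r2_proxy) with one?

    Returns the flag and the supporting PAV variant list (the variant
    itself first when it is a direct hit).
    """
    pav_variants = consequences.loc[
        consequences["consequence"].isin(PAV_CONSEQUENCES), "variant_id"
    ].unique()
    support = [v for v in pav_variants if v == variant_id or ld.r2(variant_id, v) >= r2_proxy]
    support.sort(key=lambda v: (v != variant_id, v))
    return bool(support), support


def read_eqtl_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene_id": str, "tissue": str})
    _require_columns(
        df, ["variant_id", "gene_id", "tissue", "beta_expression", "significant"], str(path)
    )
    df["beta_expression"] = df["beta_expression"].astype(float)
    df["significant"] = df["significant"].astype(str).str.lower().isin(["true", "1", "yes"])
    return df


def eqtl_overlap(
    variant_id: str,
    gene_id: str,
    protein_beta_sign: float,
    eqtls: pd.DataFrame,
    ld: LDTable,
    *,
    r2_proxy: float = 0.8,
) -> str:
    """Overlap status of one cis-pQTL with eQTLs of its gene.

    Considers the variant and any proxy at r2 >= r2_proxy with a
    significant eQTL for ``gene_id``. Expression betas in the input table
    must be oriented to the pQTL's effect allele; ``overlap_consistent``
    requires the expression and protein effects to share a sign, a sign
    clash yields ``overlap_inconsistent``, and no significant eQTL in the
    proxy set yields ``none``.
    """
    hits = eqtls.loc[(eqtls["gene_id"] == gene_id) & eqtls["significant"]]
    if hits.empty:
        return "none"
    in_ld = hits.loc[
        [v == variant_id or ld.r2(variant_id, v) >= r2_proxy for v in hits["variant_id"]]
    ]
    if in_ld.empty:
        return "none"
    consistent = np.sign(in_ld["beta_expression"]) == np.sign(protein_beta_sign)
    return "overlap_consistent" if consistent.any() else "overlap_inconsistent"


def read_druggability_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("none")
    _require_columns(df, ["uniprot_id", "tier"], str(path))
    bad = set(df["tier"]) - set(DRUGGABILITY_TIERS)
    if bad:
        raise ValidationError(f"{path}: unknown tier value(s): {sorted(bad)}")
    if "ttd_target_type" in df.columns:
        bad = set(df["ttd_target_type"]) - set(TTD_TARGET_TYPES)
        if bad:
            raise ValidationError(f"{path}: unknown target type(s): {sorted(bad)}")
    return df


def map_druggability(
    proteins: pd.DataFrame,
    druggability: pd.DataFrame | None,
    ttd: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Left-join druggable-genome tiers and therapeutic-target types.

    ``proteins`` must carry ``uniprot_id``; every input row is preserved
    exactly once. Unmatched proteins get tier / target type ``none``.
    Returns the annotated frame and a dict of per-tier and per-target-type
    counts (over matched proteins only).
    """
    out = proteins.copy()
    for source, col in ((druggability, "tier"), (ttd, "ttd_target_type")):
        if source is not None and not source.empty and col in source.columns:
            sub = source[["uniprot_id", col]].drop_duplicates()
            conflicts = sub["uniprot_id"].duplicated(keep=False)
            if conflicts.any():
                raise ValidationError(
                    f"conflicting {col} assignments for "
                    f"{sorted(sub.loc[conflicts, 'uniprot_id'].unique())}"
                )
            out = out.merge(sub, on="uniprot_id", how="left")
            out[col] = out[col].fillna("none")
        else:
            out[col] = "none"
    if len(out) != len(proteins):
        raise ValidationError("druggability join changed row count")

    counts = {
        "tier": {t: int((out["tier"] == t).sum()) for t in DRUGGABILITY_TIERS},
        "ttd_target_type": {
            t: int((out["ttd_target_type"] == t).sum()) for t in TTD_TARGET_TYPES
        },
        "ttd_annotated_total": int((out["ttd_target_type"] != "none").sum()),
    }
    return out, counts


# ---------------------------------------------------------------------------
# Bundled reference fixtures


def _data_path(name: str):
    return resources.files("protmr.data").joinpath(name)


def load_prioritized_proteins() -> pd.DataFrame:
    """Bundled reference table of cis-MR-prioritized circulating proteins.

    One row per protein x source-study association with the direction of
    the primary causal estimate on random glucose; proteins replicated in
    more than one proteomic study appear once per study.
    """
    with resources.as_file(_data_path("cis_mr_prioritized_proteins.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_druggability_reference() -> pd.DataFrame:
    """Bundled druggable-genome tier / therapeutic-target reference table."""
    with resources.as_file(_data_path("druggability_annotations.tsv")) as p:
        return read_druggability_table(p)
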