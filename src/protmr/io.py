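"""Readers and writers for GWAS summary statistics, gene annotations and LD tables.

All tabular inputs are tab-separated text with a header row. Genomic
coordinates are 1-based and inclusive throughout the package; callers with
0-based half-open (BED-style) input must add 1 to start positions before
loading.

Summary statistics are carried as :class:`pandas.DataFrame` objects with the
canonical column set in :data:`SUMMARY_COLUMNS`. Validation is strict: rows
that violate a type invariant (non-ACGT alleles, ``se <= 0``, allele
frequency outside (0, 1), p-value outside (0, 1]) are rejected with the
offending line numbers rather than silently coerced.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical summary-statistic columns, one row per variant per trait.
SUMMARY_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Default source-column names (GWAS-SSF-like). Override via ``column_map``.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "variant_id": "rsid",
    "chromosome": "chromosome",
    "position": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n": "n",
}

VALID_ALLELES = frozenset("ACGT")


class ValidationError(ValueError):
    """A row or table violates a domain invariant."""


class ConfigError(ValueError):
    """A configuration value (column map, prior, threshold) is unusable."""


class SummaryStatsWarning(UserWarning):
    """Non-fatal inconsistency in summary statistics (e.g. p vs beta/se)."""


def _require_columns(df: pd.DataFrame, needed, where: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigError(f"{where}: missing mandatory column(s) {missing}")


def validate_summary_stats(df: pd.DataFrame, *, source: str = "<frame>") -> pd.DataFrame:
    """Validate a canonical-column summary-statistics frame.

    Returns the frame with numeric dtypes enforced. Raises
    :class:`ValidationError` listing 1-based data line numbers of bad rows.
    A p-value inconsistent with ``2 * Phi(-|beta/se|)`` by more than 10%
    relative (on the p scale) raises :class:`SummaryStatsWarning` only, since
    published statistics are frequently rounded.

    Missing EAF (NaN) is allowed: those variants keep flowing through the
    pipeline but are excluded from frequency-based palindromic checks and
    from the allele-frequency form of the Steiger variance explained.
    """
    _require_columns(df, SUMMARY_COLUMNS, source)
    df = df[SUMMARY_COLUMNS].copy()
    for col in ("position", "n"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    df["chromosome"] = df["chromosome"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    lineno = np.arange(1, len(df) + 1)
    problems = []

    bad_alleles = ~(
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
    )
    same_alleles = df["effect_allele"] == df["other_allele"]
    bad_se = ~(df["se"] > 0)
    bad_eaf = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
    bad_p = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    bad_n = ~(df["n"] > 0)
    bad_pos = ~(df["position"] > 0)

    for mask, msg in [
        (bad_alleles, "allele not in {A,C,G,T}"),
        (same_alleles, "effect_allele equals other_allele"),
        (bad_se, "se must be > 0"),
        (bad_eaf, "eaf must be in (0, 1)"),
        (bad_p, "pvalue must be in (0, 1]"),
        (bad_n, "n must be a positive integer"),
        (bad_pos, "position must be >= 1"),
    ]:
        if mask.any():
            problems.append(f"{msg} at line(s) {lineno[mask.to_numpy()].tolist()}")
    if problems:
        raise ValidationError(f"{source}: " + "; ".join(problems))

    dup = df["variant_id"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"{source}: duplicated variant_id within one trait: "
            f"{sorted(df.loc[dup, 'variant_id'].unique().tolist())}"
        )

    # p vs z consistency: warn, never reject (rounded p-values are common).
    z = np.abs(df["beta"] / df["se"])
    p_implied = 2.0 * stats.norm.sf(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(df["pvalue"] - p_implied) / np.maximum(p_implied, 1e-300)
    inconsistent = (rel > 0.10) & (p_implied > 1e-300)
    if inconsistent.any():
        idx = lineno[inconsistent.to_numpy()].tolist()
        warnings.warn(
            f"{source}: p-value inconsistent with |beta/se| under the normal "
            f"approximation (>10% relative) at line(s) {idx}",
            SummaryStatsWarning,
            stacklevel=2,
        )
    return df.reset_index(drop=True)


def read_summary_stats(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read one trait's GWAS summary statistics from a TSV file.

    ``column_map`` maps canonical field names (:data:`SUMMARY_COLUMNS`) to the
    source file's column names; unspecified fields fall back to
    :data:`DEFAULT_COLUMN_MAP`, and a source column named exactly like the
    canonical field is always accepted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(SUMMARY_COLUMNS)
        if unknown:
            raise ConfigError(f"column_map refers to unknown fields: {sorted(unknown)}")
        cmap.update(column_map)
    rename = {}
    for field in SUMMARY_COLUMNS:
        if field in raw.columns:
            rename[field] = field
        elif cmap[field] in raw.columns:
            rename[cmap[field]] = field
        else:
            raise ConfigError(
                f"{path}: missing mandatory column for field '{field}' "
                f"(looked for '{cmap[field]}')"
            )
    df = raw.rename(columns=rename)
    try:
        return validate_summary_stats(df, source=str(path))
    except ValueError as exc:
        if isinstance(exc, (ValidationError, ConfigError)):
            raise
        raise ValidationError(f"{path}: non-numeric value ({exc})") from exc


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write a canonical summary-statistics frame as TSV (15 significant digits)."""
    df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.15g")


# ---------------------------------------------------------------------------
# Gene annotations


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table: gene_id, uniprot_id, chromosome, start, end.

    Positions are 1-based inclusive. Duplicate gene_id rows are an error; an
    empty table is allowed with a logged warning.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "uniprot_id": str, "chromosome": str},
    )
    _require_columns(df, ["gene_id", "uniprot_id", "chromosome", "start", "end"], str(path))
    if df.empty:
        logger.warning("%s: empty gene annotation table", path)
        return df.reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] > df["end"]
    if bad.any():
        raise ValidationError(
            f"{path}: start > end for gene(s) {df.loc[bad, 'gene_id'].tolist()}"
        )
    dup = df["gene_id"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate gene_id rows: {sorted(df.loc[dup, 'gene_id'].unique())}"
        )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# LD


@dataclass
class LDTable:
    """Symmetric pairwise r-squared lookup.

    Absent pairs default to r2 = 0; a variant with itself is r2 = 1. Built
    from a long table of (variant_a, variant_b, r2) rows.
    """

    _pairs: dict

    @classmethod
    def from_pairs(cls, records) -> "LDTable":
        pairs = {}
        for a, b, r2 in records:
            r2 = float(r2)
            if not (0.0 <= r2 <= 1.0):
                raise ValidationError(f"r2 outside [0, 1] for pair ({a}, {b}): {r2}")
            pairs[frozenset((a, b)) if a != b else (a,)] = r2
        return cls(pairs)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, r2 in self._pairs.items():
            items = sorted(key)
            a = items[0]
            b = items[1] if len(items) > 1 else items[0]
            rows.append((a, b, r2))
        return pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"])


def read_ld_table(path) -> LDTable:
    """Read a 3-column TSV (variant_a, variant_b, r2) into an :class:`LDTable`."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_a": str, "variant_b": str})
    _require_columns(df, ["variant_a", "variant_b", "r2"], str(path))
    return LDTable.from_pairs(df[["variant_a", "variant_b", "r2"]].itertuples(index=False))


def write_ld_table(ld: LDTable, path) -> None:
    ld.to_frame().to_csv(path, sep="\t", index=False, float_format="%.15g")


# ---------------------------------------------------------------------------
# Run manifest


def write_manifest(path, **entries) -> None:
    """Write a JSON run manifest (inputs, thresholds, seed, versions)."""
    import protmr

    manifest = {"package": "protmr", "version": protmr.__version__}
    manifest.update(entries)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
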