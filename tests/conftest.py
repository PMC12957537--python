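import numpy as np
import pandas as pd
import pytest

from protmr.io import SUMMARY_COLUMNS, LDTable


def make_stats(rows, n=10_000):
    """Build a canonical summary-statistics frame from compact tuples.

    Each row: (variant_id, chrom, pos, ea, oa, eaf, beta, se) with the
    p-value derived exactly from beta/se.
    """
    from scipy import stats as st

    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chromosome", "position", "effect_allele",
            "other_allele", "eaf", "beta", "se",
        ],
    )
    df["pvalue"] = 2 * st.norm.sf(np.abs(df["beta"] / df["se"]))
    df["n"] = n
    return df[SUMMARY_COLUMNS]


def make_pairs(beta_exp, se_exp, beta_out, se_out, eaf=None, n_exp=10_000, n_out=100_000):
    """Build a harmonized-pairs frame directly (all rows 'aligned')."""
    k = len(beta_exp)
    eaf = eaf if eaf is not None else [0.3] * k
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i+1}" for i in range(k)],
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "eaf_exp": eaf,
            "n_exp": n_exp,
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf_out": eaf,
            "n_out": n_out,
            "action": "aligned",
        }
    )


@pytest.fixture
def stats_builder():
    return make_stats


@pytest.fixture
def pairs_builder():
    return make_pairs


@pytest.fixture
def simple_ld():
    return LDTable.from_pairs([("rs1", "rs2", 0.5), ("rs2", "rs3", 0.8)])
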