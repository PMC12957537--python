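import itertools

import numpy as np
import pandas as pd
import pytest

from protmr.instruments import (
    InstrumentSelectionConfig,
    classify_cis_trans,
    filter_mhc,
    filter_pleiotropic_snps,
    filter_significant,
    ld_clump,
    select_instruments,
)
from protmr.io import LDTable

CFG = InstrumentSelectionConfig()


def _records(rows):
    return pd.DataFrame(
        rows, columns=["variant_id", "chromosome", "position", "pvalue"]
    )


class TestSignificance:
    @pytest.mark.parametrize(
        "p,kept", [(4.9e-8, True), (5e-8, True), (1e-6, False)]
    )
    def test_threshold_boundary_inclusive(self, p, kept):
        df = _records([("rs1", "1", 100, p)])
        out = filter_significant(df, 5e-8)
        assert (len(out) == 1) is kept

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_significant(_records([]), 1.5)


class TestMHC:
    @pytest.mark.parametrize(
        "chrom,pos,kept",
        [
            ("6", 30_000_000, False),  # inside 26-34 Mb
            ("6", 25_999_999, True),   # 1 bp below the window
            ("6", 26_000_000, False),  # inclusive lower bound
            ("6", 34_000_000, False),  # inclusive upper bound
            ("6", 34_000_001, True),
            ("7", 30_000_000, True),   # other chromosome
        ],
    )
    def test_mhc_window_boundaries(self, chrom, pos, kept):
        out = filter_mhc(_records([("rs1", chrom, pos, 1e-10)]), CFG)
        assert (len(out) == 1) is kept


def brute_force_clump(records, ld, config):
    """Independent restatement of the greedy rule for small inputs:
    repeatedly take the best remaining p-value and delete its in-window,
    in-LD neighbours, recomputing the remaining set from scratch."""
    remaining = records.sort_values(["pvalue", "variant_id"]).to_dict("records")
    kept = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top["variant_id"])
        remaining = [
            r
            for r in remaining
            if not (
                r["chromosome"] == top["chromosome"]
                and abs(r["position"] - top["position"]) <= config.clump_window_bp
                and ld.r2(r["variant_id"], top["variant_id"]) > config.clump_r2
            )
        ]
    return sorted(kept)


class TestClumping:
    def test_in_window_dependent_pair_keeps_best_p(self):
        df = _records([("rsA", "1", 1_000_000, 1e-10), ("rsB", "1", 1_100_000, 1e-8)])
        ld = LDTable.from_pairs([("rsA", "rsB", 0.5)])
        out = ld_clump(df, ld, CFG)
        assert out["variant_id"].tolist() == ["rsA"]

    def test_outside_window_both_survive(self):
        df = _records([("rsA", "1", 1_000_000, 1e-10), ("rsB", "1", 1_600_000, 1e-8)])
        ld = LDTable.from_pairs([("rsA", "rsB", 0.5)])
        assert len(ld_clump(df, ld, CFG)) == 2

    def test_missing_ld_pair_keeps_both(self):
        df = _records([("rsA", "1", 1_000_000, 1e-10), ("rsB", "1", 1_100_000, 1e-8)])
        assert len(ld_clump(df, LDTable.from_pairs([]), CFG)) == 2

    def test_chained_ld_matches_brute_force_oracle(self):
        # 5 SNPs, AR(1)-style decaying LD, all distinct p-values
        rng = np.random.default_rng(0)
        for _ in range(20):
            pvals = rng.permutation([1e-10, 1e-9, 1e-8, 1e-7, 1e-6])
            df = _records(
                [(f"rs{i}", "1", 1_000_000 + 100_000 * i, pvals[i]) for i in range(5)]
            )
            pairs = [
                (f"rs{i}", f"rs{j}", 0.8 ** abs(i - j))
                for i, j in itertools.combinations(range(5), 2)
            ]
            ld = LDTable.from_pairs(pairs)
            got = sorted(ld_clump(df, ld, CFG)["variant_id"])
            assert got == brute_force_clump(df, ld, CFG)

    def test_survivors_pairwise_independent_and_maximal(self):
        rng = np.random.default_rng(1)
        df = _records(
            [(f"rs{i}", "1", 1_000_000 + 50_000 * i, p)
             for i, p in enumerate(rng.uniform(1e-12, 1e-8, size=8))]
        )
        ld = LDTable.from_pairs(
            [(f"rs{i}", f"rs{j}", 0.6 ** abs(i - j))
             for i, j in itertools.combinations(range(8), 2)]
        )
        out = ld_clump(df, ld, CFG)
        kept = out["variant_id"].tolist()
        for a, b in itertools.combinations(kept, 2):
            pa = int(df.loc[df.variant_id == a, "position"].iloc[0])
            pb = int(df.loc[df.variant_id == b, "position"].iloc[0])
            if abs(pa - pb) <= CFG.clump_window_bp:
                assert ld.r2(a, b) <= CFG.clump_r2
        # maximality: every discarded SNP conflicts with some survivor
        for _, row in df.loc[~df.variant_id.isin(kept)].iterrows():
            assert any(
                abs(int(row.position) - int(df.loc[df.variant_id == k, "position"].iloc[0]))
                <= CFG.clump_window_bp
                and ld.r2(row.variant_id, k) > CFG.clump_r2
                for k in kept
            )

    def test_clumping_recovers_one_representative_per_causal_locus(self):
        from protmr.calibration import _sub_seed
        from protmr.instruments import filter_significant
        from protmr.simulate import SimulationConfig, simulate_two_sample

        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            cfg = SimulationConfig(seed=_sub_seed(23, rep), n_loci=5)
            exposure, _, ld, _ = simulate_two_sample(cfg)
            sig = filter_significant(exposure, 5e-8)
            clumped = ld_clump(sig, ld, CFG)
            if len(clumped) == 5 and clumped["chromosome"].nunique() == 5:
                hits += 1
        assert hits / n_reps >= 0.95


class TestPleiotropyFilter:
    @pytest.mark.parametrize("n_proteins,kept", [(5, False), (4, True), (1, True)])
    def test_five_or_more_proteins_excluded_everywhere(self, n_proteins, kept):
        rows = [("rs_shared", f"P{i}") for i in range(n_proteins)]
        rows.append(("rs_other", "P0"))
        df = pd.DataFrame(rows, columns=["variant_id", "protein_id"])
        out = filter_pleiotropic_snps(df, CFG)
        assert ("rs_shared" in set(out["variant_id"])) is kept
        assert "rs_other" in set(out["variant_id"])


class TestCisTrans:
    GENE = {"chromosome": "1", "start": 1_000_000, "end": 1_010_000}

    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("1", 1_400_000, "cis"),    # inside end + 500 kb
            ("1", 1_510_000, "cis"),    # exactly end + 500 kb
            ("1", 1_510_001, "trans"),  # 1 bp outside
            ("1", 500_000, "cis"),      # exactly start - 500 kb
            ("1", 499_999, "trans"),
            ("2", 1_000_000, "trans"),  # other chromosome
        ],
    )
    def test_window_from_gene_body(self, chrom, pos, expected):
        assert classify_cis_trans(chrom, pos, self.GENE, CFG) == expected

    def test_missing_annotation_is_unknown(self):
        assert classify_cis_trans("1", 1, None, CFG) == "unknown"


class TestChain:
    def test_significance_and_mhc_filters_commute(self):
        rng = np.random.default_rng(5)
        df = _records(
            [(f"rs{i}", rng.choice(["6", "7"]), int(rng.integers(20e6, 40e6)),
              float(rng.uniform(1e-12, 1e-4))) for i in range(50)]
        )
        a = filter_mhc(filter_significant(df, 5e-8), CFG)
        b = filter_significant(filter_mhc(df, CFG), 5e-8)
        pd.testing.assert_frame_equal(
            a.sort_values("variant_id").reset_index(drop=True),
            b.sort_values("variant_id").reset_index(drop=True),
        )

    def test_stage_counts_monotone_non_increasing(self):
        from protmr.simulate import StudyConfig, simulate_study

        study = simulate_study(StudyConfig(n_proteins=5, seed=2))
        exposure, ld = study["exposure"], study["ld"]
        sig = filter_significant(exposure, CFG.p_threshold)
        mhc = filter_mhc(sig, CFG)
        clumped = pd.concat(
            [ld_clump(g, ld, CFG) for _, g in mhc.groupby(["protein_id", "study_id"])],
            ignore_index=True,
        )
        pleio = filter_pleiotropic_snps(clumped, CFG)
        assert len(exposure) >= len(sig) >= len(mhc) >= len(clumped) >= len(pleio)

    def test_select_instruments_labels_cis_and_trans(self):
        from protmr.simulate import StudyConfig, simulate_study

        study = simulate_study(StudyConfig(n_proteins=3, seed=4))
        inst = select_instruments(study["exposure"], study["ld"], study["genes"], CFG)
        assert set(inst["cis_trans"]) <= {"cis", "trans"}
        assert (inst.groupby("protein_id")["cis_trans"]
                .apply(lambda s: (s == "cis").sum()) >= 1).all()
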