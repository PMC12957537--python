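#!/usr/bin/env python
"""Generate the synthetic proteomic study used by the downstream analyses.

Twenty circulating proteins measured in one synthetic cohort (n = 10,000),
each with ten independent pQTL loci (one cis, nine trans), against a
glycemic outcome GWAS (n = 100,000). Three proteins carry a true causal
effect of 0.2 SD outcome per SD protein; the rest are null. Writes the
exposure/outcome summary statistics, LD table, gene annotations and truth
record under results/study/.
"""

import json
from pathlib import Path

from protmr.io import write_ld_table, write_summary_stats
from protmr.simulate import StudyConfig, simulate_study

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 20260926


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = StudyConfig(seed=SEED)
    study = simulate_study(cfg)
    study["exposure"].to_csv(OUT / "exposure.tsv", sep="\t", index=False, float_format="%.15g")
    write_summary_stats(study["outcome"], OUT / "outcome.tsv")
    write_ld_table(study["ld"], OUT / "ld.tsv")
    study["genes"].to_csv(OUT / "genes.tsv", sep="\t", index=False)
    (OUT / "truth.json").write_text(json.dumps(study["truth"], indent=2) + "\n")
    causal = [p["protein_id"] for p in study["truth"]["proteins"] if p["true_effect"]]
    print(f"simulated {cfg.n_proteins} proteins x {cfg.loci_per_protein} loci "
          f"({len(study['exposure'])} exposure records); causal: {', '.join(causal)}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
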