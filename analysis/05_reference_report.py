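#!/usr/bin/env python
"""Tally the bundled reference tables of MR-prioritized proteins.

Counts association rows vs unique proteins in the cis-MR prioritized
table, and druggable-genome tier / therapeutic-target-type totals in the
druggability reference. Writes results/reference_counts.json.
"""

import json
from pathlib import Path

from protmr.annotate import (
    load_druggability_reference,
    load_prioritized_proteins,
    map_druggability,
)
from protmr.pipeline import report_counts

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    prioritized = load_prioritized_proteins()
    counts = report_counts(prioritized)
    print(f"cis-MR prioritized: {counts['association_rows']} association rows, "
          f"{counts['unique_proteins']} unique proteins")

    drug = load_druggability_reference()
    _, dcounts = map_druggability(drug[["uniprot_id"]], drug, drug)
    print("druggability tiers:", dcounts["tier"])
    print("therapeutic target types:", dcounts["ttd_target_type"],
          f"(total annotated: {dcounts['ttd_annotated_total']})")

    payload = {"prioritized": counts, "druggability": dcounts}
    (OUT / "reference_counts.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {OUT / 'reference_counts.json'}")


if __name__ == "__main__":
    main()
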