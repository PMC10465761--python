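#!/usr/bin/env python
"""Score the perturbation library against the disease signature.

Reads results/differential.tsv and results/inputs/perturbation.tsv,
computes each drug's two-sided KS connectivity score and class, and
writes the sorted table (most-reversing first) to
results/connectivity.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from sigreverse import DiseaseSignature, score_library
from sigreverse.connectivity import read_perturbation_matrix, write_connectivity


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--differential", type=Path, default=Path("results/differential.tsv"))
    ap.add_argument("--perturbation", type=Path, default=Path("results/inputs/perturbation.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/connectivity.tsv"))
    args = ap.parse_args()

    diff = pd.read_csv(args.differential, sep="\t")
    hits = diff[diff["direction"].isin(["up", "down"])].sort_values(
        ["p_value", "fold_change", "gene_id"], ascending=[True, False, True]
    )
    signature = DiseaseSignature(
        list(hits.loc[hits["direction"] == "up", "gene_id"]),
        list(hits.loc[hits["direction"] == "down", "gene_id"]),
    )
    profiles = read_perturbation_matrix(args.perturbation)
    result = score_library(signature, profiles)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_connectivity(result, args.out)
    best = result.records[0]
    print(
        f"scored {len(result.records)} drugs: {result.n_negative} negative, "
        f"{result.n_zero} zero, {result.n_positive} positive "
        f"({len(result.skipped)} skipped) -> {args.out}"
    )
    print(f"strongest reverser: {best.drug_id} (score {best.score:.3f})")


if __name__ == "__main__":
    main()
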