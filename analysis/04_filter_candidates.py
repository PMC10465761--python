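#!/usr/bin/env python
"""Push scored drugs through the four-stage candidate funnel.

Connectivity class (keep negative/zero) -> market status (keep
approved/nutraceutical) -> BBB permeability -> strictly better docking
energy than the standard anti-epileptic at all three receptors.
Writes results/funnel.json, results/funnel.tsv and prints the stage
table.
"""

import argparse
from pathlib import Path

import pandas as pd

from sigreverse import (
    ConnectivityRecord,
    build_funnel_report,
    filter_bbb,
    filter_status,
    select_better_than_standard,
    select_by_connectivity,
)
from sigreverse.filtering import DEFAULT_STANDARDS, read_annotations, read_docking


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--connectivity", type=Path, default=Path("results/connectivity.tsv"))
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.connectivity, sep="\t")
    records = [
        ConnectivityRecord(
            r["drug_id"], r["es_up"], r["es_down"], r["score"], r["class"],
            r["n_matched_up"], r["n_matched_down"],
        )
        for r in df.to_dict("records")
    ]
    ann = read_annotations(args.inputs / "annotations.csv")
    dock = read_docking(args.inputs / "docking.csv")

    selected = select_by_connectivity(records)
    safe = filter_status(selected, ann)
    bbb = filter_bbb(safe, ann)
    final, per_receptor = select_better_than_standard(dock, DEFAULT_STANDARDS, drugs=bbb)

    report = build_funnel_report(
        [
            ("scored", {r.drug_id for r in records}),
            ("connectivity", selected),
            ("status", safe),
            ("bbb", bbb),
            ("docking", final),
        ],
        class_of={r.drug_id: r.cls for r in records},
        config={"per_receptor_better": per_receptor},
    )
    args.out.mkdir(parents=True, exist_ok=True)
    report.to_json(args.out / "funnel.json")
    report.to_tsv(args.out / "funnel.tsv")

    print("funnel (stage: retained [class breakdown]):")
    for s in report.stages:
        bd = ", ".join(f"{k}={v}" for k, v in sorted(s.class_breakdown.items()))
        print(f"  {s.name:14s} {s.count:5d}  [{bd}]")
    print(f"per-receptor better-than-standard: {per_receptor}")
    print(f"reports -> {args.out / 'funnel.json'}, {args.out / 'funnel.tsv'}")


if __name__ == "__main__":
    main()
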