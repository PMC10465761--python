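#!/usr/bin/env python
"""Run the two-group differential screen and extract the disease signature.

Reads results/inputs/expression.tsv + groups.csv, applies the Welch
t-test with FC > 1.3 and p < 0.1 (both strict), and writes the
per-gene table to results/differential.tsv.
"""

import argparse
from pathlib import Path

from sigreverse import compute_differential, read_expression
from sigreverse.signature import write_differential


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--out", type=Path, default=Path("results/differential.tsv"))
    ap.add_argument("--fc-min", type=float, default=1.3)
    ap.add_argument("--p-max", type=float, default=0.1)
    args = ap.parse_args()

    expr = read_expression(args.inputs / "expression.tsv", args.inputs / "groups.csv")
    records, signature = compute_differential(expr, args.fc_min, args.p_max)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_differential(records, args.out)
    n_case = len(expr.samples_in("case"))
    n_ctrl = len(expr.samples_in("control"))
    print(
        f"screened {len(records)} genes ({n_case} case vs {n_ctrl} control; "
        f"FC > {args.fc_min}, p < {args.p_max}): "
        f"{len(signature.up_genes)} up, {len(signature.down_genes)} down -> {args.out}"
    )


if __name__ == "__main__":
    main()
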