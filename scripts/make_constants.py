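"""Regenerate the shipped calibration table src/bdgrowth/data/constants_table.csv.

For each n on the grid: 10^6 Monte Carlo draws of the pivot S_n give c_mse,
c_bias and the 0.025/0.975 quantiles; c_inv is the exact closed form.  Each
row records its own sub-seed (seed + n) so any single row can be reproduced
independently.

Run from the repository root:

    python scripts/make_constants.py [--seed 20260921] [--mc-samples 1000000]
"""

import argparse
from pathlib import Path

import pandas as pd

from bdgrowth.constants import ConstantsTable, compute_row

GRID = list(range(3, 31)) + [40, 50, 75, 100, 150, 200]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20260921)
    ap.add_argument("--mc-samples", type=int, default=10**6)
    ap.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parents[1]
        / "src"
        / "bdgrowth"
        / "data"
        / "constants_table.csv",
    )
    args = ap.parse_args()

    rows = []
    for n in GRID:
        row = compute_row(n, mc_samples=args.mc_samples, seed=args.seed + n)
        rows.append(row)
        print(
            f"n={n:4d}  c_mse={row.c_mse:.6f}  c_bias={row.c_bias:.6f}  "
            f"c_inv={row.c_inv:.6f}  q025={row.q025:.6f}  q975={row.q975:.6f}",
            flush=True,
        )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    ConstantsTable(pd.DataFrame(rows)).save(args.out)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
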