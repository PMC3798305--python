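"""Screen the 19 features for class separation (t-test + BH-FDR, q = 0.05).

Reads results/features.csv; writes results/screening.csv and prints the
selected ("optimal") feature subset.
"""

import argparse
from pathlib import Path

import pandas as pd

from vastex.screening import screen

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--q", type=float, default=0.05)
    args = ap.parse_args()

    feats = pd.read_csv(args.results / "features.csv")
    res = screen(feats, q=args.q)
    res.table.to_csv(args.results / "screening.csv")
    print(res.table.round(4).to_string())
    print(f"\nselected {len(res.selected)} of 19 features "
          f"(per-subject means, BH-FDR q={args.q}):")
    print("  " + ", ".join(res.selected))


if __name__ == "__main__":
    main()
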