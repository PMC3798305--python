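"""Render the human-readable markdown report from the results directory."""

import argparse
from pathlib import Path

from vastex.pipeline import make_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    text = make_report(args.results)
    print(text)
    print(f"wrote {args.results / 'report.md'}")


if __name__ == "__main__":
    main()
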