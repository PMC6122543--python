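#!/usr/bin/env python
"""Enumerate cis-regulatory elements in the 1.5-kb promoters and introns.

Scans the bundled IUPAC element dictionary over both strands (palindromic
elements like the CArG box counted once per position) and summarizes the
counts by functional category.
"""

import argparse
from pathlib import Path

from madswalk.pipeline import cis_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/pipeline"))
    ap.add_argument("--promoter-len", type=int, default=1500)
    args = ap.parse_args()

    summary = cis_stage(
        args.outdir / "annotation.gff3",
        args.outdir / "scaffolds.fa",
        args.outdir / "cis",
        promoter_len=args.promoter_len,
    )
    print("cis-element counts by category:")
    print(summary.to_string(index=False))
    top = summary.iloc[0]
    print(
        f"largest category: {top['category']} "
        f"({top['count']} hits, {100 * top['proportion']:.1f}%)"
    )


if __name__ == "__main__":
    main()
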