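#!/usr/bin/env python
"""Score the finished run against the generator's planted ground truth:
sensitivity per structure class and false ceRNA edges."""

import argparse
import json
from pathlib import Path

from stressrna.pipeline import validate_against_truth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    report = validate_against_truth(args.outdir, args.indir / "ground_truth.json")
    (args.outdir / "recovery_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    for k in sorted(report):
        print(f"  {k}: {report[k]:.3f}")


if __name__ == "__main__":
    main()
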