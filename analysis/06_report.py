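#!/usr/bin/env python
"""Assemble the per-stage outputs into one summary document.

Collects the Ks histogram, SiZer map and peaks, node tallies, repeat
summary and insertion-age histogram from results/ into
results/report.md (stages not yet run are marked as such).
"""

import argparse
import shutil
from pathlib import Path

from ploidyscape.report import build_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    # stage outputs live in per-stage subdirectories; pool them
    pool = args.results / "report_pool"
    pool.mkdir(parents=True, exist_ok=True)
    for sub in ("ks", "sizer", "maps", "ltr"):
        d = args.results / sub
        if d.is_dir():
            for f in d.glob("*.tsv"):
                shutil.copy(f, pool / f.name)
    text = build_report(pool)
    target = args.results / "report.md"
    target.write_text(text, encoding="utf-8")
    print(f"report written to {target} ({len(text.splitlines())} lines)")


if __name__ == "__main__":
    main()
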