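"""End-of-run report: one markdown document assembling every stage's
outputs from a run directory, with figures when matplotlib can write
them.  Stages whose outputs are absent are marked "not run"."""

from __future__ import annotations

from pathlib import Path

from . import io


def _section(title: str) -> list[str]:
    return [f"## {title}", ""]


def _table(rows: list[dict], columns: list[str]) -> list[str]:
    if not rows:
        return ["(empty)", ""]
    out = ["| " + " | ".join(columns) + " |",
           "| " + " | ".join("---" for _ in columns) + " |"]
    for r in rows:
        out.append("| " + " | ".join(str(r.get(c, ".")) for c in columns) + " |")
    out.append("")
    return out


def _ks_section(run_dir: Path, lines: list[str]) -> None:
    lines.extend(_section("Paralog-age (Ks) distribution"))
    hist = run_dir / "ks_histogram.tsv"
    if not hist.exists():
        lines.extend(["not run", ""])
        return
    rows = io.read_tsv(hist)
    n = sum(int(r["count"]) for r in rows)
    top = max(rows, key=lambda r: int(r["count"])) if rows else None
    lines.append(f"{n} paralog pairs retained in the Ks window (0.05 bins).")
    if top:
        lines.append(
            f"Fullest bin: [{top['bin_start']}, {top['bin_end']}) with {top['count']} pairs."
        )
    lines.append("")
    _plot_histogram(run_dir, rows)


def _plot_histogram(run_dir: Path, rows: list[dict]) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        xs = [float(r["bin_start"]) for r in rows]
        cs = [int(r["count"]) for r in rows]
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.bar(xs, cs, width=0.05, align="edge", color="#888")
        ax.set_xlabel("Ks")
        ax.set_ylabel("pairs")
        fig.tight_layout()
        fig.savefig(run_dir / "ks_histogram.png", dpi=120)
        plt.close(fig)
    except Exception:
        pass


def _sizer_section(run_dir: Path, lines: list[str]) -> None:
    lines.extend(_section("SiZer significance map and peak calls"))
    peaks = run_dir / "sizer_peaks.tsv"
    if not peaks.exists():
        lines.extend(["not run", ""])
        return
    rows = sorted(io.read_tsv(peaks), key=lambda r: float(r["location"]))
    if rows:
        lines.append("Peaks (significant increase-to-decrease transitions), ascending:")
        lines.append("")
        lines.extend(_table(rows, ["location", "bandwidth_support", "flank_lo", "flank_hi"]))
    else:
        lines.extend(["No significant peaks called.", ""])
    _plot_sizer(run_dir)


def _plot_sizer(run_dir: Path) -> None:
    map_path = run_dir / "sizer_map.tsv"
    if not map_path.exists():
        return
    try:
        import numpy as np
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        rows = io.read_tsv(map_path)
        xs = sorted({float(r["x"]) for r in rows})
        hs = sorted({float(r["h"]) for r in rows})
        code = {"sparse": 0, "flat": 1, "increase": 2, "decrease": 3}
        grid = np.zeros((len(hs), len(xs)))
        xi = {x: i for i, x in enumerate(xs)}
        hi = {h: i for i, h in enumerate(hs)}
        for r in rows:
            grid[hi[float(r["h"])], xi[float(r["x"])]] = code[r["state"]]
        # the established color semantics: gray sparse, purple flat,
        # blue increase, red decrease; white lines mark +/-2h windows
        cmap = ListedColormap(["#999999", "#9467bd", "#1f77b4", "#d62728"])
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.pcolormesh(xs, np.log10(hs), grid, cmap=cmap, vmin=0, vmax=3, shading="nearest")
        mid = 0.5 * (xs[0] + xs[-1])
        ax.plot([mid - 2 * h for h in hs], np.log10(hs), color="white", lw=1)
        ax.plot([mid + 2 * h for h in hs], np.log10(hs), color="white", lw=1)
        ax.set_xlim(xs[0], xs[-1])
        ax.set_xlabel("Ks")
        ax.set_ylabel("log10 bandwidth")
        fig.tight_layout()
        fig.savefig(run_dir / "sizer_map.png", dpi=120)
        plt.close(fig)
    except Exception:
        pass


def _maps_section(run_dir: Path, lines: list[str]) -> None:
    lines.extend(_section("Gene-duplication mapping (per species-tree node)"))
    path = run_dir / "maps_tally.tsv"
    if not path.exists():
        lines.extend(["not run", ""])
        return
    lines.extend(_table(io.read_tsv(path), ["node", "n_matching", "n_dup", "proportion"]))


def _ltr_section(run_dir: Path, lines: list[str]) -> None:
    lines.extend(_section("Repeat landscape and LTR insertion ages"))
    summ = run_dir / "repeat_summary.tsv"
    if not summ.exists():
        lines.extend(["not run", ""])
        return
    lines.extend(
        _table(io.read_tsv(summ), ["class", "element_count", "length_bp", "pct_genome", "mean_length"])
    )
    ages_path = run_dir / "ltr_ages.tsv"
    if ages_path.exists():
        rows = io.read_tsv(ages_path)
        ages = [float(r["age_years"]) for r in rows if r["age_years"] != "."]
        if ages:
            lines.append(f"{len(ages)} dated insertions; oldest {max(ages)/1e6:.2f} My.")
            lines.append("")
            lines.append("Insertion ages (0.5-My bins, 0-7 My):")
            lines.append("")
            binned = [0] * 14
            for a in ages:
                if 0 <= a < 7e6:
                    binned[int(a / 5e5)] += 1
            lines.extend(
                _table(
                    [
                        {"bin_My": f"{i*0.5:.1f}-{(i+1)*0.5:.1f}", "count": c}
                        for i, c in enumerate(binned)
                    ],
                    ["bin_My", "count"],
                )
            )


def build_report(run_dir: str | Path) -> str:
    """Assemble the summary document for one run directory."""
    run_dir = Path(run_dir)
    lines: list[str] = ["# ploidyscape run report", ""]
    _ks_section(run_dir, lines)
    _sizer_section(run_dir, lines)
    _maps_section(run_dir, lines)
    _ltr_section(run_dir, lines)
    return "\n".join(lines) + "\n"
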