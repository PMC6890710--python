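"""Repeat-landscape summary tables."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass


@dataclass
class SummaryRow:
    label: str
    element_count: int
    total_bp: int
    pct_genome: float
    mean_length: float


def _merge(intervals):
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return out


def summarize_repeats(annotation: list[dict], genome_length: int) -> list[SummaryRow]:
    """Per-label element count, merged bp, % genome and mean length,
    plus an 'unmasked' remainder row; percentages sum to 100 once
    cross-label overlaps are absent (they are merged within labels)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    by_label: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for row in annotation:
        if not (0 <= row["start"] <= row["end"]):
            raise ValueError(f"bad interval in annotation: {row}")
        by_label[row["label"]].append((row["start"], row["end"], row["contig"]))
    rows: list[SummaryRow] = []
    total_masked = 0
    for label in sorted(by_label):
        ivs = by_label[label]
        count = len(ivs)
        lens = [hi - lo for lo, hi, _ in ivs]
        per_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for lo, hi, contig in ivs:
            per_contig[contig].append((lo, hi))
        bp = sum(
            hi - lo for contig in per_contig for lo, hi in _merge(per_contig[contig])
        )
        total_masked += bp
        rows.append(
            SummaryRow(
                label=label,
                element_count=count,
                total_bp=bp,
                pct_genome=100.0 * bp / genome_length,
                mean_length=sum(lens) / count if count else 0.0,
            )
        )
    remainder = genome_length - total_masked
    rows.append(
        SummaryRow(
            label="unmasked",
            element_count=0,
            total_bp=remainder,
            pct_genome=100.0 * remainder / genome_length,
            mean_length=0.0,
        )
    )
    return rows


def summary_to_rows(rows: list[SummaryRow]) -> list[dict]:
    return [
        {
            "class": r.label,
            "element_count": r.element_count,
            "length_bp": r.total_bp,
            "pct_genome": round(r.pct_genome, 3),
            "mean_length": round(r.mean_length, 1),
        }
        for r in rows
    ]
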