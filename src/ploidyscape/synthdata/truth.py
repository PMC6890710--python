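"""Ground-truth records for the synthetic generators."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ElementTruth:
    element_id: str
    contig: str
    ltr5: tuple[int, int]      # 0-based half-open genome interval
    ltr3: tuple[int, int]
    tsd: str
    age_years: float
    nested_in: str | None = None
    family: int = 0
    gappy: bool = False
    kind: str = "element"      # "element" or "decoy"

    @property
    def start(self) -> int:
        return self.ltr5[0]

    @property
    def end(self) -> int:
        return self.ltr3[1]


@dataclass
class TruthTable:
    """One truth row per planted object, keyed by stable identifiers."""

    paralog_truth: dict[tuple[str, str], tuple[float, str]] = field(default_factory=dict)
    tree_truth: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    element_truth: dict[str, ElementTruth] = field(default_factory=dict)

    def paralog_rows(self) -> list[dict]:
        return [
            {"gene_a": a, "gene_b": b, "true_ks": round(ks, 6), "origin": origin}
            for (a, b), (ks, origin) in sorted(self.paralog_truth.items())
        ]

    def tree_rows(self) -> list[dict]:
        rows = []
        for tree_id, events in sorted(self.tree_truth.items()):
            if not events:
                rows.append({"tree": tree_id, "node": ".", "n_dup": 0})
            for node, count in events:
                rows.append({"tree": tree_id, "node": node, "n_dup": count})
        return rows

    def element_gff_rows(self, source: str = "synthdata") -> list[str]:
        """Truth as GFF3 lines (1-based, inclusive)."""
        lines = ["##gff-version 3"]
        for eid, t in sorted(self.element_truth.items()):
            attrs = (
                f"ID={eid};ltr5={t.ltr5[0] + 1}-{t.ltr5[1]};"
                f"ltr3={t.ltr3[0] + 1}-{t.ltr3[1]};tsd={t.tsd};"
                f"age_years={t.age_years:.1f};"
                f"nested_in={t.nested_in or '.'};family={t.family};"
                f"gappy={int(t.gappy)}"
            )
            ftype = "LTR_retrotransposon" if t.kind == "element" else "tandem_duplication"
            lines.append(
                "\t".join(
                    [
                        t.contig,
                        source,
                        ftype,
                        str(t.start + 1),
                        str(t.end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
            )
        return lines
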