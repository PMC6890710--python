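"""File formats: FASTA, newick, tab-separated tables, GFF3.

One dialect everywhere: tabular outputs are headered, tab-separated,
UTF-8, with "." for missing values; FASTA is wrapped at 60 columns
with case preserved (soft-masking survives a round-trip); GFF3 is
1-based inclusive with a version pragma.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy

_SEQ_OK = re.compile(r"^[A-Za-z*\-]+$")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered mapping id -> sequence; errors carry line numbers."""
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    records[current] = "".join(chunks)
                current = line[1:].split()[0]
                if not current:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                if current in records:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate FASTA ID {current!r}"
                    )
                chunks = []
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: sequence before header")
                if not _SEQ_OK.match(line):
                    raise ValueError(
                        f"{path}:{lineno}: non-IUPAC characters in sequence"
                    )
                chunks.append(line)
        if current is not None:
            records[current] = "".join(chunks)
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    seen = set()
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in records.items():
            if rid in seen:
                raise ValueError(f"duplicate FASTA ID {rid!r}")
            seen.add(rid)
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_newick(path: str | Path) -> str:
    """Validated newick string (labels may contain '|')."""
    text = Path(path).read_text(encoding="utf-8").strip()
    depth = 0
    for off, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"{path}: unbalanced ')' at offset {off}")
    if depth != 0:
        raise ValueError(f"{path}: {depth} unclosed '(' in newick")
    # round-trip through dendropy to validate structure
    dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    return text


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip() + "\n", encoding="utf-8")


def read_newick_list(path: str | Path) -> list[str]:
    """One newick tree per line."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line:
            out.append(line)
    return out


def write_tsv(rows: list[dict], path: str | Path, columns: list[str] | None = None) -> None:
    if columns is None:
        columns = list(rows[0]) if rows else []
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, ".")) for c in columns) + "\n")


def read_tsv(path: str | Path) -> list[dict]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        return []
    cols = lines[0].split("\t")
    return [dict(zip(cols, line.split("\t"))) for line in lines[1:] if line]


def write_gff3(lines: list[str], path: str | Path) -> None:
    text = "\n".join(lines)
    if not text.startswith("##gff-version"):
        text = "##gff-version 3\n" + text
    Path(path).write_text(text + "\n", encoding="utf-8")


def elements_to_gff(elements, source: str = "ploidyscape") -> list[str]:
    """Annotated LTR elements as GFF3 lines (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for el in elements:
        attrs = (
            f"ID={el.element_id};ltr_identity={el.ltr_identity:.2f};"
            f"tsd={el.tsd or '.'};motif={'tgca' if el.motif_ok else '.'};"
            f"age_class={el.age_class or '.'};"
            f"insertion_age_years={'.' if el.age_years is None else f'{el.age_years:.1f}'};"
            f"flags={','.join(sorted(el.flags)) or '.'}"
        )
        lines.append(
            "\t".join(
                [
                    el.contig,
                    source,
                    "LTR_retrotransposon",
                    str(el.start + 1),
                    str(el.end),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    return lines
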