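"""Transcript annotations and region typing.

A deliberately small transcript model: each transcript owns a stranded
interval on a reference, an ordered list of exons, optional UTRs, and a
coding flag. That is enough to type an edited position as UTR, coding
exon, non-coding exon, intron or intergenic — the granularity used when
summarising where editing targets fall on nuclear RNAs. Amino-acid
consequences are out of scope.

Coordinates are 0-based half-open internally; GFF3 output uses the
standard 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

#: Precedence when overlapping feature classes both contain a position.
REGION_PRECEDENCE = (
    "5'UTR",
    "3'UTR",
    "coding exon",
    "non-coding exon",
    "intron",
    "intergenic",
)


@dataclass
class Transcript:
    gene: str
    ref_name: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    coding: bool = True
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"exon [{s}, {e}) outside transcript [{self.start}, {self.end})"
                )

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def region_at(self, position: int) -> str | None:
        """Region label for a position, or None if outside the transcript."""
        if not self.contains(position):
            return None
        hits = set()
        if self.utr5 and self.utr5[0] <= position < self.utr5[1]:
            hits.add("5'UTR")
        if self.utr3 and self.utr3[0] <= position < self.utr3[1]:
            hits.add("3'UTR")
        in_exon = any(s <= position < e for s, e in self.exons)
        if in_exon:
            hits.add("coding exon" if self.coding else "non-coding exon")
        else:
            hits.add("intron")
        for label in REGION_PRECEDENCE:
            if label in hits:
                return label
        return None  # pragma: no cover


@dataclass
class AnnotationSet:
    """Transcripts plus named gene-set memberships."""

    transcripts: list[Transcript]
    gene_sets: dict[str, set[str]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return [t.gene for t in self.transcripts]

    def transcript_at(self, ref_name: str, position: int) -> Transcript | None:
        for t in self.transcripts:
            if t.ref_name == ref_name and t.contains(position):
                return t
        return None

    def region_of(self, ref_name: str, position: int) -> tuple[str, str | None]:
        """(region label, gene) for a position; intergenic outside all."""
        t = self.transcript_at(ref_name, position)
        if t is None:
            return "intergenic", None
        return t.region_at(position), t.gene


# --- GFF3-lite I/O -------------------------------------------------------

_TYPE_MAP = {
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def write_gff3(ann: AnnotationSet, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for t in ann.transcripts:
        attrs = f"ID={t.gene};gene={t.gene};coding={'true' if t.coding else 'false'}"
        lines.append("\t".join([
            t.ref_name, "editscan", "transcript",
            str(t.start + 1), str(t.end), ".", t.strand, ".", attrs,
        ]))
        for s, e in t.exons:
            lines.append("\t".join([
                t.ref_name, "editscan", "exon",
                str(s + 1), str(e), ".", t.strand, ".", f"Parent={t.gene}",
            ]))
        for kind, iv in (("five_prime_UTR", t.utr5), ("three_prime_UTR", t.utr3)):
            if iv is not None:
                lines.append("\t".join([
                    t.ref_name, "editscan", kind,
                    str(iv[0] + 1), str(iv[1]), ".", t.strand, ".",
                    f"Parent={t.gene}",
                ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> AnnotationSet:
    """Read the GFF3-lite dialect written by :func:`write_gff3`."""
    rows: list[tuple[str, str, int, int, str, dict[str, str]]] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        rows.append((f[0], f[2], int(f[3]) - 1, int(f[4]), f[6], _parse_attrs(f[8])))

    transcripts: dict[str, dict] = {}
    for ref, ftype, start, end, strand, attrs in rows:
        if ftype == "transcript":
            gene = attrs.get("gene", attrs.get("ID"))
            transcripts[attrs["ID"]] = dict(
                gene=gene, ref_name=ref, start=start, end=end, strand=strand,
                exons=[], coding=attrs.get("coding", "true") == "true",
                utr5=None, utr3=None,
            )
    for ref, ftype, start, end, strand, attrs in rows:
        parent = attrs.get("Parent")
        if parent not in transcripts:
            continue
        if ftype == "exon":
            transcripts[parent]["exons"].append((start, end))
        elif ftype in _TYPE_MAP:
            transcripts[parent][_TYPE_MAP[ftype]] = (start, end)
    return AnnotationSet([Transcript(**kw) for kw in transcripts.values()])


def write_gene_sets(gene_sets: dict[str, set[str]], path: str | Path) -> None:
    lines = ["gene\tset"]
    for name in sorted(gene_sets):
        for gene in sorted(gene_sets[name]):
            lines.append(f"{gene}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    gene_sets: dict[str, set[str]] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        gene, name = line.split("\t")
        gene_sets.setdefault(name, set()).add(gene)
    return gene_sets
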