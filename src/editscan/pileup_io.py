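"""Pileup table I/O.

The native dialect is a TSV with header ``ref pos refbase A C G U depth``
and 0-based positions. A converter from samtools-mpileup text output is
provided for pileups produced outside the package; it handles the
read-base string's match/mismatch/indel/read-start/read-end syntax but
ignores base qualities (the caller is depth/count based).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .synth import PILEUP_COLUMNS

_INDEL = re.compile(r"[+-](\d+)")


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns: {sorted(missing)}")
    if not (df[["A", "C", "G", "U"]].sum(axis=1) == df["depth"]).all():
        raise ValueError("base counts do not sum to depth")
    return df[PILEUP_COLUMNS]


def write_pileup_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def _count_bases(ref_base: str, bases: str) -> dict[str, int]:
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    i = 0
    while i < len(bases):
        ch = bases[i]
        if ch == "^":          # read start: skip mapping-quality char
            i += 2
            continue
        if ch == "$":          # read end marker
            i += 1
            continue
        if ch in "+-":         # indel: skip length digits and inserted seq
            m = _INDEL.match(bases, i)
            i = m.end() + int(m.group(1))
            continue
        if ch in ".,":
            counts[ref_base] += 1
        elif ch.upper() in "ACGT":
            base = ch.upper().replace("T", "U")
            counts[base] += 1
        # '*' (deletion placeholder) and 'N' contribute no base count
        i += 1
    return counts


def read_mpileup(path: str | Path) -> pd.DataFrame:
    """Convert samtools-mpileup text (1-based) to the native dialect."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        ref, pos1, ref_base = fields[0], int(fields[1]), fields[2].upper()
        ref_base = ref_base.replace("T", "U")
        bases = fields[4] if len(fields) > 4 else ""
        counts = _count_bases(ref_base, bases)
        depth = sum(counts.values())
        rows.append({"ref": ref, "pos": pos1 - 1, "refbase": ref_base,
                     **counts, "depth": depth})
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)
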