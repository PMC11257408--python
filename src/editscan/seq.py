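"""Reference sequences in RNA space.

All coordinates are 0-based, half-open. Sequences are held in the RNA
alphabet (A/C/G/U); DNA input is transcribed on read and written back as
DNA on FASTA export, since editing chemistry (C-to-U, the UC dinucleotide
context) is reasoned about on the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_BASES = "ACGU"

_DNA_TO_RNA = str.maketrans("Tt", "Uu")
_RNA_TO_DNA = str.maketrans("Uu", "Tt")


@dataclass(frozen=True)
class Feature:
    """A labelled, stranded interval on a reference (0-based, half-open)."""

    label: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class ReferenceSequence:
    """An RNA reference with optional labelled features.

    Parameters
    ----------
    name:
        Sequence identifier.
    sequence:
        Uppercase RNA string over A/C/G/U.
    features:
        Labelled intervals, each within ``[0, len(sequence))``.
    """

    name: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.sequence.upper().translate(_DNA_TO_RNA)
        if not seq:
            raise ValueError("reference sequence must be non-empty")
        bad = set(seq) - set(RNA_BASES)
        if bad:
            raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
        self.sequence = seq
        n = len(seq)
        for f in self.features:
            if not (0 <= f.start < f.end <= n):
                raise ValueError(
                    f"feature {f.label!r} interval [{f.start}, {f.end}) "
                    f"outside sequence of length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def positions_of(self, base: str) -> list[int]:
        return [i for i, b in enumerate(self.sequence) if b == base]

    def uc_positions(self) -> list[int]:
        """0-based positions of the C in every UC dinucleotide."""
        s = self.sequence
        return [i for i in range(1, len(s)) if s[i - 1] == "U" and s[i] == "C"]

    def context(self, position: int, flank: int = 10, pad: str = "-") -> str:
        """Window of ``2*flank + 1`` bases centred on ``position``.

        Positions running off either end are padded with ``pad`` so every
        context has the same length, which keeps position-frequency
        matrices rectangular.
        """
        if not 0 <= position < len(self.sequence):
            raise IndexError(f"position {position} outside [0, {len(self)})")
        s = self.sequence
        left = s[max(0, position - flank): position].rjust(flank, pad)
        right = s[position + 1: position + 1 + flank].ljust(flank, pad)
        return left + s[position] + right


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read FASTA into RNA-space references (T is transcribed to U)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return [ReferenceSequence(r.id, str(r.seq)) for r in records]


def write_fasta(refs: Iterable[ReferenceSequence], path: str | Path,
                alphabet: str = "dna") -> None:
    """Write references to FASTA, as DNA by default (U back-transcribed)."""
    records = []
    for ref in refs:
        seq = ref.sequence
        if alphabet == "dna":
            seq = seq.translate(_RNA_TO_DNA)
        records.append(SeqRecord(Seq(seq), id=ref.name, description=""))
    SeqIO.write(records, str(path), "fasta")


def load_human_5s_rrna() -> ReferenceSequence:
    """The 121-nt human 5S rRNA consensus (5SrRNAdb accession E00204)."""
    path = Path(__file__).parent / "data" / "rna5s_human_E00204.fasta"
    return read_fasta(path)[0]
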