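"""Target RNA definitions and FASTA input.

Every downstream coordinate refers to a :class:`TargetRNA`: positions are
1-based along the RNA 5'->3', and the reserved index 0 denotes the
full-length (no RT stop) category in stop-count vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

__all__ = ["TargetRNA", "read_targets", "DEFAULT_LINKER"]

# 3' linker ligated to the RNA after modification; provides the universal
# RT priming site so every nucleotide of the target can be probed.
DEFAULT_LINKER = "CACTCGGGCACCAAGGAC"

# Full IUPAC nucleotide alphabet (T and U both accepted on input).
IUPAC_NUCLEOTIDES = set("ACGTURYSWKMBDHVN")


def _canonical_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class TargetRNA:
    """A named RNA sequence, the coordinate frame for all counting.

    Parameters
    ----------
    name : str
        Identifier, unique within a target set.
    sequence : str
        Nucleotide sequence 5'->3' (DNA or RNA spelling; stored uppercased
        as given, with a canonical RNA form available via :attr:`rna`).
    linker : str
        Optional 3' linker appended during library construction; reads may
        extend into it but it carries no reactivity positions.
    notes : str
        Free-text annotation.
    """

    name: str
    sequence: str
    linker: str = DEFAULT_LINKER
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "linker", self.linker.upper())
        if not self.name:
            raise ValueError("target name must be non-empty")
        if not self.sequence:
            raise ValueError(f"target {self.name!r}: empty sequence")
        for offset, ch in enumerate(self.sequence):
            if ch not in IUPAC_NUCLEOTIDES:
                raise ValueError(
                    f"target {self.name!r}: non-nucleotide character {ch!r} "
                    f"at offset {offset}"
                )

    @property
    def rna(self) -> str:
        """Canonical RNA-alphabet form of the sequence (T -> U)."""
        return _canonical_rna(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


def read_targets(path) -> list[TargetRNA]:
    """Read target RNAs from a FASTA file.

    Sequences are uppercased; T and U are treated as equivalent downstream
    (the original spelling is preserved on the returned objects). Duplicate
    record names, empty sequences and non-nucleotide characters are hard
    errors naming the offending record.
    """
    targets: list[TargetRNA] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in seen:
            raise ValueError(f"duplicate target name {name!r} in {path}")
        seen.add(name)
        targets.append(TargetRNA(name=name, sequence=str(record.seq)))
    if not targets:
        raise ValueError(f"no FASTA records found in {path}")
    return targets
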