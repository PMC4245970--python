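"""Secondary-structure containers and the CT / dot-bracket formats.

A :class:`SecondaryStructure` is a set of base pairs (i, j), 1-based with
i < j, over an RNA of known length. CT files follow the common dialect:
the first token of the header line is the length, column 5 of each
nucleotide line is the pairing partner (0 = unpaired); further columns are
ignored. The dot-bracket parser handles nested pairs only — pseudoknot
bracket tiers are rejected rather than silently dropped, since dropped
pairs would corrupt downstream sensitivity/PPV scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SecondaryStructure",
    "parse_ct",
    "write_ct",
    "parse_dotbracket",
    "to_dotbracket",
]


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of canonical base pairs over an RNA of a given length."""

    length: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("structure length must be >= 1")
        pairs = frozenset(tuple(p) for p in self.pairs)
        seen: set[int] = set()
        for i, j in sorted(pairs):
            if not (1 <= i < j <= self.length):
                raise ValueError(
                    f"pair ({i}, {j}) out of range for length {self.length}"
                )
            for idx in (i, j):
                if idx in seen:
                    raise ValueError(f"nucleotide {idx} appears in more than one pair")
                seen.add(idx)
        object.__setattr__(self, "pairs", pairs)

    @property
    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def partner(self, i: int) -> int:
        """Pairing partner of position i, or 0 if unpaired."""
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return 0


def parse_ct(path) -> SecondaryStructure:
    """Parse a CT file into a :class:`SecondaryStructure`.

    Asymmetric pairing records (i says j but j says k != i) and partners
    out of range are hard errors.
    """
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    if not lines:
        raise ValueError(f"{path}: empty CT file")
    try:
        length = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed CT header {lines[0]!r}") from exc
    if len(lines) < 1 + length:
        raise ValueError(
            f"{path}: CT header declares {length} nucleotides but only "
            f"{len(lines) - 1} lines follow"
        )
    partner = [0] * (length + 1)
    for ln in lines[1 : 1 + length]:
        cols = ln.split()
        if len(cols) < 5:
            raise ValueError(f"{path}: CT line has fewer than 5 columns: {ln!r}")
        i, j = int(cols[0]), int(cols[4])
        if not (1 <= i <= length):
            raise ValueError(f"{path}: nucleotide index {i} out of range 1..{length}")
        if j < 0 or j > length:
            raise ValueError(f"{path}: partner index {j} out of range at line for {i}")
        partner[i] = j
    pairs: set[tuple[int, int]] = set()
    for i in range(1, length + 1):
        j = partner[i]
        if j == 0:
            continue
        if partner[j] != i:
            raise ValueError(
                f"{path}: asymmetric pairing — {i} pairs to {j} but {j} pairs "
                f"to {partner[j]}"
            )
        pairs.add((min(i, j), max(i, j)))
    return SecondaryStructure(length=length, pairs=frozenset(pairs))


def write_ct(structure: SecondaryStructure, path, sequence: str | None = None,
             title: str = "structure") -> None:
    """Write a CT file; ``sequence`` defaults to all-N if not given."""
    seq = (sequence or "N" * structure.length).upper()
    if len(seq) != structure.length:
        raise ValueError("sequence length does not match structure length")
    partner = {i: 0 for i in range(1, structure.length + 1)}
    for i, j in structure.pairs:
        partner[i] = j
        partner[j] = i
    with open(path, "w") as fh:
        fh.write(f"{structure.length} {title}\n")
        for i in range(1, structure.length + 1):
            nxt = i + 1 if i < structure.length else 0
            fh.write(f"{i} {seq[i - 1]} {i - 1} {nxt} {partner[i]} {i}\n")


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string (nested '(' ')' pairs and '.' only).

    Unbalanced brackets and any other character are hard errors reporting
    the 1-based position.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty dot-bracket string")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(
                f"unsupported character {ch!r} at position {pos} "
                "(pseudoknot tiers and letters are not handled)"
            )
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(length=len(text), pairs=frozenset(pairs))


def to_dotbracket(structure: SecondaryStructure) -> str:
    """Render a structure as dot-bracket; fails on crossing (pseudoknotted) pairs."""
    chars = ["."] * structure.length
    ordered = structure.sorted_pairs
    for a, (i, j) in enumerate(ordered):
        for k, l in ordered[a + 1 :]:
            if i < k < j < l:
                raise ValueError(
                    f"pairs ({i},{j}) and ({k},{l}) cross; not representable "
                    "in single-tier dot-bracket"
                )
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)
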