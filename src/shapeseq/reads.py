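"""Paired-end read processing: demultiplex, trim, align, count RT stops.

The experiment encodes the treatment channel in a degenerate 4-nt handle at
the start of R1 (default RRRY for the reagent-treated (+) channel, YYYR for
the mock-treated (-) channel). After handle removal and adapter trimming,
R1 is matched as a substring of target+linker starting at the cDNA 3'-end
position, and R2 is checked for consistency from the linker side.

Coordinate convention (load-bearing): a fragment whose 5'-most aligned
target position is p means reverse transcriptase synthesized its last base
at p, blocked by the adduct (or spontaneous drop-off site) one nucleotide
5' of it — so the stop is attributed to k = p - 1. A fragment reaching
position 1 is a full-length read-through, k = 0. Changing this offset
shifts every reactivity spectrum by one position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .targets import TargetRNA, _canonical_rna

__all__ = [
    "ReadPair",
    "StopCountVector",
    "Alignment",
    "ProcessingConfig",
    "demultiplex_by_handle",
    "trim_adapter",
    "align_fragment",
    "count_stops",
    "process_read_pairs",
    "read_fastq_pairs",
    "write_counts_table",
    "read_counts_table",
]

# Read-1 sequencing adapter (TruSeq); seen as read-through when the insert
# is shorter than the read length.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

# IUPAC degenerate nucleotide codes over the RNA alphabet (T folded into U).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("U"), "T": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "S": frozenset("CG"),
    "W": frozenset("AU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}

_RC = str.maketrans("ACGU", "UGCA")


def _revcomp_rna(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _matches_iupac(seq: str, pattern: str) -> bool:
    if len(seq) < len(pattern):
        return False
    return all(base in IUPAC_SETS[code] for base, code in zip(seq, pattern))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read; ``handle_seq`` records the removed channel handle."""

    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str = ""
    r2_qual: str = ""
    handle_seq: str = ""

    def __post_init__(self) -> None:
        if self.r1_qual and len(self.r1_qual) != len(self.r1_seq):
            raise ValueError(f"read {self.id}: R1 sequence/quality length mismatch")
        if self.r2_qual and len(self.r2_qual) != len(self.r2_seq):
            raise ValueError(f"read {self.id}: R2 sequence/quality length mismatch")


@dataclass
class StopCountVector:
    """Per-channel RT-stop counts for one target.

    ``counts[k]`` for k = 1..L is the number of fragments whose stop was
    attributed to nucleotide k; ``counts[0]`` is the full-length
    read-through category.
    """

    target_name: str
    channel: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValueError("counts must be a 1-D vector indexed 0..L with L >= 1")
        if np.any(self.counts < 0):
            raise ValueError("stop counts must be non-negative")
        if self.channel not in ("plus", "minus"):
            raise ValueError(f"channel must be 'plus' or 'minus', got {self.channel!r}")

    @property
    def length(self) -> int:
        """Target length L (counts vector has L + 1 entries)."""
        return self.counts.size - 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Alignment:
    """Outcome of aligning one read pair."""

    status: str  # aligned | unaligned | ambiguous
    target_name: str | None = None
    channel: str | None = None
    stop_index: int | None = None

    @property
    def full_length(self) -> bool:
        return self.stop_index == 0


@dataclass
class ProcessingConfig:
    """Knobs of the read-processing pipeline (defaults match common practice
    for this assay: 4-nt RRRY/YYYR handles, 35-nt reads, exact matching)."""

    plus_handle: str = "RRRY"
    minus_handle: str = "YYYR"
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 4
    max_mismatch_rate: float = 0.0
    max_mismatches: int = 0
    read_len: int = 35
    exclude_3prime_terminal: bool = True
    min_mean_quality: float | None = None  # off by default; no quality filter


def demultiplex_by_handle(
    pair: ReadPair,
    plus_handle: str = "RRRY",
    minus_handle: str = "YYYR",
) -> tuple[str, ReadPair]:
    """Assign a read pair to a channel by its R1 handle prefix.

    Returns ``(channel, stripped_pair)`` where channel is ``"plus"``,
    ``"minus"`` or ``"unassigned"``. The handle bases are removed from R1
    of the returned pair (and recorded on ``handle_seq``); an unassigned
    pair is returned unchanged. A read matching both handles is ambiguous
    and therefore unassigned.
    """
    if len(plus_handle) != len(minus_handle):
        raise ValueError("plus and minus handles must have equal length")
    n = len(plus_handle)
    if n > len(pair.r1_seq):
        raise ValueError(
            f"handle length {n} exceeds R1 length {len(pair.r1_seq)} "
            f"for read {pair.id}"
        )
    prefix = _canonical_rna(pair.r1_seq[:n])
    plus = _matches_iupac(prefix, _canonical_rna(plus_handle))
    minus = _matches_iupac(prefix, _canonical_rna(minus_handle))
    if plus == minus:  # zero or two matches
        return "unassigned", pair
    stripped = replace(
        pair,
        r1_seq=pair.r1_seq[n:],
        r1_qual=pair.r1_qual[n:] if pair.r1_qual else "",
        handle_seq=pair.r1_seq[:n],
    )
    return ("plus" if plus else "minus"), stripped


def trim_adapter(
    seq: str,
    adapter: str,
    min_overlap: int = 4,
    max_mismatch_rate: float = 0.0,
) -> str:
    """Remove adapter read-through from the 3' end of ``seq``.

    Finds the longest suffix of ``seq`` that matches a prefix of
    ``adapter`` with at least ``min_overlap`` bases and a mismatch fraction
    at most ``max_mismatch_rate``; no qualifying overlap leaves the
    sequence unchanged (a valid outcome, not an error).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    s = _canonical_rna(seq)
    a = _canonical_rna(adapter)
    for n in range(min(len(s), len(a)), min_overlap - 1, -1):
        mismatches = _hamming(s[-n:], a[:n])
        if mismatches <= max_mismatch_rate * n:
            return seq[:-n]
    return seq


def _candidate_starts(
    fragment: str, extended: str, max_mismatches: int, max_overhang: int
) -> list[int]:
    """0-based start offsets where ``fragment`` matches within ``extended``.

    Up to ``max_overhang`` trailing bases may extend past the end of
    ``extended`` (soft-clipped): adapter read-through shorter than the
    trimmer's minimum overlap cannot be removed, so a short untrimmable
    remnant must not block alignment.
    """
    if max_mismatches == 0:
        starts, at = [], extended.find(fragment)
        while at != -1:
            starts.append(at)
            at = extended.find(fragment, at + 1)
        for h in range(1, max_overhang + 1):
            n = len(fragment) - h
            off = len(extended) - n
            if n >= 1 and off >= 0 and extended[off:] == fragment[:n]:
                starts.append(off)
        return sorted(set(starts))
    starts = []
    for off in range(len(extended)):
        n = min(len(fragment), len(extended) - off)
        if n < 1 or len(fragment) - n > max_overhang:
            continue
        if _hamming(fragment[:n], extended[off : off + n]) <= max_mismatches:
            starts.append(off)
    return sorted(set(starts))


def align_fragment(
    pair: ReadPair,
    targets: list[TargetRNA],
    max_mismatches: int = 0,
    max_overhang: int = 3,
) -> Alignment:
    """Align a demultiplexed, adapter-trimmed read pair to the target set.

    R1 (handle removed) must match target+linker as a substring beginning
    at the stop position; R2, read from the linker side, must be consistent
    with the same fragment. Reads matching more than one (target, position)
    are reported ambiguous and discarded — random assignment would bias
    drop-off estimates at repeated sequence.
    """
    if not targets:
        raise ValueError("empty target set")
    f1 = _canonical_rna(pair.r1_seq)
    r2rc = _revcomp_rna(_canonical_rna(pair.r2_seq))
    handle = _canonical_rna(pair.handle_seq)
    if not f1:
        return Alignment(status="unaligned")
    hits: list[tuple[str, int]] = []
    for target in targets:
        extended = target.rna + _canonical_rna(target.linker)
        for off in _candidate_starts(f1, extended, max_mismatches, max_overhang):
            if off > target.length:  # fragment starting inside the linker
                continue
            insert = handle + extended[off:]
            t = min(len(r2rc), len(insert))
            if t and _hamming(r2rc[-t:], insert[-t:]) > max_mismatches:
                continue
            hits.append((target.name, off))  # stop index k = off (= p - 1)
    if not hits:
        return Alignment(status="unaligned")
    if len(set(hits)) > 1:
        return Alignment(status="ambiguous")
    name, k = hits[0]
    return Alignment(status="aligned", target_name=name, stop_index=k)


def count_stops(
    alignments: Iterable[Alignment],
    target: TargetRNA,
    channel: str,
    exclude_3prime_terminal: bool = True,
) -> StopCountVector:
    """Tally aligned stop indices into a :class:`StopCountVector`.

    With the 3'-terminal exclusion on (default), stops attributed to the
    position adjacent to the linker (k = L) are dropped, because fragments
    of a single nucleotide cannot be uniquely assigned in practice; the
    effective scored length is then L - 1.
    """
    counts = np.zeros(target.length + 1, dtype=np.int64)
    for aln in alignments:
        if aln.status != "aligned":
            continue
        if aln.target_name != target.name or (aln.channel not in (None, channel)):
            raise ValueError("alignment stream does not match target/channel")
        k = aln.stop_index
        if exclude_3prime_terminal and k == target.length:
            continue
        counts[k] += 1
    return StopCountVector(target_name=target.name, channel=channel, counts=counts)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files in lockstep."""
    with open(r1_path) as fh1, open(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            if t1.split()[0] != t2.split()[0]:
                raise ValueError(f"mate id mismatch: {t1!r} vs {t2!r}")
            yield ReadPair(id=t1.split()[0], r1_seq=s1, r2_seq=s2,
                           r1_qual=q1, r2_qual=q2)


def _mean_phred(qual: str) -> float:
    return float(np.mean([ord(c) - 33 for c in qual])) if qual else 0.0


def process_read_pairs(
    pairs: Iterable[ReadPair],
    targets: list[TargetRNA],
    config: ProcessingConfig | None = None,
) -> tuple[dict[tuple[str, str], StopCountVector], dict[str, int]]:
    """Full pipeline: demultiplex -> trim -> align -> count, for all targets.

    Returns ``({(target_name, channel): StopCountVector}, stats)`` where
    ``stats`` accounts for every input pair (nothing is dropped silently):
    total = unassigned + quality_filtered + unaligned + ambiguous + aligned
    (+ excluded_3prime when the terminal-position exclusion applies).
    """
    cfg = config or ProcessingConfig()
    counts = {
        (t.name, ch): np.zeros(t.length + 1, dtype=np.int64)
        for t in targets for ch in ("plus", "minus")
    }
    lengths = {t.name: t.length for t in targets}
    stats = dict(total=0, plus_assigned=0, minus_assigned=0, unassigned=0,
                 quality_filtered=0, aligned=0, unaligned=0, ambiguous=0,
                 excluded_3prime=0)
    for pair in pairs:
        stats["total"] += 1
        if cfg.min_mean_quality is not None and (
            _mean_phred(pair.r1_qual) < cfg.min_mean_quality
            or _mean_phred(pair.r2_qual) < cfg.min_mean_quality
        ):
            stats["quality_filtered"] += 1
            continue
        channel, stripped = demultiplex_by_handle(
            pair, cfg.plus_handle, cfg.minus_handle
        )
        if channel == "unassigned":
            stats["unassigned"] += 1
            continue
        stats[f"{channel}_assigned"] += 1
        trimmed = replace(
            stripped,
            r1_seq=trim_adapter(stripped.r1_seq, cfg.adapter,
                                cfg.min_overlap, cfg.max_mismatch_rate),
            r2_seq=trim_adapter(stripped.r2_seq, cfg.adapter,
                                cfg.min_overlap, cfg.max_mismatch_rate),
            r1_qual="", r2_qual="",
        )
        aln = align_fragment(trimmed, targets, cfg.max_mismatches,
                             max_overhang=cfg.min_overlap - 1)
        if aln.status != "aligned":
            stats[aln.status] += 1
            continue
        k = aln.stop_index
        if cfg.exclude_3prime_terminal and k == lengths[aln.target_name]:
            stats["excluded_3prime"] += 1
            continue
        stats["aligned"] += 1
        counts[(aln.target_name, channel)][k] += 1
    vectors = {
        (name, ch): StopCountVector(target_name=name, channel=ch, counts=arr)
        for (name, ch), arr in counts.items()
    }
    return vectors, stats


def write_counts_table(plus: StopCountVector, minus: StopCountVector, path) -> None:
    """Write the per-target count table (TSV: index, plus_count, minus_count;
    index 0 is the full-length category)."""
    if plus.target_name != minus.target_name or plus.length != minus.length:
        raise ValueError("plus/minus vectors must describe the same target")
    with open(path, "w") as fh:
        fh.write(f"# target={plus.target_name} length={plus.length}\n")
        fh.write("index\tplus_count\tminus_count\n")
        for k in range(plus.length + 1):
            fh.write(f"{k}\t{plus.counts[k]}\t{minus.counts[k]}\n")


def read_counts_table(path) -> tuple[StopCountVector, StopCountVector]:
    """Read a count table written by :func:`write_counts_table`."""
    name = "unknown"
    rows: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("target="):
                        name = tok.split("=", 1)[1]
                continue
            if line.startswith("index"):
                continue
            k, p, m = line.split("\t")
            rows.append((int(k), int(p), int(m)))
    rows.sort()
    plus = np.array([r[1] for r in rows], dtype=np.int64)
    minus = np.array([r[2] for r in rows], dtype=np.int64)
    return (
        StopCountVector(target_name=name, channel="plus", counts=plus),
        StopCountVector(target_name=name, channel="minus", counts=minus),
    )
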