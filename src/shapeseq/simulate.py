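"""Generative simulator of the two-channel RT-stop experiment.

Produces synthetic data at two levels: per-channel stop-count vectors
drawn exactly from the drop-off model (for estimator tests), and full
paired-end FASTQ reads laid out as the library is sequenced (for pipeline
tests): a degenerate channel handle, the cDNA fragment in target
coordinates, the 3' linker, and adapter read-through when the insert is
shorter than the read length. All randomness derives from the seed in
:class:`SimParams`; identical parameters give byte-identical FASTQ.

The single-hit regime is assumed: at most one adduct per molecule, the
operating point the theta-distribution formalism is built on. Sequencing
error is substitution-only, since the aligner upstream is Hamming-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import DropoffModel, stop_distribution
from .reads import DEFAULT_ADAPTER, IUPAC_SETS, StopCountVector
from .targets import TargetRNA

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_stop_counts",
    "emit_fastq",
    "simulate_experiment",
    "make_structured_theta",
]

_TO_DNA = str.maketrans("U", "T")
_RC_DNA = str.maketrans("ACGT", "TGCA")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_RC_DNA)[::-1]


@dataclass(frozen=True)
class SimParams:
    """Ground truth and library layout for one synthetic experiment.

    ``model`` carries the true theta, natural drop-off hazards gamma and
    modified fraction p_mod; the linker is taken from ``target``. Defaults
    mirror the assay as run: 35-nt reads, RRRY/YYYR handles, no
    sequencing error.
    """

    target: TargetRNA
    model: DropoffModel
    n_plus: int
    n_minus: int
    seed: int
    read_len: int = 35
    plus_handle: str = "RRRY"
    minus_handle: str = "YYYR"
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.model.L != self.target.length:
            raise ValueError("model length does not match target length")
        if self.n_plus <= 0 or self.n_minus <= 0:
            raise ValueError("molecule counts must be positive")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")
        if self.read_len <= len(self.plus_handle):
            raise ValueError("read_len must exceed the handle length")


@dataclass
class SimTruth:
    """Ground-truth record accompanying a simulated experiment."""

    theta_true: np.ndarray
    gamma: np.ndarray
    p_mod: float
    seed: int
    plus_stops: np.ndarray  # per-molecule stop index, 0 = full length
    minus_stops: np.ndarray

    def write(self, path) -> None:
        """Tab-separated sidecar: position, theta_true, gamma."""
        with open(path, "w") as fh:
            fh.write("position\ttheta_true\tgamma\n")
            for i, (t, g) in enumerate(zip(self.theta_true, self.gamma), start=1):
                fh.write(f"{i}\t{t:.10g}\t{g:.10g}\n")


def simulate_stop_counts(
    params: SimParams,
) -> tuple[StopCountVector, StopCountVector, SimTruth]:
    """Draw per-molecule stop indices for both channels and tally them.

    Each (-) molecule walks L -> 1 with natural hazard gamma_k at every
    reached position. Each (+) molecule is modified with probability
    p_mod at a site s ~ theta; RT stops at the first event encountered
    walking inward — the natural drop-off if it fires 3' of s, otherwise
    s itself with certainty. Sampling uses the exact marginal stop
    distribution, which is equivalent to the positional walk.
    """
    rng = np.random.default_rng(params.seed)
    model = params.model
    L = model.L

    p_minus = stop_distribution(model, "minus")
    minus_stops = rng.choice(L + 1, size=params.n_minus, p=p_minus)

    natural = rng.choice(L + 1, size=params.n_plus, p=p_minus)
    modified = rng.random(params.n_plus) < model.p_mod
    sites = rng.choice(np.arange(1, L + 1), size=params.n_plus, p=model.theta)
    # walking L -> 1, the larger index is hit first; unmodified molecules
    # follow the natural process alone
    plus_stops = np.where(modified, np.maximum(natural, sites), natural)

    plus = StopCountVector(
        target_name=params.target.name, channel="plus",
        counts=np.bincount(plus_stops, minlength=L + 1),
    )
    minus = StopCountVector(
        target_name=params.target.name, channel="minus",
        counts=np.bincount(minus_stops, minlength=L + 1),
    )
    truth = SimTruth(
        theta_true=model.theta.copy(), gamma=model.gamma.copy(),
        p_mod=model.p_mod, seed=params.seed,
        plus_stops=plus_stops, minus_stops=minus_stops,
    )
    return plus, minus, truth


def _instantiate_handle(handle: str, rng: np.random.Generator) -> str:
    """Draw concrete DNA bases for a degenerate handle (uniform per code)."""
    out = []
    for code in handle.upper():
        choices = sorted(IUPAC_SETS[code])  # RNA alphabet; U -> T below
        out.append(choices[rng.integers(len(choices))])
    return "".join(out).translate(_TO_DNA)


def _make_read(insert: str, adapter: str, read_len: int) -> str:
    if len(insert) >= read_len:
        return insert[:read_len]
    read = insert + adapter[: read_len - len(insert)]
    return read + "A" * (read_len - len(read))  # pad if adapter exhausted


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        alternatives = _BASES[_BASES != arr[i]]
        arr[i] = alternatives[rng.integers(alternatives.size)]
    return arr.tobytes().decode()


def emit_fastq(params: SimParams, truth: SimTruth, r1_path, r2_path) -> None:
    """Write the simulated molecules as paired FASTQ (both channels combined).

    For a molecule with stop index k the cDNA covers target positions
    k+1..L plus the linker; R1 reads handle + fragment + linker (5'->3' in
    target sense) and R2 reads the reverse complement from the linker
    side. Inserts shorter than the read length run through into the
    adapter. Qualities are uniform ('I').
    """
    rng = np.random.default_rng([params.seed, 1])
    target_dna = params.target.rna.translate(_TO_DNA)
    linker = params.target.linker.upper().translate(_TO_DNA)
    qual = "I" * params.read_len
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for channel, handle, stops in (
            ("plus", params.plus_handle, truth.plus_stops),
            ("minus", params.minus_handle, truth.minus_stops),
        ):
            for i, k in enumerate(stops):
                fragment = target_dna[int(k):]
                insert = _instantiate_handle(handle, rng) + fragment + linker
                r1 = _make_read(insert, params.adapter, params.read_len)
                r2 = _make_read(_revcomp_dna(insert), params.adapter,
                                params.read_len)
                r1 = _apply_errors(r1, params.error_rate, rng)
                r2 = _apply_errors(r2, params.error_rate, rng)
                rid = f"sim_{channel}_{i}"
                f1.write(f"@{rid}\n{r1}\n+\n{qual}\n")
                f2.write(f"@{rid}\n{r2}\n+\n{qual}\n")


def simulate_experiment(params: SimParams, outdir) -> tuple[
    StopCountVector, StopCountVector, SimTruth
]:
    """Run the simulator end to end and write R1/R2 FASTQ, the truth
    sidecar and a parameter echo into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plus, minus, truth = simulate_stop_counts(params)
    emit_fastq(params, truth, outdir / "R1.fastq", outdir / "R2.fastq")
    truth.write(outdir / "truth.tsv")
    echo = {
        "target": params.target.name,
        "length": params.target.length,
        "n_plus": params.n_plus,
        "n_minus": params.n_minus,
        "p_mod": params.model.p_mod,
        "read_len": params.read_len,
        "plus_handle": params.plus_handle,
        "minus_handle": params.minus_handle,
        "adapter": params.adapter,
        "linker": params.target.linker,
        "error_rate": params.error_rate,
        "seed": params.seed,
    }
    (outdir / "params.json").write_text(json.dumps(echo, indent=2) + "\n")
    return plus, minus, truth


def make_structured_theta(L: int, seed: int, hot_fraction: float = 0.2,
                          exclude_last: bool = True) -> np.ndarray:
    """A reactivity-like theta: mostly near-zero (paired) positions with a
    minority of strongly reactive (loop-like) sites.

    With ``exclude_last`` the linker-adjacent position gets zero mass,
    matching the scored range when the 3'-terminal exclusion is on.
    """
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.05, 0.3, size=L)
    n_hot = max(1, int(round(hot_fraction * L)))
    usable = L - 1 if exclude_last else L
    hot = rng.choice(usable, size=min(n_hot, usable), replace=False)
    theta[hot] = rng.uniform(2.0, 8.0, size=hot.size)
    if exclude_last:
        theta[-1] = 0.0
    return theta / theta.sum()
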