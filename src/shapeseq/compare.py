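"""Fragment distributions, correlations between runs, scale conversion.

The machinery used to compare experimental conditions: stop-count vectors
are normalized to fragment frequency distributions, reactivity spectra
from different runs are compared by Pearson correlation over shared
positions, and externally produced reactivity scales are renormalized to
the theta scale (sum 1 over positions with data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reads import StopCountVector

__all__ = [
    "FragmentDistribution",
    "to_distribution",
    "pearson",
    "normalize_to_theta",
    "comparison_report",
]


@dataclass(frozen=True)
class FragmentDistribution:
    """Per-position fragment frequencies for one target and channel.

    ``frequencies[k]`` is the fraction of the channel's fragments whose
    stop index is k (index 0 = full-length); they sum to 1.
    """

    target_name: str
    channel: str
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.ndim != 1 or freqs.size < 2:
            raise ValueError("frequencies must be a 1-D vector indexed 0..L")
        if np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0, atol=1e-9):
            raise ValueError("frequencies must be non-negative and sum to 1")
        object.__setattr__(self, "frequencies", freqs)


def to_distribution(counts: StopCountVector) -> FragmentDistribution:
    """Fragment counts divided by the channel total (sums to 1)."""
    total = counts.total
    if total == 0:
        raise ValueError(
            f"{counts.target_name}/{counts.channel}: no fragments observed, "
            "distribution undefined"
        )
    return FragmentDistribution(
        target_name=counts.target_name,
        channel=counts.channel,
        frequencies=counts.counts / total,
    )


def pearson(x, y) -> float | None:
    """Product-moment correlation; None (not a number) when undefined.

    Undefined when either vector is constant — reported as
    not-applicable rather than 0 or 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("pearson requires two equal-length 1-D vectors, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def normalize_to_theta(reactivities) -> tuple[np.ndarray, bool]:
    """Rescale an external reactivity profile to the theta scale.

    Negative entries are clamped to 0 first (the returned flag reports
    whether any were); no-data entries (NaN) propagate as NaN and are
    excluded from the normalization. The finite entries of the result sum
    to 1.
    """
    r = np.asarray(reactivities, dtype=float).copy()
    if r.ndim != 1 or r.size == 0:
        raise ValueError("reactivities must be a non-empty 1-D vector")
    finite = np.isfinite(r)
    clamped = bool(np.any(r[finite] < 0))
    r[finite & (r < 0)] = 0.0
    total = r[finite].sum()
    if total <= 0:
        raise ValueError("all-zero reactivity vector cannot be normalized")
    r[finite] = r[finite] / total
    return r, clamped


def comparison_report(entries, path) -> None:
    """Write a comparison table (TSV: pair id, channel, n positions, R).

    ``entries`` is an iterable of (pair_id, channel, x, y); x and y are
    compared over positions finite in both (no-data dropped pairwise).
    """
    with open(path, "w") as fh:
        fh.write("pair\tchannel\tn_positions\tR\n")
        for pair_id, channel, x, y in entries:
            x = np.asarray(x, dtype=float)
            y = np.asarray(y, dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            r = pearson(x[keep], y[keep]) if keep.sum() >= 2 else None
            r_str = "NA" if r is None else f"{r:.6f}"
            fh.write(f"{pair_id}\t{channel}\t{int(keep.sum())}\t{r_str}\n")
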