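"""Maximum-likelihood decay correction of two-channel RT-stop counts.

The generative model
--------------------
Reverse transcriptase enters at the 3' end and copies positions L, L-1,
..., 1 in order. In the mock-treated (-) channel it terminates at position
k (failing to add nucleotide k) with natural per-position hazard
``gamma_k`` given that it reached k, so

    P-(stop = k) = gamma_k * prod_{j>k} (1 - gamma_j),      k = 1..L
    P-(full length, k = 0) = prod_j (1 - gamma_j).

In the reagent-treated (+) channel a molecule carries a single adduct with
probability ``p_mod``, placed at site s with probability ``theta_s``
(single-hit regime); RT stops with certainty upon reaching an adduct, and
the natural hazards still apply at every position it reaches.

The estimator
-------------
Write the empirical hazards ``beta_k = Y_k / sum_{j<=k} Y_j`` (minus) and
``alpha_k = X_k / sum_{j<=k} X_j`` (plus). Profiling gamma from the minus
channel (gamma_hat = beta), the plus-channel likelihood factorizes over
per-position stop hazards, and the maximum-likelihood estimate is, in
closed form,

    m_k     = max(0, (alpha_k - beta_k) / (1 - beta_k))
    u_k     = m_k * prod_{j>k} (1 - m_j)
    p_mod   = sum_k u_k
    theta_k = u_k / p_mod.

``m_k`` is the probability that a molecule reaching position k is
modified there; the survival product converts these conditional hazards
into the unconditional site distribution. The widely quoted ratio form
``theta ∝ m`` is the small-hazard approximation of this estimate and is
kept in the diagnostics for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import StopCountVector
from .targets import TargetRNA

__all__ = [
    "DropoffModel",
    "stop_distribution",
    "loglikelihood",
    "ReactivityModel",
    "ReactivityResults",
    "estimate_theta",
]

#: absolute tolerance for the sum-to-one check on estimated theta
NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class DropoffModel:
    """Parameters of the two-channel RT drop-off process.

    ``gamma`` and ``theta`` are position-indexed arrays of length L:
    entry ``i - 1`` refers to nucleotide i. ``theta`` sums to 1 (it is the
    modification-site distribution conditional on being modified);
    ``p_mod`` is the fraction of (+)-channel molecules carrying an adduct.
    """

    gamma: np.ndarray
    theta: np.ndarray
    p_mod: float

    def __post_init__(self) -> None:
        gamma = np.asarray(self.gamma, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        if gamma.ndim != 1 or theta.shape != gamma.shape:
            raise ValueError("gamma and theta must be 1-D arrays of equal length")
        if np.any(gamma < 0) or np.any(gamma >= 1):
            raise ValueError("each gamma_k must lie in [0, 1)")
        if np.any(theta < 0) or not np.isclose(theta.sum(), 1.0, atol=1e-8):
            raise ValueError("theta must be non-negative and sum to 1")
        if not (0.0 <= self.p_mod <= 1.0):
            raise ValueError("p_mod must lie in [0, 1]")
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "theta", theta)

    @property
    def L(self) -> int:
        return self.gamma.size


def _survival(gamma: np.ndarray) -> np.ndarray:
    """surv[k] = prod_{j>k} (1 - gamma_j) for k = 0..L (surv[L] = 1)."""
    L = gamma.size
    surv = np.ones(L + 1)
    surv[:L] = np.cumprod((1.0 - gamma)[::-1])[::-1]
    return surv


def stop_distribution(model: DropoffModel, channel: str) -> np.ndarray:
    """Exact stop-index distribution P(stop = k), k = 0..L, for a channel."""
    L = model.L
    surv = _survival(model.gamma)
    p = np.zeros(L + 1)
    if channel == "minus":
        p[0] = surv[0]
        p[1:] = model.gamma * surv[1:]
    elif channel == "plus":
        # T_ge[k] = sum_{s >= k} theta_s
        t_ge = np.cumsum(model.theta[::-1])[::-1]
        p[0] = (1.0 - model.p_mod) * surv[0]
        p[1:] = surv[1:] * (
            model.gamma * (1.0 - model.p_mod * t_ge) + model.p_mod * model.theta
        )
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return p


def _counts_array(counts, L: int) -> np.ndarray:
    arr = counts.counts if isinstance(counts, StopCountVector) else np.asarray(counts)
    arr = np.asarray(arr, dtype=np.int64)
    if arr.shape != (L + 1,):
        raise ValueError(f"count vector must have length L + 1 = {L + 1}")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return arr


def loglikelihood(model: DropoffModel, plus, minus) -> float:
    """Joint log-likelihood of both channels' stop counts under ``model``.

    Any positive count at a stop index of model probability zero makes the
    data impossible; the function then returns ``-inf`` (distinct from any
    finite log-likelihood) rather than raising.
    """
    x = _counts_array(plus, model.L)
    y = _counts_array(minus, model.L)
    total = 0.0
    for counts, channel in ((y, "minus"), (x, "plus")):
        p = stop_distribution(model, channel)
        observed = counts > 0
        if np.any(p[observed] <= 0.0):
            return float("-inf")
        total += float(np.sum(counts[observed] * np.log(p[observed])))
    return total


@dataclass
class ReactivityResults:
    """Fitted per-nucleotide reactivities and diagnostics.

    ``theta`` is the estimated modification-site distribution over
    ``scored_positions`` (summing to 1 unless ``degenerate``); ``rho`` is
    the length-rescaled reactivity ``L' * theta`` with mean 1, the scale
    used for folding constraints. ``gamma_hat`` is the natural drop-off
    hazard profiled from the minus channel, and ``p_mod`` the estimated
    fraction of modified molecules (a nuisance quantity, reported for
    diagnostics). Standard errors are first-order delta-method
    approximations that neglect cross-position covariance.
    """

    target_name: str
    scored_positions: np.ndarray
    theta: np.ndarray
    rho: np.ndarray
    theta_se: np.ndarray
    p_mod: float
    gamma_hat: np.ndarray
    alpha: np.ndarray
    raw_signal: np.ndarray
    theta_ratio: np.ndarray
    flags: pd.DataFrame
    degenerate: bool
    llf: float
    nobs_plus: int
    nobs_minus: int
    sequence: str | None = None
    model: "ReactivityModel | None" = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Per-position table: position, nucleotide, theta, rho, se, flags."""
        flag_strings = [
            ",".join(col for col in self.flags.columns if row[col]) or "-"
            for _, row in self.flags.iterrows()
        ]
        nts = (
            [self.sequence[i - 1] for i in self.scored_positions]
            if self.sequence
            else ["N"] * self.scored_positions.size
        )
        return pd.DataFrame(
            {
                "position": self.scored_positions,
                "nucleotide": nts,
                "theta": self.theta,
                "rho": self.rho,
                "theta_se": self.theta_se,
                "flags": flag_strings,
            }
        )

    def write_reactivity_table(self, path) -> None:
        """Write the tab-separated reactivity table (index, nucleotide,
        theta, rho, flags)."""
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# target={self.target_name} "
                     f"scored={self.scored_positions.size} "
                     f"degenerate={int(self.degenerate)}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.8g")

    def summary(self, max_rows: int = 60) -> str:
        """Human-readable fit report in the spirit of statsmodels."""
        lines = [
            "Two-channel RT-stop decay correction (maximum likelihood)",
            "=" * 62,
            f"Target: {self.target_name}    scored positions: "
            f"{self.scored_positions[0]}..{self.scored_positions[-1]} "
            f"(L' = {self.scored_positions.size})",
            f"Reads: (+) {self.nobs_plus}    (-) {self.nobs_minus}",
            f"Estimated modified fraction p_mod: {self.p_mod:.4f}",
            f"Log-likelihood: {self.llf:.2f}",
        ]
        if self.degenerate:
            lines.append("WARNING: no modification signal detected "
                         "(degenerate all-zero profile)")
        lines.append("-" * 62)
        frame = self.to_frame()
        if len(frame) > max_rows:
            shown = pd.concat([frame.head(max_rows // 2), frame.tail(max_rows // 2)])
            lines.append(shown.to_string(index=False))
            lines.append(f"... ({len(frame) - max_rows} rows omitted)")
        else:
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of rho along the sequence (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, self.scored_positions.size / 8), 3))
        ax.bar(self.scored_positions, self.rho, width=0.8, color="#2c7fb8")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("nucleotide position")
        ax.set_ylabel(r"$\rho$ (mean 1)")
        ax.set_title(self.target_name)
        return ax


class ReactivityModel:
    """Decay-correction model for one target's (+)/(-) stop counts.

    Parameters
    ----------
    plus, minus : StopCountVector or array of length L + 1
        Stop counts per channel; index 0 is the full-length category.
    target : TargetRNA, optional
        Supplies the sequence for reporting and the target name.
    exclude_3prime_terminal : bool
        Drop the position adjacent to the 3' linker from estimation
        (default True): single-nucleotide fragments cannot be uniquely
        aligned, so the scored length is L' = L - 1.
    """

    def __init__(self, plus, minus, target: TargetRNA | None = None,
                 exclude_3prime_terminal: bool = True):
        if isinstance(plus, StopCountVector) and isinstance(minus, StopCountVector):
            if plus.length != minus.length:
                raise ValueError("plus/minus vectors differ in length")
            if plus.target_name != minus.target_name:
                raise ValueError("plus/minus vectors describe different targets")
            self.target_name = plus.target_name
        else:
            self.target_name = target.name if target else "target"
        x = np.asarray(plus.counts if isinstance(plus, StopCountVector) else plus,
                       dtype=np.int64)
        y = np.asarray(minus.counts if isinstance(minus, StopCountVector) else minus,
                       dtype=np.int64)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValueError("count vectors must be 1-D, equal length >= 2")
        if x.sum() == 0 or y.sum() == 0:
            raise ValueError("both channels must contain at least one read")
        self.L = x.size - 1
        self.exclude_3prime_terminal = bool(exclude_3prime_terminal)
        self.scored_length = self.L - 1 if self.exclude_3prime_terminal else self.L
        if self.scored_length < 1:
            raise ValueError("no scorable positions after 3'-terminal exclusion")
        self.plus = x
        self.minus = y
        self.target = target
        if target is not None and target.length != self.L:
            raise ValueError("target length does not match count vectors")

    @classmethod
    def from_counts_table(cls, path, target: TargetRNA | None = None,
                          **kwargs) -> "ReactivityModel":
        from .reads import read_counts_table

        plus, minus = read_counts_table(path)
        return cls(plus, minus, target=target, **kwargs)

    def fit(self) -> ReactivityResults:
        """Closed-form maximum-likelihood fit (see module docstring)."""
        lp = self.scored_length
        x = self.plus[: lp + 1].astype(float)
        y = self.minus[: lp + 1].astype(float)
        reach_x = np.cumsum(x)
        reach_y = np.cumsum(y)

        pos = np.arange(1, lp + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha = np.where(reach_x[1:] > 0, x[1:] / reach_x[1:], 0.0)
            beta = np.where(reach_y[1:] > 0, y[1:] / reach_y[1:], 0.0)
        unreached_plus = reach_x[1:] == 0
        unreached_minus = reach_y[1:] == 0
        saturated = beta >= 1.0  # every (-) molecule reaching k stops: unusable

        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(saturated, np.nan, (alpha - beta) / (1.0 - beta))
        usable = ~(unreached_plus | unreached_minus | saturated)
        m = np.where(usable, np.clip(raw, 0.0, 1.0), 0.0)
        clamped = usable & (raw < 0)

        # survival product converts conditional hazards m_k into the
        # unconditional modification-site mass u_k
        surv_after = np.ones(lp)
        if lp > 1:
            surv_after[:-1] = np.cumprod((1.0 - m)[::-1])[::-1][1:]
        u = m * surv_after
        p_mod = float(u.sum())
        degenerate = p_mod <= 0.0
        theta = np.zeros(lp) if degenerate else u / p_mod
        if not degenerate:
            err = abs(theta.sum() - 1.0)
            assert err <= NORMALIZATION_TOL, f"theta normalization off by {err}"
        rho = lp * theta

        # first-order delta-method SEs on theta via var(alpha), var(beta)
        with np.errstate(invalid="ignore", divide="ignore"):
            var_a = np.where(reach_x[1:] > 0, alpha * (1 - alpha) / reach_x[1:], 0.0)
            var_b = np.where(reach_y[1:] > 0, beta * (1 - beta) / reach_y[1:], 0.0)
            var_m = np.where(
                usable,
                var_a / (1 - beta) ** 2 + (1 - alpha) ** 2 * var_b / (1 - beta) ** 4,
                0.0,
            )
        theta_se = (
            np.zeros(lp)
            if degenerate
            else np.sqrt(var_m) * surv_after / p_mod
        )

        m_sum = m.sum()
        theta_ratio = m / m_sum if m_sum > 0 else np.zeros(lp)

        flags = pd.DataFrame(
            {
                "clamped": clamped,
                "unreached_plus": unreached_plus,
                "unreached_minus": unreached_minus,
                "saturated": saturated,
            },
            index=pos,
        )

        gamma_hat = np.where(saturated, 0.0, beta)
        fitted = DropoffModel(
            gamma=gamma_hat,
            theta=theta if not degenerate else np.full(lp, 1.0 / lp),
            p_mod=0.0 if degenerate else min(p_mod, 1.0),
        )
        llf = loglikelihood(fitted, x.astype(int), y.astype(int))

        seq = None
        if self.target is not None:
            seq = self.target.rna[:lp]
        return ReactivityResults(
            target_name=self.target_name,
            scored_positions=pos,
            theta=theta,
            rho=rho,
            theta_se=theta_se,
            p_mod=p_mod,
            gamma_hat=gamma_hat,
            alpha=alpha,
            raw_signal=raw,
            theta_ratio=theta_ratio,
            flags=flags,
            degenerate=degenerate,
            llf=llf,
            nobs_plus=int(self.plus.sum()),
            nobs_minus=int(self.minus.sum()),
            sequence=seq,
            model=self,
        )


def estimate_theta(plus, minus, target: TargetRNA | None = None,
                   exclude_3prime_terminal: bool = True) -> ReactivityResults:
    """Convenience wrapper: build a :class:`ReactivityModel` and fit it."""
    return ReactivityModel(
        plus, minus, target=target,
        exclude_3prime_terminal=exclude_3prime_terminal,
    ).fit()
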