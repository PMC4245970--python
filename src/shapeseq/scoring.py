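"""Sensitivity / PPV scoring of predicted against accepted structures.

Sensitivity is the fraction of base pairs in the accepted (typically
crystallographic) structure that the prediction recovers; PPV (positive
predictive value) is the fraction of predicted pairs that are correct.
Numerators and denominators are kept as integers so scores remain
auditable as fractions (e.g. 303/360).

With ``slippage`` on — the convention of the standard scoring tools in
this field — a predicted pair (i, j) is credited if the accepted
structure contains any of (i, j), (i±1, j) or (i, j±1), each accepted
pair creditable at most once. Crediting is a maximum bipartite matching
between predicted and accepted pairs, so the count never depends on
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .structures import SecondaryStructure

__all__ = ["StructureScore", "sensitivity_ppv"]


@dataclass(frozen=True)
class StructureScore:
    """Sensitivity and PPV as audited integer fractions.

    ``sensitivity_num / sensitivity_den`` and ``ppv_num / ppv_den``; a
    denominator of 0 (empty accepted or predicted pair set) makes the
    corresponding score undefined (None), never 0 or 1.
    """

    sensitivity_num: int
    sensitivity_den: int
    ppv_num: int
    ppv_den: int

    @property
    def sensitivity(self) -> float | None:
        if self.sensitivity_den == 0:
            return None
        return self.sensitivity_num / self.sensitivity_den

    @property
    def ppv(self) -> float | None:
        if self.ppv_den == 0:
            return None
        return self.ppv_num / self.ppv_den

    def __str__(self) -> str:
        def frac(n, d):
            return f"{n}/{d} = {100 * n / d:.1f}%" if d else "n/a (empty)"

        return (f"sensitivity {frac(self.sensitivity_num, self.sensitivity_den)}, "
                f"PPV {frac(self.ppv_num, self.ppv_den)}")


def _slip_compatible(p: tuple[int, int], a: tuple[int, int]) -> bool:
    (i, j), (x, y) = p, a
    return (i == x and abs(j - y) <= 1) or (j == y and abs(i - x) <= 1)


def sensitivity_ppv(
    predicted: SecondaryStructure,
    accepted: SecondaryStructure,
    slippage: bool = True,
    exclude: set[int] | None = None,
) -> StructureScore:
    """Score a predicted structure against an accepted one.

    Parameters
    ----------
    predicted, accepted : SecondaryStructure
        Must describe RNAs of the same length.
    slippage : bool
        Allow one-position register shifts when crediting pairs
        (default True, matching common scorer behaviour).
    exclude : set of int, optional
        1-based positions to leave out of scoring (e.g. 5'-end
        nucleotides added only for in vitro synthesis); any pair touching
        an excluded position is removed from both structures first.
    """
    if predicted.length != accepted.length:
        raise ValueError(
            f"structures differ in length: {predicted.length} vs {accepted.length}"
        )
    excl = exclude or set()
    pred = [p for p in predicted.sorted_pairs if not (p[0] in excl or p[1] in excl)]
    acc = [p for p in accepted.sorted_pairs if not (p[0] in excl or p[1] in excl)]

    if not slippage:
        correct = len(set(pred) & set(acc))
    elif pred and acc:
        rows, cols = [], []
        for pi, p in enumerate(pred):
            for ai, a in enumerate(acc):
                if _slip_compatible(p, a):
                    rows.append(pi)
                    cols.append(ai)
        graph = csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(len(pred), len(acc)),
        )
        matching = maximum_bipartite_matching(graph, perm_type="column")
        correct = int(np.sum(matching >= 0))
    else:
        correct = 0

    return StructureScore(
        sensitivity_num=correct,
        sensitivity_den=len(acc),
        ppv_num=correct,
        ppv_den=len(pred),
    )
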