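"""Cross-species comparison: sqrt transform, one-way ANOVA, Tukey HSD.

Biomass, carbon flux and carbon sink per observational unit (transect
by default) are square-root transformed to stabilize variance, then
compared across species with a classical one-way ANOVA; pairwise
differences use Tukey's honestly-significant-difference test on the
studentized range, which controls the family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "sqrt_transform",
    "one_way_anova",
    "tukey_hsd",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupComparison:
    """ANOVA + Tukey summary for one response across species."""

    response: str
    group_names: Tuple[str, ...]
    f_statistic: float
    p_value: float
    pairwise_p: Dict[Tuple[str, str], float]

    def __post_init__(self) -> None:
        k = len(self.group_names)
        if len(self.pairwise_p) != k * (k - 1) // 2:
            raise ValueError("need one pairwise entry per unordered species pair")


def sqrt_transform(values: Sequence[float]) -> np.ndarray:
    """Element-wise square root; rejects negative inputs."""
    arr = np.asarray(values, dtype=float)
    if arr.size and np.any(arr < 0):
        raise ValueError("square-root transform requires non-negative values")
    return np.sqrt(arr)


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    return arrays


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    Degenerate case: when both the between- and within-group sums of
    squares vanish (all observations identical) the test is undefined
    and (0.0, 1.0) is returned.
    """
    arrays = _check_groups(groups)
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def tukey_hsd(groups: Sequence[Sequence[float]]) -> np.ndarray:
    """Pairwise family-wise-adjusted p values (full k x k matrix)."""
    arrays = _check_groups(groups)
    if np.ptp(np.concatenate(arrays)) == 0:
        k = len(arrays)
        return np.ones((k, k))
    result = sps.tukey_hsd(*arrays)
    return np.asarray(result.pvalue)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    response: str = "response",
    transform: bool = True,
) -> GroupComparison:
    """Run the full comparison for one response across named groups."""
    names = tuple(groups.keys())
    data = [sqrt_transform(groups[n]) if transform else np.asarray(groups[n], float)
            for n in names]
    f, p = one_way_anova(data)
    pmat = tukey_hsd(data)
    pairwise = {
        (names[i], names[j]): float(pmat[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    return GroupComparison(
        response=response, group_names=names,
        f_statistic=f, p_value=p, pairwise_p=pairwise,
    )
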