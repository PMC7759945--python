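"""Mantel permutation test between two species x species pairwise matrices.

Correlates the vectorised upper triangles of two symmetric matrices (here:
temporal overlap Dhat vs spatial co-occurrence effect size) and assesses
significance by simultaneous row/column label permutation of the second
matrix.  With S <= 7 species every label permutation is enumerated, so the
p-value is exact; larger communities fall back to Monte-Carlo sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import as_rng

#: label counts up to which all permutations are enumerated exactly
EXACT_ENUMERATION_LIMIT = 7


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    exact: bool
    method: str
    alternative: str


def _as_matrix(m) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), list(m.index)
    return np.asarray(m, dtype=float), None


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(
    m1,
    m2,
    n_perm: int = 999,
    seed=None,
    method: str = "pearson",
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two labelled symmetric matrices.

    ``method`` is 'pearson' or 'spearman' (the latter makes the p-value
    invariant to monotone rescaling); ``alternative`` is 'greater'
    (one-sided on r) or 'two-sided' (on |r|).
    """
    a, labels1 = _as_matrix(m1)
    b, labels2 = _as_matrix(m2)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if labels1 is not None and labels2 is not None and labels1 != labels2:
        raise ValueError("matrix labels do not match")
    s = a.shape[0]
    if s < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    if not (np.allclose(a, a.T, equal_nan=True) and np.allclose(b, b.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")

    va = _upper(a)
    if method == "spearman":
        va = rankdata(va)
    if np.ptp(va) == 0 or np.ptp(_upper(b)) == 0:
        raise ValueError("correlation undefined for a constant matrix")

    def corr(perm: np.ndarray) -> float:
        vb = _upper(b[np.ix_(perm, perm)])
        if method == "spearman":
            vb = rankdata(vb)
        va_c = va - va.mean()
        vb_c = vb - vb.mean()
        return float(va_c @ vb_c / math.sqrt((va_c @ va_c) * (vb_c @ vb_c)))

    identity = np.arange(s)
    r_obs = corr(identity)

    def extreme(r_perm: float) -> bool:
        if alternative == "two-sided":
            return abs(r_perm) >= abs(r_obs) - 1e-12
        return r_perm >= r_obs - 1e-12

    if s <= EXACT_ENUMERATION_LIMIT:
        count = total = 0
        for perm in permutations(range(s)):
            total += 1
            if extreme(corr(np.array(perm))):
                count += 1
        return MantelResult(r_obs, count / total, total, True, method, alternative)

    rng = as_rng(seed)
    count = 0
    for _ in range(n_perm):
        if extreme(corr(rng.permutation(s))):
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm, False, method, alternative)
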