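"""Probabilistic spatial co-occurrence on a station x species presence matrix.

For a pair of species detected at N1 and N2 of N stations and sharing
Q_obs stations, the null model fixes both margins and treats the shared
stations as hypergeometric:

    P_j  = C(N1, j) * C(N - N1, N2 - j) / C(N, N2)
    p_lt = sum_{j < Q_obs} P_j        (fewer shared sites than observed)
    p_gt = sum_{j > Q_obs} P_j        (more shared sites than observed)

Small p_gt indicates positive association (shared habitat preference),
small p_lt negative association (avoidance/competition); otherwise the
pair is spatially random.  The standardised effect size
(Q_obs - N1*N2/N) / N lies in [-1, 1] and is comparable across studies.

Detection is taken at face value ("naive" co-occurrence): a species is
present at a station iff it produced at least one independent event there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .events import EventSeries

log = logging.getLogger(__name__)

#: pairs whose rarer species occupies fewer stations than this are flagged
LOW_POWER_FLOOR = 5


def build_detection_matrix(
    series: Mapping[str, EventSeries],
    stations: Iterable[str] | None = None,
    species: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Station x species binary presence matrix.

    ``stations`` defaults to every station appearing in the events; passing
    the retained-station list keeps stations where only excluded species
    occurred.  A species with no events is allowed only if named explicitly
    in ``species``.
    """
    seen = sorted({st for s in series.values() for st in s.station_ids.tolist()})
    if stations is None:
        stations = seen
    else:
        stations = sorted(set(stations))
        unknown = set(seen) - set(stations)
        if unknown:
            raise ValueError(f"events at stations outside the station list: {sorted(unknown)[:5]}")
    cols = sorted(series) if species is None else list(species)
    mat = pd.DataFrame(0, index=stations, columns=cols, dtype=int)
    for name in cols:
        if name not in series:
            continue
        occupied = [st for st in set(series[name].station_ids.tolist()) if st]
        mat.loc[occupied, name] = 1
    return mat


def pj_probability(N: int, N1: int, N2: int, j: int) -> float:
    """Probability the pair shares exactly j stations under fixed margins.

    Zero outside the hypergeometric support; evaluated in log space by
    scipy's hypergeometric pmf.
    """
    _check_margins(N, N1, N2)
    if j < max(0, N1 + N2 - N) or j > min(N1, N2):
        return 0.0
    return float(hypergeom.pmf(j, N, N1, N2))


def cooccurrence_test(N: int, N1: int, N2: int, Q_obs: int) -> tuple[float, float]:
    """(p_lt, p_gt) for the observed number of shared stations.

    The sums run over the hypergeometric support only; terms beyond
    min(N1, N2) are identically zero.
    """
    _check_margins(N, N1, N2)
    lo, hi = max(0, N1 + N2 - N), min(N1, N2)
    if not lo <= Q_obs <= hi:
        raise ValueError(f"Q_obs={Q_obs} outside support [{lo}, {hi}]")
    p_lt = float(hypergeom.cdf(Q_obs - 1, N, N1, N2))
    p_gt = float(hypergeom.sf(Q_obs, N, N1, N2))
    return p_lt, p_gt


def effect_size(N: int, N1: int, N2: int, Q_obs: int) -> float:
    """Standardised effect size (Q_obs - expected) / N, in [-1, 1]."""
    _check_margins(N, N1, N2)
    return float((Q_obs - N1 * N2 / N) / N)


def classify_cooccurrence(p_lt: float, p_gt: float, alpha: float = 0.05) -> str:
    """'negative' (p_lt < alpha), 'positive' (p_gt < alpha), else 'random'.

    Both probabilities below alpha is a pathological margin configuration;
    it is flagged and the smaller tail wins.
    """
    if not (0 <= p_lt <= 1 and 0 <= p_gt <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_lt < alpha and p_gt < alpha:
        log.warning("both tails significant (p_lt=%.3g, p_gt=%.3g); reporting the smaller", p_lt, p_gt)
        return "negative" if p_lt <= p_gt else "positive"
    if p_lt < alpha:
        return "negative"
    if p_gt < alpha:
        return "positive"
    return "random"


def _check_margins(N: int, N1: int, N2: int) -> None:
    if N < 1:
        raise ValueError("N must be positive")
    if not (0 <= N1 <= N and 0 <= N2 <= N):
        raise ValueError("need 0 <= N1, N2 <= N")


@dataclass(frozen=True)
class CooccurrenceResult:
    species_a: str
    species_b: str
    N: int
    N1: int
    N2: int
    Q_obs: int
    expected: float
    p_lt: float
    p_gt: float
    effect_size: float
    classification: str
    low_power: bool


def pairwise_cooccurrence(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    exclude: tuple[str, ...] = (),
    low_power_floor: int = LOW_POWER_FLOOR,
) -> pd.DataFrame:
    """Long-format pair table over all species pairs of a presence matrix.

    Pairs whose rarer species occupies fewer than ``low_power_floor``
    stations are still reported but flagged ``low_power``.
    """
    species = [s for s in matrix.columns if s not in exclude]
    N = int(matrix.shape[0])
    rows = []
    for a, b in combinations(species, 2):
        va = matrix[a].to_numpy() > 0
        vb = matrix[b].to_numpy() > 0
        N1, N2 = int(va.sum()), int(vb.sum())
        q = int((va & vb).sum())
        p_lt, p_gt = cooccurrence_test(N, N1, N2, q)
        rows.append(
            CooccurrenceResult(
                a, b, N, N1, N2, q, N1 * N2 / N, p_lt, p_gt,
                effect_size(N, N1, N2, q),
                classify_cooccurrence(p_lt, p_gt, alpha),
                min(N1, N2) < low_power_floor,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def effect_size_matrix(table: pd.DataFrame, species: list[str] | None = None) -> pd.DataFrame:
    """Symmetric species x species matrix of standardised effect sizes
    (zero diagonal), the spatial counterpart of the overlap matrix."""
    if species is None:
        species = sorted(set(table["species_a"]) | set(table["species_b"]))
    mat = pd.DataFrame(0.0, index=species, columns=species)
    for row in table.itertuples():
        mat.loc[row.species_a, row.species_b] = row.effect_size
        mat.loc[row.species_b, row.species_a] = row.effect_size
    return mat
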