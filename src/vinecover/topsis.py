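"""TOPSIS: ranking alternatives by relative closeness to the ideal solution.

Given a decision matrix ``x_ij`` (alternatives x criteria), criterion
directions (benefit = larger is better, cost = smaller is better) and a
weight vector summing to one, the method

1. column-normalises by the Euclidean norm, ``r_ij = x_ij / sqrt(sum_i x_ij^2)``;
2. weights, ``v_ij = w_j r_ij``;
3. takes the positive ideal solution (PIS) as the per-column best weighted
   value (max for benefit criteria, min for cost) and the negative ideal
   solution (NIS) as the per-column worst;
4. measures Euclidean separations ``d*`` (from PIS) and ``d-`` (from NIS);
5. scores each alternative by relative closeness ``RC = d- / (d* + d-)``
   in [0, 1] and ranks in descending RC.

Cost criteria are handled by the min/max swap in step 3 on raw-sign
normalised values.  An optional preprocessing mode replaces cost columns by
``max_col - x`` before normalisation (``invert_costs=True``) for
reproduction experiments with the alternative convention; it is off by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BENEFIT",
    "COST",
    "CriterionSpec",
    "DecisionMatrix",
    "NormalizedMatrix",
    "IdealSolutions",
    "RankingResult",
    "DegenerateColumnError",
    "DegeneracyWarning",
    "make_decision_matrix",
    "vector_normalize",
    "apply_weights",
    "ideal_solutions",
    "rank_alternatives",
]

BENEFIT = "benefit"
COST = "cost"

WEIGHT_SUM_TOL = 1e-6
RC_TIE_TOL = 1e-12


class DegenerateColumnError(ValueError):
    """A criterion column is all zero; Euclidean normalisation is undefined."""


class DegeneracyWarning(UserWarning):
    """Constant column or indistinguishable alternatives encountered."""


@dataclass(frozen=True)
class CriterionSpec:
    """One named criterion: optimisation direction and importance weight."""

    name: str
    direction: str
    weight: float

    def __post_init__(self):
        if self.direction not in (BENEFIT, COST):
            raise ValueError(
                f"criterion {self.name!r}: direction must be "
                f"'{BENEFIT}' or '{COST}', got {self.direction!r}"
            )
        if not self.weight >= 0:
            raise ValueError(f"criterion {self.name!r}: weight must be >= 0")


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria performance table with criterion metadata."""

    values: np.ndarray
    alternative_labels: tuple[str, ...]
    criteria: tuple[CriterionSpec, ...]

    @property
    def n_alternatives(self) -> int:
        return self.values.shape[0]

    @property
    def m_criteria(self) -> int:
        return self.values.shape[1]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.criteria])

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(c.direction for c in self.criteria)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.alternative_labels),
            columns=[c.name for c in self.criteria],
        )


@dataclass(frozen=True)
class NormalizedMatrix:
    """Euclidean-normalised (``r``) and weighted (``v``) decision values."""

    r_values: np.ndarray
    v_values: np.ndarray | None = None


@dataclass(frozen=True)
class IdealSolutions:
    """Per-criterion positive (best) and negative (worst) ideal points."""

    pis: np.ndarray
    nis: np.ndarray


@dataclass(frozen=True)
class RankingResult:
    """Separations, relative closeness and rank for each alternative."""

    alternative_labels: tuple[str, ...]
    d_star: np.ndarray
    d_minus: np.ndarray
    rc: np.ndarray
    rank: np.ndarray
    ties: tuple[tuple[str, str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_star": self.d_star,
                "d_minus": self.d_minus,
                "rc": self.rc,
                "rank": self.rank,
            },
            index=list(self.alternative_labels),
        )

    def rc_of(self, label: str) -> float:
        return float(self.rc[self.alternative_labels.index(label)])

    def rank_of(self, label: str) -> int:
        return int(self.rank[self.alternative_labels.index(label)])

    def top(self) -> str:
        return self.alternative_labels[int(np.argmin(self.rank))]


def make_decision_matrix(values, alternative_labels, criteria) -> DecisionMatrix:
    """Validate and build a :class:`DecisionMatrix`.

    Requires >= 2 alternatives, >= 1 criterion, finite nonnegative values,
    positive column norms, and weights summing to 1 within 1e-6.
    """
    x = np.asarray(values, dtype=float)
    criteria = tuple(criteria)
    alternative_labels = tuple(str(a) for a in alternative_labels)
    if x.ndim != 2:
        raise ValueError(f"decision matrix must be 2-D, got {x.ndim}-D")
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 alternatives")
    if m < 1 or len(criteria) != m:
        raise ValueError(f"{len(criteria)} criterion specs for {m} columns")
    if len(alternative_labels) != n:
        raise ValueError(f"{len(alternative_labels)} labels for {n} alternatives")
    if not np.all(np.isfinite(x)):
        i, j = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(f"non-finite value at alternative {i}, criterion {j}")
    if np.any(x < 0):
        i, j = np.argwhere(x < 0)[0]
        raise ValueError(
            f"negative value {x[i, j]} at alternative {alternative_labels[i]!r}, "
            f"criterion {criteria[j].name!r}: scores and masses must be nonnegative"
        )
    wsum = sum(c.weight for c in criteria)
    if abs(wsum - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(f"criterion weights sum to {wsum:.8g}, expected 1")
    zero = np.flatnonzero((x ** 2).sum(axis=0) == 0)
    if zero.size:
        raise DegenerateColumnError(
            f"criterion {criteria[zero[0]].name!r} is all zero; "
            "normalisation is undefined"
        )
    return DecisionMatrix(values=x, alternative_labels=alternative_labels,
                          criteria=criteria)


def vector_normalize(dm: DecisionMatrix) -> NormalizedMatrix:
    """Normalise each column to unit Euclidean norm."""
    norms = np.sqrt((dm.values ** 2).sum(axis=0))
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise DegenerateColumnError(
            f"criterion {dm.criteria[zero[0]].name!r} is all zero"
        )
    return NormalizedMatrix(r_values=dm.values / norms)


def apply_weights(normalized: NormalizedMatrix, weights) -> NormalizedMatrix:
    """Elementwise product ``v_ij = w_j * r_ij``."""
    w = np.asarray(weights, dtype=float)
    r = normalized.r_values
    if w.shape != (r.shape[1],):
        raise ValueError(f"{w.size} weights for {r.shape[1]} criteria")
    if abs(w.sum() - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(f"weights sum to {w.sum():.8g}, expected 1")
    return NormalizedMatrix(r_values=r, v_values=w * r)


def ideal_solutions(v_values: np.ndarray, criteria) -> IdealSolutions:
    """Per-column extrema: best for PIS, worst for NIS, by direction."""
    is_benefit = np.array([c.direction == BENEFIT for c in criteria])
    cmax = v_values.max(axis=0)
    cmin = v_values.min(axis=0)
    return IdealSolutions(
        pis=np.where(is_benefit, cmax, cmin),
        nis=np.where(is_benefit, cmin, cmax),
    )


def _invert_costs(dm: DecisionMatrix) -> DecisionMatrix:
    """Replace each cost column by ``max_col - x`` and flip its direction.

    A constant cost column inverts to all zeros; it carried no discriminating
    information, so it is kept as zeros (contributing nothing) with a warning
    rather than raised as degenerate.
    """
    x = dm.values.copy()
    specs = []
    for j, c in enumerate(dm.criteria):
        if c.direction == COST:
            x[:, j] = x[:, j].max() - x[:, j]
            if not x[:, j].any():
                warnings.warn(
                    f"cost criterion {c.name!r} is constant; inverted column is "
                    "all zero and contributes nothing", DegeneracyWarning,
                    stacklevel=3,
                )
            specs.append(CriterionSpec(c.name, BENEFIT, c.weight))
        else:
            specs.append(c)
    return DecisionMatrix(values=x, alternative_labels=dm.alternative_labels,
                          criteria=tuple(specs))


def rank_alternatives(dm: DecisionMatrix, invert_costs: bool = False) -> RankingResult:
    """Full TOPSIS chain: normalise, weight, ideals, separations, RC, rank.

    Ties in RC (within 1e-12) receive consecutive ranks in input order and
    are reported on the result.  If an alternative is equidistant from both
    ideals with zero separation (all alternatives identical), its RC is
    defined as 0.5 with a degeneracy warning.
    """
    if invert_costs:
        dm = _invert_costs(dm)
        norms = np.sqrt((dm.values ** 2).sum(axis=0))
        safe = np.where(norms == 0, 1.0, norms)
        normalized = NormalizedMatrix(r_values=dm.values / safe)
    else:
        constant = (dm.values.max(axis=0) - dm.values.min(axis=0)) == 0
        if constant.any():
            names = [c.name for c, k in zip(dm.criteria, constant) if k]
            warnings.warn(
                f"constant criterion column(s) {names}: PIS = NIS there, "
                "contributing nothing to separations", DegeneracyWarning,
                stacklevel=2,
            )
        normalized = vector_normalize(dm)
    weighted = apply_weights(normalized, dm.weights)
    v = weighted.v_values
    ideals = ideal_solutions(v, dm.criteria)
    d_star = np.sqrt(((v - ideals.pis) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - ideals.nis) ** 2).sum(axis=1))
    total = d_star + d_minus
    degenerate = total == 0
    if degenerate.any():
        warnings.warn(
            "alternative(s) with zero separation from both ideals; RC set to 0.5",
            DegeneracyWarning, stacklevel=2,
        )
    rc = np.where(degenerate, 0.5, d_minus / np.where(degenerate, 1.0, total))
    # stable sort on -rc keeps input order among exact ties
    order = np.argsort(-rc, kind="stable")
    rank = np.empty(len(rc), dtype=int)
    rank[order] = np.arange(1, len(rc) + 1)
    ties = tuple(
        (dm.alternative_labels[order[k]], dm.alternative_labels[order[k + 1]])
        for k in range(len(order) - 1)
        if abs(rc[order[k]] - rc[order[k + 1]]) <= RC_TIE_TOL
    )
    return RankingResult(
        alternative_labels=dm.alternative_labels,
        d_star=d_star, d_minus=d_minus, rc=rc, rank=rank, ties=ties,
    )
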