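"""Synthetic judgment and decision matrices with known ground truth.

Two generator families support testing of the whole pipeline offline:

* pairwise comparison matrices built from a planted weight vector, either
  perfectly consistent (``a_ij = w_i / w_j``) or perturbed with
  multiplicative lognormal noise on the upper triangle (the lower triangle
  stays exactly reciprocal, so positivity and reciprocity hold by
  construction and ``sigma`` is the single inconsistency knob);
* decision matrices mimicking the field-data structure: right-skewed
  continuous biomass-like columns (lognormal) and ordinal 1-3 / 1-5 / 1-7
  score columns, with mixed benefit/cost directions and an optional planted
  dominant alternative that must come out rank 1.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ahp import PairwiseComparisonMatrix, validate_pcm
from .topsis import BENEFIT, COST, CriterionSpec, DecisionMatrix, make_decision_matrix

__all__ = [
    "ColumnSpec",
    "SynthSpec",
    "consistent_pcm_from_weights",
    "perturbed_pcm",
    "synth_decision_matrix",
    "random_weights",
    "table_like_spec",
]


def consistent_pcm_from_weights(w, labels=None) -> PairwiseComparisonMatrix:
    """Perfectly consistent comparison matrix ``a_ij = w_i / w_j``."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return validate_pcm(np.outer(w, 1.0 / w), labels)


def perturbed_pcm(w, sigma: float, seed: int, labels=None) -> PairwiseComparisonMatrix:
    """Comparison matrix around planted weights with lognormal judgment noise.

    Upper-triangle entries are ``(w_i/w_j) * exp(eps)`` with
    ``eps ~ Normal(0, sigma^2)``; the lower triangle is set to exact
    reciprocals.  ``sigma = 0`` reproduces the consistent matrix.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    n = w.size
    rng = np.random.default_rng(seed)
    a = np.outer(w, 1.0 / w)
    iu = np.triu_indices(n, k=1)
    a[iu] *= np.exp(rng.normal(0.0, sigma, size=len(iu[0])))
    a[(iu[1], iu[0])] = 1.0 / a[iu]
    np.fill_diagonal(a, 1.0)
    return validate_pcm(a, labels)


def random_weights(n: int, seed: int) -> np.ndarray:
    """Random positive weight vector summing to 1 (flat Dirichlet)."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(n))


@dataclass(frozen=True)
class ColumnSpec:
    """One synthetic criterion column.

    kind ``"lognormal"`` draws continuous positive values with parameters
    ``(mu, sigma)`` of the underlying normal; kind ``"ordinal"`` draws
    integers uniformly on ``[lo, hi]``.
    """

    name: str
    direction: str
    kind: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in ("lognormal", "ordinal"):
            raise ValueError(f"unknown generator kind {self.kind!r}")


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic decision matrix; seed fully determines output."""

    n_alternatives: int
    criteria: tuple[ColumnSpec, ...]
    seed: int
    planted_winner: int | None = None
    weights: tuple[float, ...] | None = None  # default: equal

    def __post_init__(self):
        if self.n_alternatives < 2:
            raise ValueError("need at least 2 alternatives")
        if self.planted_winner is not None and not (
            0 <= self.planted_winner < self.n_alternatives
        ):
            raise ValueError("planted_winner out of range")


def table_like_spec(seed: int, n_alternatives: int = 15,
                    planted_winner: int | None = None) -> SynthSpec:
    """Spec emulating the inter-row field table: one right-skewed biomass
    column (observed range spans roughly 1 to 8,600 kg/ha), a continuous-ish
    coverage score, and ordinal risk/tolerance scores with mixed directions."""
    cols = (
        ColumnSpec("dry_biomass", BENEFIT, "lognormal", (7.2, 0.9)),
        ColumnSpec("ground_coverage", BENEFIT, "ordinal", (1, 5)),
        ColumnSpec("invasiveness_risk", COST, "ordinal", (1, 3)),
        ColumnSpec("pest_sensitivity", COST, "ordinal", (1, 3)),
        ColumnSpec("drought_tolerance", BENEFIT, "ordinal", (1, 3)),
        ColumnSpec("winter_hardiness", BENEFIT, "ordinal", (1, 7)),
        ColumnSpec("traffic_tolerance", BENEFIT, "ordinal", (1, 2)),
    )
    return SynthSpec(n_alternatives=n_alternatives, criteria=cols, seed=seed,
                     planted_winner=planted_winner)


def synth_decision_matrix(spec: SynthSpec) -> DecisionMatrix:
    """Draw a decision matrix from a :class:`SynthSpec`.

    With a planted winner, that alternative's row is shifted strictly past
    the column extremes (above the max for benefit criteria, below the min
    but still positive for cost criteria), so dominance makes it rank 1.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_alternatives, len(spec.criteria)
    x = np.empty((n, m))
    for j, col in enumerate(spec.criteria):
        if col.kind == "lognormal":
            mu, sd = col.params
            x[:, j] = rng.lognormal(mu, sd, size=n)
        else:
            lo, hi = col.params
            x[:, j] = rng.integers(int(lo), int(hi) + 1, size=n)
    if spec.planted_winner is not None:
        k = spec.planted_winner
        others = np.delete(np.arange(n), k)
        for j, col in enumerate(spec.criteria):
            rest = x[others, j]
            if col.direction == BENEFIT:
                x[k, j] = rest.max() * 1.1 + 1.0
            else:
                x[k, j] = rest.min() * 0.5
                if x[k, j] <= 0:
                    x[k, j] = min(rest.min(), 1.0) * 0.5
    if spec.weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(spec.weights, dtype=float)
        w = w / w.sum()
    criteria = tuple(
        CriterionSpec(c.name, c.direction, float(wj))
        for c, wj in zip(spec.criteria, w)
    )
    labels = tuple(f"A{i + 1}" for i in range(n))
    return make_decision_matrix(x, labels, criteria)
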