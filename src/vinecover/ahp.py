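"""Analytic Hierarchy Process: criterion weights from pairwise comparisons.

A decision maker expresses the relative importance of ``n`` criteria as a
positive reciprocal matrix ``A`` on the Saaty 1-9 scale, where ``a_ij``
estimates the importance ratio ``w_i / w_j``.  The priority weights are the
principal right eigenvector of ``A`` (``A w = lambda_max w``), normalised to
sum to one.  Judgment coherence is measured by the consistency index
``CI = (lambda_max - n) / (n - 1)`` and the consistency ratio ``CR = CI / RI``
against the tabulated average random index ``RI``; ``CR < 0.10`` is the
conventional acceptance gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairwiseComparisonMatrix",
    "WeightVector",
    "ConsistencyReport",
    "PCMStructureError",
    "PCMDomainError",
    "ReciprocityError",
    "ConvergenceError",
    "SaatyScaleWarning",
    "RI_TABLE",
    "validate_pcm",
    "derive_weights",
    "consistency",
    "lookup_ri",
    "CR_THRESHOLD",
]

#: Average random consistency index for reciprocal matrices of order 1..10.
RI_TABLE = {1: 0.0, 2: 0.0, 3: 0.52, 4: 0.89, 5: 1.11,
            6: 1.25, 7: 1.35, 8: 1.40, 9: 1.45, 10: 1.49}

#: Judgments with a consistency ratio at or above this value are rejected.
CR_THRESHOLD = 0.10

RECIPROCITY_TOL = 1e-9


class PCMStructureError(ValueError):
    """Comparison matrix is not a square n>=2 array."""


class PCMDomainError(ValueError):
    """Comparison matrix contains a nonpositive or non-finite entry."""


class ReciprocityError(ValueError):
    """a_ij * a_ji deviates from 1 beyond tolerance."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries diagnostics."""

    def __init__(self, msg: str, iterations: int, residual: float):
        super().__init__(f"{msg} (iterations={iterations}, residual={residual:.3e})")
        self.iterations = iterations
        self.residual = residual


class SaatyScaleWarning(UserWarning):
    """Entry outside the 1/9..9 Saaty range; valid, but unusual."""


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """Validated n x n positive reciprocal judgment matrix."""

    entries: np.ndarray
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class WeightVector:
    """Normalised criterion priorities (positive, sum to one)."""

    weights: np.ndarray
    labels: tuple[str, ...]

    def as_dict(self) -> dict[str, float]:
        return {lab: float(w) for lab, w in zip(self.labels, self.weights)}


@dataclass(frozen=True)
class ConsistencyReport:
    """Principal eigenvalue and derived consistency statistics."""

    lambda_max: float
    ci: float
    ri: float
    cr: float
    acceptable: bool
    iterations: int = field(default=0, compare=False)


def validate_pcm(entries, labels=None) -> PairwiseComparisonMatrix:
    """Validate a raw array as a pairwise comparison matrix.

    Parameters
    ----------
    entries
        Square array-like of positive reals with unit diagonal and
        reciprocal symmetry ``a_ij * a_ji = 1``.
    labels
        Optional criterion names; defaults to ``C1..Cn``.

    Raises
    ------
    PCMStructureError, PCMDomainError, ReciprocityError
    """
    a = np.asarray(entries, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise PCMStructureError(f"comparison matrix must be square, got shape {a.shape}")
    n = a.shape[0]
    if n < 2:
        raise PCMStructureError("comparison matrix needs at least 2 criteria")
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        bad = np.argwhere(~np.isfinite(a) | (a <= 0))[0]
        raise PCMDomainError(
            f"entry a[{bad[0]},{bad[1]}]={a[bad[0], bad[1]]!r} is not a positive real"
        )
    if not np.allclose(np.diag(a), 1.0, atol=RECIPROCITY_TOL, rtol=0):
        raise ReciprocityError("diagonal entries must equal 1")
    dev = np.abs(a * a.T - 1.0)
    if dev.max() > RECIPROCITY_TOL:
        i, j = np.unravel_index(np.argmax(dev), dev.shape)
        raise ReciprocityError(
            f"a[{i},{j}]*a[{j},{i}] = {a[i, j] * a[j, i]:.12g} deviates from 1 "
            f"by {dev[i, j]:.3g} (> {RECIPROCITY_TOL:g}); "
            "use repair_reciprocity=True when loading rounded CSV reciprocals"
        )
    if np.any(a > 9 + 1e-12) or np.any(a < 1 / 9 - 1e-12):
        warnings.warn(
            "entries outside the Saaty 1/9..9 range", SaatyScaleWarning, stacklevel=2
        )
    if labels is None:
        labels = tuple(f"C{i + 1}" for i in range(n))
    else:
        labels = tuple(str(x) for x in labels)
        if len(labels) != n:
            raise PCMStructureError(f"{len(labels)} labels for a {n}x{n} matrix")
    return PairwiseComparisonMatrix(entries=a, labels=labels)


def _power_iteration(a: np.ndarray, tol: float, max_iter: int):
    """Dominant eigenvector of a positive matrix by L1-normalised iteration.

    Perron-Frobenius guarantees a unique positive dominant eigenvector, so
    plain iteration from the uniform vector converges without deflation.
    """
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    residual = np.inf
    for it in range(1, max_iter + 1):
        aw = a @ w
        w_new = aw / aw.sum()
        residual = np.abs(w_new - w).max()
        w = w_new
        if residual < tol:
            aw = a @ w
            lambda_max = float(np.mean(aw / w))
            return w, lambda_max, it
    raise ConvergenceError("power iteration did not converge", max_iter, residual)


def derive_weights(
    pcm: PairwiseComparisonMatrix, tol: float = 1e-10, max_iter: int = 10_000
) -> WeightVector:
    """Principal right eigenvector of the comparison matrix, summing to 1."""
    w, _, _ = _power_iteration(pcm.entries, tol, max_iter)
    return WeightVector(weights=w, labels=pcm.labels)


def consistency(
    pcm: PairwiseComparisonMatrix, tol: float = 1e-10, max_iter: int = 10_000
) -> ConsistencyReport:
    """Consistency statistics from the same eigen-solution as derive_weights."""
    n = pcm.n
    _, lambda_max, iters = _power_iteration(pcm.entries, tol, max_iter)
    if n <= 2:
        # a 2x2 reciprocal matrix is always consistent; RI = 0 by convention
        ci = 0.0
        cr = 0.0
    else:
        ci = (lambda_max - n) / (n - 1)
        cr = ci / lookup_ri(n)
    return ConsistencyReport(
        lambda_max=lambda_max, ci=ci, ri=lookup_ri(n), cr=cr,
        acceptable=cr < CR_THRESHOLD, iterations=iters,
    )


def lookup_ri(n: int) -> float:
    """Tabulated average random consistency index for matrix order ``n``."""
    if not 1 <= n <= 10:
        raise ValueError(f"random index table covers n=1..10, got n={n}")
    return RI_TABLE[int(n)]
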