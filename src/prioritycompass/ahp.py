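"""Criterion weighting by the analytic hierarchy process (AHP).

Experts compare criteria pairwise on a ratio scale; each expert's judgments
form a positive reciprocal matrix ``A`` with ``a_ij ~ w_i / w_j``.  Weights
are recovered as the normalized principal right eigenvector of ``A``
(Saaty's eigenvector method, computed by power iteration), with the row
geometric-mean method available as a cross-check — the two coincide exactly
on perfectly consistent matrices.

Judgment quality is screened with the consistency ratio

    CI = (lambda_max - n) / (n - 1),      CR = CI / RI(n),

where ``RI(n)`` is the mean CI of random reciprocal matrices (Saaty's
random-index table).  Judgments with ``CR < 0.1`` are conventionally
acceptable.  Multiple experts are combined by the element-wise geometric
mean of their matrices (aggregation of individual judgments), which is the
standard group rule because it is the only averaging that preserves
reciprocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "AhpError",
    "ConvergenceError",
    "PairwiseMatrix",
    "ConsistencyReport",
    "SAATY_RANDOM_INDEX",
    "CONSISTENCY_THRESHOLD",
    "build_consistent_matrix",
    "derive_weights",
    "consistency_ratio",
    "aggregate_expert_matrices",
]

#: Saaty's random consistency index by matrix order.
SAATY_RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

#: Conventional acceptability threshold for the consistency ratio.
CONSISTENCY_THRESHOLD = 0.1

_RECIPROCITY_RTOL = 1e-9


class AhpError(ValueError):
    """Invalid pairwise-comparison input."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge."""

    def __init__(self, iterations: int):
        self.iterations = iterations
        super().__init__(
            f"power iteration did not converge within {iterations} iterations"
        )


@dataclass(frozen=True)
class PairwiseMatrix:
    """Square positive reciprocal matrix of criterion comparisons.

    Invariants (checked on construction): unit diagonal, all entries
    positive, ``a_ij * a_ji = 1`` within relative tolerance 1e-9.
    """

    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise AhpError(f"pairwise matrix must be square, got shape {arr.shape}")
        n = arr.shape[0]
        if n == 0:
            raise AhpError("empty pairwise matrix")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise AhpError("pairwise matrix entries must be positive and finite")
        if not np.allclose(np.diag(arr), 1.0, rtol=0, atol=1e-12):
            raise AhpError("pairwise matrix diagonal must be 1")
        if not np.allclose(arr * arr.T, 1.0, rtol=_RECIPROCITY_RTOL, atol=0):
            raise AhpError("matrix is not reciprocal: a_ij * a_ji != 1")
        labels = tuple(self.labels) if self.labels else tuple(
            f"c{i + 1}" for i in range(n)
        )
        if len(labels) != n:
            raise AhpError(f"{len(labels)} labels for a {n}x{n} matrix")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_consistent_matrix(
    weights: Sequence[float], labels: Sequence[str] = ()
) -> PairwiseMatrix:
    """Perfectly consistent matrix ``a_ij = w_i / w_j`` from positive weights.

    Any positive rescaling of ``weights`` yields the same matrix.  Used both
    to encode known weights and as the noiseless oracle in tests.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise AhpError("weights must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise AhpError("weights must be positive and finite")
    values = np.outer(w, 1.0 / w)
    np.fill_diagonal(values, 1.0)
    # enforce exact float reciprocity of the two triangles
    iu = np.triu_indices(w.size, k=1)
    values[(iu[1], iu[0])] = 1.0 / values[iu]
    return PairwiseMatrix(values, tuple(labels))


def _as_matrix(matrix: Union[PairwiseMatrix, np.ndarray]) -> PairwiseMatrix:
    if isinstance(matrix, PairwiseMatrix):
        return matrix
    return PairwiseMatrix(np.asarray(matrix, dtype=float))


def derive_weights(
    matrix: Union[PairwiseMatrix, np.ndarray],
    method: str = "eigenvector",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Criterion weights and principal eigenvalue estimate from a matrix.

    ``method="eigenvector"`` runs power iteration until the successive
    iterates differ by less than ``tol`` in max-norm (default 1e-12, capped
    at 10,000 iterations); ``method="geometric_mean"`` normalizes the row
    geometric means.  Both return ``(weights summing to 1, lambda_max)``.
    """
    pm = _as_matrix(matrix)
    arr = pm.values
    n = pm.n
    if method == "eigenvector":
        w = np.full(n, 1.0 / n)
        for _ in range(max_iter):
            v = arr @ w
            w_next = v / v.sum()
            if np.max(np.abs(w_next - w)) < tol:
                w = w_next
                break
            w = w_next
        else:
            raise ConvergenceError(max_iter)
    elif method == "geometric_mean":
        w = np.exp(np.mean(np.log(arr), axis=1))
        w = w / w.sum()
    else:
        raise AhpError(f"unknown weighting method {method!r}")
    lambda_max = float(np.mean((arr @ w) / w))
    return w, lambda_max


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency screen of a pairwise matrix."""

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    passed: bool
    threshold: float = CONSISTENCY_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "lambda_max": self.lambda_max,
            "ci": self.ci,
            "ri": self.ri,
            "cr": self.cr,
            "passed": self.passed,
            "threshold": self.threshold,
        }


def consistency_ratio(
    matrix: Union[PairwiseMatrix, np.ndarray],
    ri: Optional[float] = None,
    threshold: float = CONSISTENCY_THRESHOLD,
) -> ConsistencyReport:
    """Consistency index and ratio of a reciprocal matrix.

    ``CI = (lambda_max - n)/(n - 1)`` and ``CR = CI/RI`` with the random
    index taken from Saaty's table (or supplied via ``ri``).  For n <= 2 a
    reciprocal matrix is always consistent and CR is defined as 0; for
    n > 10 a user-supplied RI is required.
    """
    pm = _as_matrix(matrix)
    n = pm.n
    _, lambda_max = derive_weights(pm, method="eigenvector")
    if n <= 2:
        ci = 0.0
        ri_val = 0.0 if ri is None else float(ri)
        cr = 0.0
    else:
        ci = (lambda_max - n) / (n - 1)
        if ri is None:
            if n not in SAATY_RANDOM_INDEX:
                raise AhpError(
                    f"no packaged random index for n={n}; pass ri= explicitly"
                )
            ri_val = SAATY_RANDOM_INDEX[n]
        else:
            ri_val = float(ri)
        cr = ci / ri_val
    # numerical floor: lambda_max >= n up to round-off
    if cr < -1e-9:
        raise AhpError(f"negative consistency ratio {cr}: invalid matrix")
    cr = max(cr, 0.0)
    ci = max(ci, 0.0)
    return ConsistencyReport(
        n=n, lambda_max=lambda_max, ci=ci, ri=ri_val, cr=cr,
        passed=cr < threshold, threshold=threshold,
    )


def aggregate_expert_matrices(
    matrices: Iterable[Union[PairwiseMatrix, np.ndarray]],
) -> PairwiseMatrix:
    """Element-wise geometric mean of expert matrices.

    All matrices must share dimension and labels.  The upper triangle is
    averaged in log space and the lower triangle set to its exact
    reciprocal, so the aggregate is reciprocal by construction.
    """
    mats = [_as_matrix(m) for m in matrices]
    if not mats:
        raise AhpError("no matrices to aggregate")
    n = mats[0].n
    labels = mats[0].labels
    for m in mats[1:]:
        if m.n != n:
            raise AhpError(f"dimension mismatch: {m.n} != {n}")
        if m.labels != labels:
            raise AhpError(f"label mismatch: {m.labels} != {labels}")
    log_mean = np.mean([np.log(m.values) for m in mats], axis=0)
    agg = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    agg[iu] = np.exp(log_mean[iu])
    agg[(iu[1], iu[0])] = 1.0 / agg[iu]
    return PairwiseMatrix(agg, labels)
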