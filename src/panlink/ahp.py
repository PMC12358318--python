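"""Analytic Hierarchy Process: factor weights from an expert pairwise
comparison matrix, with Saaty consistency checking.

The comparison matrix holds relative-importance judgements a_ij > 0 with
a_ii = 1 and (up to rounding of the published/elicited entries) a_ij = 1/a_ji.
Weights are the normalized principal right eigenvector obtained by power
iteration; the consistency index CI = (lambda_max - n)/(n - 1) is scaled by
Saaty's random index RI(n) to the consistency ratio CR, acceptable when
CR < 0.10.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PairwiseMatrix",
    "WeightVector",
    "compute_weights",
    "consistency_ratio",
    "SAATY_RI",
    "read_matrix_csv",
    "write_weights_csv",
]

#: Saaty's random consistency index by matrix order.
SAATY_RI = {3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

#: Default factor ordering of the ten-criterion resistance comparison.
DEFAULT_LABELS = ("E1", "E2", "E3", "E4", "E5", "A1", "A2.1", "A2.2", "A2.3", "A3")

#: Worked example: a ten-criterion comparison matrix elicited from an expert
#: panel scoring how strongly each resistance factor impedes protected-area
#: connectivity on a developed coast.  Entries are rounded to the precision
#: they were published at, so reciprocity holds only approximately (the soft
#: check warns).  Anthropogenic factors (A1..A3) dominate the ecological
#: gradient factors (E1..E5) by roughly 2.2-2.6 to 1.
EXAMPLE_EXPERT_MATRIX = (
    (1.000, 0.957, 1.032, 0.985, 1.049, 0.405, 0.463, 0.447, 0.440, 0.430),
    (1.045, 1.000, 1.078, 1.029, 1.107, 0.423, 0.480, 0.467, 0.460, 0.449),
    (0.969, 0.928, 1.000, 0.955, 1.017, 0.393, 0.445, 0.433, 0.427, 0.420),
    (1.1015, 0.972, 1.047, 1.000, 1.065, 0.411, 0.465, 0.453, 0.446, 0.437),
    (0.953, 0.903, 0.983, 0.939, 1.000, 0.386, 0.436, 0.426, 0.419, 0.412),
    (2.468, 2.364, 2.545, 2.433, 2.591, 1.000, 1.142, 1.102, 1.086, 1.071),
    (2.160, 2.083, 2.247, 2.151, 2.294, 0.876, 1.000, 0.962, 0.943, 0.930),
    (2.237, 2.141, 2.310, 2.208, 2.346, 0.907, 1.039, 1.000, 0.980, 0.965),
    (2.272, 2.174, 2.343, 2.243, 2.387, 0.921, 1.060, 1.020, 1.000, 0.985),
    (2.326, 2.227, 2.381, 2.287, 2.427, 0.934, 1.075, 1.036, 1.015, 1.000),
)


def example_expert_matrix() -> "PairwiseMatrix":
    """The package's worked-example ten-factor expert matrix."""
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # rounded entries trip the reciprocity warning
        return PairwiseMatrix(labels=DEFAULT_LABELS,
                              a=np.array(EXAMPLE_EXPERT_MATRIX))


@dataclass
class PairwiseMatrix:
    """Reciprocal pairwise comparison matrix with labeled criteria.

    Reciprocity is a soft check: published matrices carry rounded entries, so
    |a_ij * a_ji - 1| above ``reciprocity_tol`` warns and above
    ``reciprocity_reject`` (relative error 0.10) raises.
    """

    labels: tuple[str, ...]
    a: np.ndarray
    reciprocity_tol: float = 0.02
    reciprocity_reject: float = 0.10

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.a = np.asarray(self.a, dtype=np.float64)
        n = len(self.labels)
        if self.a.shape != (n, n):
            raise ValueError(f"matrix shape {self.a.shape} does not match {n} labels")
        if not np.all(self.a > 0):
            raise ValueError("pairwise comparison entries must all be positive")
        if not np.allclose(np.diag(self.a), 1.0, atol=1e-9):
            raise ValueError("diagonal entries must equal 1")
        err = np.abs(self.a * self.a.T - 1.0)
        worst = float(err.max())
        if worst > self.reciprocity_reject:
            raise ValueError(
                f"reciprocity violated: max |a_ij*a_ji - 1| = {worst:.4f} > "
                f"{self.reciprocity_reject}"
            )
        if worst > self.reciprocity_tol:
            warnings.warn(
                f"rounded pairwise entries: max |a_ij*a_ji - 1| = {worst:.4f}",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class WeightVector:
    """Normalized AHP factor weights plus consistency statistics."""

    labels: tuple[str, ...]
    w: np.ndarray
    lambda_max: float
    ci: float
    cr: float
    ri: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if not np.isclose(self.w.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {lab: float(wi) for lab, wi in zip(self.labels, self.w)}


def _principal_eigenvector(a: np.ndarray, tol: float = 1e-10,
                           max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """Power iteration for the Perron vector of a positive matrix.

    Returns (unit-sum eigenvector, lambda_max from the Rayleigh quotient)."""
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        y = a @ w
        s = y.sum()
        if not np.isfinite(s) or s <= 0:
            raise ArithmeticError("power iteration diverged")
        y /= s
        lam = float((y @ (a @ y)) / (y @ y))
        if np.max(np.abs(y - w)) < tol:
            return y, lam
        w = y
    raise ArithmeticError(f"power iteration did not converge in {max_iter} steps")


def compute_weights(m: PairwiseMatrix, tol: float = 1e-10,
                    max_iter: int = 10_000) -> WeightVector:
    """Factor weights = normalized principal right eigenvector of the matrix."""
    w, lam = _principal_eigenvector(m.a, tol=tol, max_iter=max_iter)
    n = m.n
    if n >= 3:
        ci, cr, ri = _consistency_from_lambda(lam, n)
    else:
        ci, cr, ri = 0.0, 0.0, float("nan")
    return WeightVector(labels=m.labels, w=w, lambda_max=lam, ci=ci, cr=cr, ri=ri)


def _consistency_from_lambda(lambda_max: float, n: int) -> tuple[float, float, float]:
    if n not in SAATY_RI:
        raise ValueError(f"random index undefined for n={n} (table covers 3..10)")
    ri = SAATY_RI[n]
    ci = (lambda_max - n) / (n - 1)
    cr = ci / ri
    # lambda_max >= n for reciprocal matrices; tiny negative CI is numerical noise
    if -1e-9 < ci < 0:
        ci, cr = 0.0, 0.0
    return ci, cr, ri


def consistency_ratio(m: PairwiseMatrix) -> tuple[float, float]:
    """(CI, CR) of the matrix; requires 3 <= n <= 10 (Saaty's RI table)."""
    if m.n < 3:
        raise ValueError("consistency ratio is undefined for n < 3")
    _, lam = _principal_eigenvector(m.a)
    ci, cr, _ = _consistency_from_lambda(lam, m.n)
    return ci, cr


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_matrix_csv(path: str | Path, **kwargs) -> PairwiseMatrix:
    """Read a labeled (n+1 x n+1) comparison matrix CSV (header row + column)."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    labels = tuple(c.strip() for c in rows[0][1:])
    a = np.array([[float(c) for c in r[1 : len(labels) + 1]] for r in rows[1:]])
    return PairwiseMatrix(labels=labels, a=a, **kwargs)


def write_weights_csv(wv: WeightVector, path: str | Path) -> None:
    """Weights at 4 decimals plus lambda_max / CI / CR footer rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["criteria", "weight"])
        for lab, wi in zip(wv.labels, wv.w):
            w.writerow([lab, f"{wi:.4f}"])
        w.writerow(["lambda_max", f"{wv.lambda_max:.6f}"])
        w.writerow(["ci", f"{wv.ci:.6f}"])
        w.writerow(["cr", f"{wv.cr:.6f}"])
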