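"""Commonality analysis: unique and shared variance across 3 predictors.

For a criterion y and predictors A, B, C the all-orderings hierarchical
regression procedure reduces to comparing the R-squared values of all
seven predictor subsets:

    unique(A)      = R2(ABC) - R2(BC)
    shared(A, B)   = R2(AC) + R2(BC) - R2(ABC) - R2(C)
    shared(A, B, C)= R2(ABC) - R2(AB) - R2(AC) - R2(BC)
                     + R2(A) + R2(B) + R2(C)

(and cyclic permutations).  The seven components always sum exactly to
the full-model R2.  Shared components can be negative under statistical
suppression and are reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "CommonalityDecomposition",
    "subset_r2",
    "commonality",
    "commonality_from_correlations",
]


@dataclass(frozen=True)
class CommonalityDecomposition:
    """Unique, pairwise-shared and three-way-shared variance components.

    All values are proportions of criterion variance; labels identify
    the predictors (A, B, C in input order).
    """

    labels: tuple[str, str, str]
    unique: tuple[float, float, float]
    shared_pairs: dict[str, float]       # keys like "A,B" using labels
    shared_all: float
    r2_full: float

    @property
    def total(self) -> float:
        return float(
            sum(self.unique) + sum(self.shared_pairs.values()) + self.shared_all
        )

    def to_dict(self) -> dict:
        d = {f"unique_{lab}": u for lab, u in zip(self.labels, self.unique)}
        d.update({f"shared_{k}": v for k, v in self.shared_pairs.items()})
        d["shared_all"] = self.shared_all
        d["r2_full"] = self.r2_full
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.to_dict().items()), columns=["component", "value"]
        )


def subset_r2(y: np.ndarray, X: np.ndarray, subset) -> float:
    """OLS coefficient of determination for a predictor subset.

    An intercept is always included.  Raises on singular designs,
    naming the offending predictor columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    subset = list(subset)
    if not subset:
        raise ValueError("subset must contain at least one predictor")
    Xs = X[:, subset]
    if np.any(Xs.std(axis=0) == 0):
        bad = [subset[k] for k in np.where(Xs.std(axis=0) == 0)[0]]
        raise ValueError(f"constant predictor column(s) {bad} in subset")
    design = np.column_stack([np.ones(len(y)), Xs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"collinear predictor columns {subset}: singular design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("criterion has zero variance")
    return 1.0 - float((resid**2).sum()) / sst


def _decompose(r2: dict[frozenset, float], labels) -> CommonalityDecomposition:
    """Assemble components from the 7 subset R2 values keyed by index set."""
    A, B, C = 0, 1, 2
    R = lambda *ix: r2[frozenset(ix)]
    unique = (
        R(A, B, C) - R(B, C),
        R(A, B, C) - R(A, C),
        R(A, B, C) - R(A, B),
    )
    pairs = {}
    for (i, j) in combinations((A, B, C), 2):
        (k,) = {A, B, C} - {i, j}
        pairs[f"{labels[i]},{labels[j]}"] = R(i, k) + R(j, k) - R(A, B, C) - R(k)
    shared_all = (
        R(A, B, C)
        - R(A, B) - R(A, C) - R(B, C)
        + R(A) + R(B) + R(C)
    )
    if any(v < -1e-10 for v in pairs.values()) or shared_all < -1e-10:
        warnings.warn(
            "negative shared variance component (suppression); reported as-is",
            stacklevel=3,
        )
    return CommonalityDecomposition(
        labels=tuple(labels),
        unique=tuple(float(u) for u in unique),
        shared_pairs={k: float(v) for k, v in pairs.items()},
        shared_all=float(shared_all),
        r2_full=float(R(A, B, C)),
    )


def commonality(
    y,
    x1,
    x2,
    x3,
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> CommonalityDecomposition:
    """Full commonality decomposition from raw data vectors."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.column_stack([np.asarray(x, dtype=float).ravel() for x in (x1, x2, x3)])
    if X.shape[0] != y.shape[0]:
        raise ValueError("predictors and criterion have unequal lengths")
    if y.shape[0] <= 10:
        raise ValueError("commonality analysis needs n > 10 observations")
    r2 = {
        frozenset(sub): subset_r2(y, X, sub)
        for r in (1, 2, 3)
        for sub in combinations(range(3), r)
    }
    return _decompose(r2, labels)


def commonality_from_correlations(
    R_xx,
    r_xy,
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> CommonalityDecomposition:
    """Decomposition from a 3x3 predictor correlation matrix and validities.

    Uses the closed form R2(subset) = r' R^-1 r on each subset, so the
    result matches :func:`commonality` applied to any dataset with
    exactly these correlations (e.g. latent-variable correlations from
    a fitted structural model).
    """
    R_xx = np.asarray(R_xx, dtype=float)
    r_xy = np.asarray(r_xy, dtype=float).ravel()
    if R_xx.shape != (3, 3) or r_xy.shape != (3,):
        raise ValueError("expected a 3x3 correlation matrix and 3 validities")
    if not np.allclose(R_xx, R_xx.T, atol=1e-10):
        raise ValueError("predictor correlation matrix is not symmetric")
    eig = np.linalg.eigvalsh(R_xx)
    if eig[0] <= 0:
        raise ValueError(
            f"predictor correlation matrix not positive definite (min eig {eig[0]:.3g})"
        )
    r2 = {}
    for r in (1, 2, 3):
        for sub in combinations(range(3), r):
            ix = list(sub)
            r2[frozenset(sub)] = float(
                r_xy[ix] @ np.linalg.solve(R_xx[np.ix_(ix, ix)], r_xy[ix])
            )
    return _decompose(r2, labels)
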