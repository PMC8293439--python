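"""Two-factor non-compensatory logistic item responses and test scores.

The response function multiplies a logistic success probability for the
domain-general factor by one for the domain-specific factor:

    P = logistic(a_g * (z(theta_g) - b_g)) * logistic(a_s * (z(theta_s) - b_s))

Processes are compensatory within a pool (only the summed theta
matters) but non-compensatory across pools: a sufficiently low z on
either factor caps the product near zero no matter how able the person
is on the other factor.  Thetas are z-scored across persons per (test,
item) so that difficulties drawn from Normal(0, sd) live on the same
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .process_space import ConfigurationError, SimulationConfig
from .sampling_design import TestBlueprint, ThetaArray

__all__ = [
    "ItemBank",
    "ResponseArray",
    "ScoreMatrix",
    "standardize_theta",
    "draw_item_difficulties",
    "pot_probability",
    "response_probabilities",
    "draw_responses",
    "aggregate_scores",
]


def standardize_theta(theta: ThetaArray, ddof: int = 1) -> ThetaArray:
    """Z-score thetas across persons within each (test, item) cell.

    Cells with zero cross-person variance (e.g. an item whose sampling
    vector is all zeros, so theta is constant) are mapped to z = 0 for
    every person rather than NaN.
    """
    def z(arr: np.ndarray) -> np.ndarray:
        mean = arr.mean(axis=0, keepdims=True)
        sd = arr.std(axis=0, ddof=ddof, keepdims=True)
        out = np.zeros_like(arr)
        np.divide(arr - mean, sd, out=out, where=sd > 0)
        return out

    return ThetaArray(
        theta_g=z(theta.theta_g), theta_s=z(theta.theta_s), test_ids=theta.test_ids
    )


@dataclass(frozen=True)
class ItemBank:
    """Discrimination and difficulty parameters per (test, item).

    ``b_g[t]`` / ``b_s[t]`` are length-``n_items`` difficulty arrays for
    the general and specific factors of test t; discriminations are a
    single shared constant.
    """

    b_g: list[np.ndarray]
    b_s: list[np.ndarray]
    discrimination: float
    test_ids: list[str]

    def __post_init__(self) -> None:
        if self.discrimination <= 0:
            raise ConfigurationError("discrimination must be > 0")
        if not (len(self.b_g) == len(self.b_s) == len(self.test_ids)):
            raise ConfigurationError("item bank lists must align with test ids")
        for bg, bs in zip(self.b_g, self.b_s):
            if bg.shape != bs.shape or bg.ndim != 1:
                raise ConfigurationError("difficulty arrays malformed")
            if not (np.all(np.isfinite(bg)) and np.all(np.isfinite(bs))):
                raise ConfigurationError("difficulties contain non-finite values")


def draw_item_difficulties(
    blueprints: list[TestBlueprint],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ItemBank:
    """Draw independent normal difficulties per item and factor.

    Broad-ability tests use sd ``difficulty_sd_broad`` (default 1); EF
    tests use the much tighter ``difficulty_sd_ef`` (default 0.05),
    reflecting near-constant difficulty of executive tasks.  b_g and b_s
    are drawn independently (no within-item correlation is imposed).
    """
    b_g, b_s = [], []
    for bp in blueprints:
        sd = config.difficulty_sd_ef if bp.is_ef else config.difficulty_sd_broad
        b_g.append(rng.normal(0.0, sd, bp.n_items))
        b_s.append(rng.normal(0.0, sd, bp.n_items))
    return ItemBank(
        b_g=b_g,
        b_s=b_s,
        discrimination=config.discrimination,
        test_ids=[bp.test_id for bp in blueprints],
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    # scipy.special.expit without the import; stable for large |x|
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def pot_probability(factors: list[tuple[float, float, float]]) -> float | np.ndarray:
    """Probability of a correct response as a product over domains.

    Each factor is a tuple ``(z, b, a)`` — standardized aggregate
    ability, difficulty and discrimination for one domain.  The result
    is ``prod_l logistic(a_l * (z_l - b_l))``: compensatory within each
    domain (z already aggregates the sampled processes) and
    non-compensatory across domains.  With two factors and a = 1 this is
    the simulator's response function.  Entries may be arrays of a
    common shape.
    """
    if not factors:
        raise ValueError("pot_probability requires at least one (z, b, a) factor")
    prob: float | np.ndarray = 1.0
    for z, b, a in factors:
        a = np.asarray(a, dtype=float)
        if np.any(a <= 0):
            raise ValueError("discrimination parameters must be > 0")
        prob = prob * _logistic(a * (np.asarray(z, dtype=float) - b))
    return prob


def response_probabilities(z: ThetaArray, bank: ItemBank) -> np.ndarray:
    """Vectorized two-factor response probabilities, persons x tests x items."""
    if z.test_ids != bank.test_ids:
        raise ConfigurationError("theta and item bank test ids differ")
    n_subj, n_tests, n_items = z.shape
    P = np.empty((n_subj, n_tests, n_items))
    a = bank.discrimination
    for t in range(n_tests):
        P[:, t, :] = _logistic(a * (z.theta_g[:, t, :] - bank.b_g[t])) * _logistic(
            a * (z.theta_s[:, t, :] - bank.b_s[t])
        )
    return P


@dataclass(frozen=True)
class ResponseArray:
    """Binary item responses and the probabilities that generated them."""

    U: np.ndarray
    P: np.ndarray
    test_ids: list[str]

    def __post_init__(self) -> None:
        if self.U.shape != self.P.shape or self.U.ndim != 3:
            raise ConfigurationError("response arrays malformed")
        if not np.isin(self.U, (0, 1)).all():
            raise ConfigurationError("responses must be binary")


def draw_responses(
    P: np.ndarray, rng: np.random.Generator, test_ids: list[str]
) -> ResponseArray:
    """Draw independent Bernoulli responses from a probability array."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > 1) or not np.all(np.isfinite(P)):
        raise ValueError("response probabilities must lie in [0, 1]")
    U = (rng.random(P.shape) < P).astype(np.int8)
    return ResponseArray(U=U, P=P, test_ids=test_ids)


@dataclass(frozen=True)
class ScoreMatrix:
    """Persons x tests integer test scores (number-correct)."""

    values: np.ndarray
    test_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.test_ids):
            raise ConfigurationError("score matrix shape inconsistent with test ids")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.test_ids)
        df.index.name = "subject"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def covariance(self, ddof: int = 1) -> pd.DataFrame:
        """Sample covariance of the test scores (N-1 denominator)."""
        return self.to_frame().cov(ddof=ddof)


def aggregate_scores(responses: ResponseArray) -> ScoreMatrix:
    """Sum binary item responses into number-correct test scores."""
    return ScoreMatrix(
        values=responses.U.sum(axis=2, dtype=np.int64), test_ids=responses.test_ids
    )
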