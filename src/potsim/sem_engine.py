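"""Covariance-structure (SEM) engine: model specs, ML fitting, fit indices.

Models are expressed in RAM form over the stacked vector of observed
and latent variables: ``A`` holds directed coefficients (loadings and
regressions), ``S`` holds variances and covariances of exogenous terms
and residuals.  The implied covariance of the observed block is

    Sigma = F (I - A)^-1 S (I - A)^-T F^T

with ``F`` the filter onto observed variables.  Fitting minimizes the
normal-theory maximum-likelihood discrepancy

    F_ML = ln|Sigma| - ln|S_sample| + tr(S_sample Sigma^-1) - p

by quasi-Newton iteration with an analytic gradient; the model test
statistic is chi-square = (N - 1) F_ML.

Identification uses the marker-variable rule: the first loading of each
latent variable is fixed to 1.  The fully standardized solution is
computed afterwards from the implied joint covariance of all variables
and is invariant to that choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SemModelSpec",
    "SemFit",
    "FitIndices",
    "model1_spec",
    "model2_spec",
    "study2_spec",
    "saturated_spec",
    "implied_covariance",
    "fit_ml",
    "fit_indices",
    "rmsea_ci",
    "standardized_solution",
    "factor_scores",
    "SemInputError",
]

BROAD_TEST_IDS = (
    "fluid1", "fluid2", "fluid3",
    "verbal1", "verbal2", "verbal3",
    "spatial1", "spatial2", "spatial3",
)
EF_TEST_IDS = ("inhibition", "updating", "shifting")


class SemInputError(ValueError):
    """Raised for structurally invalid model or data input."""


@dataclass(frozen=True)
class Param:
    """One cell of A (op '~') or S (op '~~').

    ``lhs ~ rhs`` means an arrow rhs -> lhs with coefficient A[lhs, rhs]
    (a loading when rhs is latent, a regression otherwise);
    ``lhs ~~ rhs`` is the symmetric S entry (a variance when lhs == rhs).
    ``value`` of None marks the parameter free.
    """

    lhs: str
    op: str
    rhs: str
    value: float | None = None

    @property
    def free(self) -> bool:
        return self.value is None

    @property
    def label(self) -> str:
        return f"{self.lhs}{self.op}{self.rhs}"


@dataclass(frozen=True)
class SemModelSpec:
    """A covariance-structure model over named observed/latent variables."""

    observed: tuple[str, ...]
    latent: tuple[str, ...]
    params: tuple[Param, ...]

    def __post_init__(self) -> None:
        names = self.observed + self.latent
        if len(set(names)) != len(names):
            raise SemInputError("duplicate variable names in model spec")
        for p in self.params:
            if p.op not in ("~", "~~"):
                raise SemInputError(f"unknown operator {p.op!r}")
            for v in (p.lhs, p.rhs):
                if v not in names:
                    raise SemInputError(f"parameter references unknown variable {v!r}")
        seen = set()
        for p in self.params:
            key = (p.op,) + (
                tuple(sorted((p.lhs, p.rhs))) if p.op == "~~" else (p.lhs, p.rhs)
            )
            if key in seen:
                raise SemInputError(f"duplicate parameter {p.label}")
            seen.add(key)
        mentioned = {p.lhs for p in self.params} | {p.rhs for p in self.params}
        for v in self.observed:
            if v not in mentioned:
                raise SemInputError(f"observed variable {v!r} appears in no equation")

    # -- bookkeeping --------------------------------------------------

    @property
    def all_vars(self) -> tuple[str, ...]:
        return self.observed + self.latent

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def free_params(self) -> tuple[Param, ...]:
        return tuple(p for p in self.params if p.free)

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    @property
    def df(self) -> int:
        p = self.n_observed
        return p * (p + 1) // 2 - self.n_free

    def index(self, name: str) -> int:
        return self.all_vars.index(name)

    def build_matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fill A and S from a free-parameter vector (fixed values baked in)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise SemInputError(
                f"expected {self.n_free} free parameters, got {theta.shape}"
            )
        n = len(self.all_vars)
        A = np.zeros((n, n))
        S = np.zeros((n, n))
        k = 0
        for p in self.params:
            val = theta[k] if p.free else p.value
            if p.free:
                k += 1
            i, j = self.index(p.lhs), self.index(p.rhs)
            if p.op == "~":
                A[i, j] = val
            else:
                S[i, j] = val
                S[j, i] = val
        return A, S

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "observed": list(self.observed),
            "latent": list(self.latent),
            "params": [
                {"lhs": p.lhs, "op": p.op, "rhs": p.rhs, "value": p.value}
                for p in self.params
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SemModelSpec":
        return cls(
            observed=tuple(d["observed"]),
            latent=tuple(d["latent"]),
            params=tuple(Param(**p) for p in d["params"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SemModelSpec":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------
# Stock model builders
# ---------------------------------------------------------------------

def _measurement(
    factor: str, indicators: Sequence[str], marker: bool = True
) -> list[Param]:
    """Marker-identified loadings plus free residual variances."""
    out = []
    for k, ind in enumerate(indicators):
        fixed = 1.0 if (marker and k == 0) else None
        out.append(Param(ind, "~", factor, fixed))
        out.append(Param(ind, "~~", ind))
    return out


def model1_spec(test_ids: Sequence[str] = BROAD_TEST_IDS) -> SemModelSpec:
    """Higher-order CFA: 9 tests -> fluid/verbal/spatial -> g.

    Three tests load on each first-order broad-ability factor and the
    three factors load on a single second-order general factor.  Marker
    identification throughout; residuals uncorrelated.  df = 24.
    """
    if len(test_ids) != 9:
        raise SemInputError("model 1 requires exactly 9 test ids (3 per factor)")
    factors = ("Fluid", "Verbal", "Spatial")
    params: list[Param] = []
    for f, ids in zip(factors, np.array_split(np.asarray(test_ids, dtype=object), 3)):
        params += _measurement(f, list(ids))
    for k, f in enumerate(factors):
        params.append(Param(f, "~", "g", 1.0 if k == 0 else None))
        params.append(Param(f, "~~", f))  # first-order disturbance
    params.append(Param("g", "~~", "g"))
    return SemModelSpec(
        observed=tuple(test_ids), latent=factors + ("g",), params=tuple(params)
    )


def model2_spec(
    test_ids: Sequence[str] = BROAD_TEST_IDS,
    ef_ids: Sequence[str] = EF_TEST_IDS,
) -> SemModelSpec:
    """Model 1 plus three orthogonal manifest EF predictors of g.

    The EF test scores enter as exogenous observed variables regressing
    on g, with free variances and covariances fixed to zero (the
    simulated executive attention processes are independent).  The g
    variance becomes a free disturbance.  df = 51.
    """
    base = model1_spec(test_ids)
    if len(ef_ids) != 3:
        raise SemInputError("model 2 requires exactly 3 EF predictor ids")
    params = list(base.params)
    for ef in ef_ids:
        params.append(Param("g", "~", ef))
        params.append(Param(ef, "~~", ef))
    for i in range(3):
        for j in range(i + 1, 3):
            params.append(Param(ef_ids[i], "~~", ef_ids[j], 0.0))
    return SemModelSpec(
        observed=base.observed + tuple(ef_ids),
        latent=base.latent,
        params=tuple(params),
    )


def study2_spec(structure: Mapping) -> SemModelSpec:
    """Three latent EF factors predicting g, from a structure config.

    ``structure`` maps EF factor names to indicator lists under
    ``"factors"``, and describes the criterion under ``"g"`` as either
    ``{"indicators": [...]}`` (latent g) or ``{"composite": name}``
    (manifest criterion).  ``"ef_covariances"`` is ``"zero"`` (default,
    mirroring the orthogonal-process simulation) or ``"free"``.
    """
    factors: Mapping[str, Sequence[str]] = structure["factors"]
    if not factors:
        raise SemInputError("structure must define at least one EF factor")
    g_cfg = structure.get("g", {})
    ef_cov = structure.get("ef_covariances", "zero")
    if ef_cov not in ("zero", "free"):
        raise SemInputError(f"ef_covariances must be 'zero' or 'free', got {ef_cov!r}")

    observed: list[str] = []
    params: list[Param] = []
    names = list(factors)
    for fname, inds in factors.items():
        if not inds:
            raise SemInputError(f"factor {fname!r} has no indicators")
        observed += list(inds)
        params += _measurement(fname, inds)
        params.append(Param(fname, "~~", fname))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            params.append(
                Param(names[i], "~~", names[j], None if ef_cov == "free" else 0.0)
            )

    latent = list(names)
    if "indicators" in g_cfg:
        g_inds = list(g_cfg["indicators"])
        observed += g_inds
        params += _measurement("g", g_inds)
        criterion = "g"
        latent.append("g")
        params.append(Param("g", "~~", "g"))  # disturbance
    elif "composite" in g_cfg:
        criterion = g_cfg["composite"]
        observed.append(criterion)
        params.append(Param(criterion, "~~", criterion))
    else:
        raise SemInputError("structure['g'] needs 'indicators' or 'composite'")
    for fname in names:
        params.append(Param(criterion, "~", fname))
    dup = [v for v in observed if observed.count(v) > 1]
    if dup:
        raise SemInputError(f"indicator(s) assigned twice: {sorted(set(dup))}")
    return SemModelSpec(
        observed=tuple(observed), latent=tuple(latent), params=tuple(params)
    )


def saturated_spec(names: Sequence[str]) -> SemModelSpec:
    """All variances and covariances free; zero df by construction."""
    params = [
        Param(a, "~~", b)
        for i, a in enumerate(names)
        for b in list(names)[i:]
    ]
    return SemModelSpec(observed=tuple(names), latent=(), params=tuple(params))


# ---------------------------------------------------------------------
# Implied covariance and ML fitting
# ---------------------------------------------------------------------

def _joint_covariance(spec: SemModelSpec, theta: np.ndarray) -> np.ndarray:
    """Implied covariance of the stacked (observed + latent) vector."""
    A, S = spec.build_matrices(theta)
    B = np.linalg.inv(np.eye(A.shape[0]) - A)
    return B @ S @ B.T


def implied_covariance(spec: SemModelSpec, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance matrix of the observed variables."""
    p = spec.n_observed
    return _joint_covariance(spec, theta)[:p, :p]


def _as_cov_array(S, observed: Sequence[str]) -> np.ndarray:
    """Coerce a covariance input to an ndarray aligned with the spec order."""
    if isinstance(S, pd.DataFrame):
        missing = [v for v in observed if v not in S.columns]
        if missing:
            raise SemInputError(f"covariance matrix lacks variables {missing}")
        S = S.loc[list(observed), list(observed)].to_numpy(dtype=float)
    else:
        S = np.asarray(S, dtype=float)
        if S.shape != (len(observed), len(observed)):
            raise SemInputError(
                f"covariance matrix shape {S.shape} does not match "
                f"{len(observed)} observed variables"
            )
    if not np.allclose(S, S.T, atol=1e-8):
        raise SemInputError("covariance matrix is not symmetric")
    eigvals = np.linalg.eigvalsh(S)
    if eigvals[0] <= 0:
        raise SemInputError(
            f"covariance matrix not positive definite (min eigenvalue {eigvals[0]:.3g})"
        )
    return S


def _default_starts(spec: SemModelSpec, S: np.ndarray) -> np.ndarray:
    """Heuristic start values anchored to the sample covariance scale.

    Each latent variable is traced through marker loadings to an
    observed anchor; free loadings start at the anchor-covariance ratio,
    variances at half the (anchored) observed variance, regressions and
    covariances at zero-ish.
    """
    obs = {v: i for i, v in enumerate(spec.observed)}

    marker_of: dict[str, str] = {}
    for p in spec.params:
        if p.op == "~" and not p.free and p.value == 1.0 and p.rhs in spec.latent:
            marker_of.setdefault(p.rhs, p.lhs)

    def anchor(var: str, depth: int = 0) -> tuple[int, int]:
        """(observed index, marker depth) reached by following markers."""
        if var in obs:
            return obs[var], depth
        nxt = marker_of.get(var)
        if nxt is None or depth > 10:
            return 0, depth
        return anchor(nxt, depth + 1)

    endogenous = {p.lhs for p in spec.params if p.op == "~"}
    starts = []
    for p in spec.free_params:
        if p.op == "~":
            ia, _ = anchor(p.lhs)
            ib, _ = anchor(p.rhs)
            denom = S[ib, ib]
            starts.append(S[ia, ib] / denom if denom > 0 else 0.1)
        elif p.lhs == p.rhs:
            i, d = anchor(p.lhs)
            halvings = d + 1 if p.lhs not in obs else (1 if p.lhs in endogenous else 0)
            starts.append(max(S[i, i] * 0.5 ** halvings, 1e-3))
        else:
            starts.append(0.0)
    return np.asarray(starts, dtype=float)


def _fml_and_grad(
    spec: SemModelSpec, theta: np.ndarray, S: np.ndarray, logdet_S: float
) -> tuple[float, np.ndarray]:
    """ML discrepancy and its analytic gradient in RAM form."""
    n_all = len(spec.all_vars)
    p = spec.n_observed
    A, Smat = spec.build_matrices(theta)
    try:
        B = np.linalg.inv(np.eye(n_all) - A)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(theta)
    V = B @ Smat @ B.T
    Sigma = V[:p, :p]
    try:
        chol = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(theta)
    logdet_Sigma = 2.0 * np.log(np.diag(chol)).sum()
    Sigma_inv = np.linalg.inv(Sigma)
    fml = logdet_Sigma - logdet_S + float((Sigma_inv * S).sum()) - p
    # W = d F / d Sigma ; lift to the joint space, then chain through RAM
    W = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    Wf = np.zeros((n_all, n_all))
    Wf[:p, :p] = W
    G_A = 2.0 * (V @ Wf @ B)          # d F / d A[dst, src] = G_A[src, dst]
    G_S = B.T @ Wf @ B                # d F / d S[i, j]
    grad = np.empty_like(theta)
    k = 0
    for prm in spec.params:
        if not prm.free:
            continue
        i, j = spec.index(prm.lhs), spec.index(prm.rhs)
        if prm.op == "~":
            grad[k] = G_A[j, i]
        else:
            grad[k] = G_S[i, j] * (1.0 if i == j else 2.0)
        k += 1
    return fml, grad


@dataclass
class FitIndices:
    """Standard absolute and incremental fit measures."""

    cfi: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float

    def to_dict(self) -> dict:
        return {
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "rmsea_ci_lower": self.rmsea_ci[0],
            "rmsea_ci_upper": self.rmsea_ci[1],
            "srmr": self.srmr,
        }


@dataclass
class SemFit:
    """Result of a maximum-likelihood covariance-structure fit."""

    spec: SemModelSpec
    theta: np.ndarray
    fml: float
    chisq: float
    df: int
    pvalue: float
    n_obs: int
    sample_cov: np.ndarray
    implied_cov: np.ndarray
    converged: bool
    n_restarts: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def estimates(self) -> pd.DataFrame:
        """Parameter table (unstandardized and fully standardized)."""
        return standardized_solution(self)

    def standardized_path(self, lhs: str, rhs: str) -> float:
        tab = self.estimates
        row = tab[(tab.lhs == lhs) & (tab.op == "~") & (tab.rhs == rhs)]
        if row.empty:
            raise KeyError(f"no path {lhs} ~ {rhs} in model")
        return float(row["std"].iloc[0])

    def to_dict(self) -> dict:
        fi = fit_indices(self)
        return {
            "chisq": self.chisq,
            "df": self.df,
            "pvalue": self.pvalue,
            "fml": self.fml,
            "n": self.n_obs,
            "converged": self.converged,
            "warnings": list(self.warnings),
            **fi.to_dict(),
            "estimates": self.estimates.to_dict(orient="records"),
        }


def fit_ml(
    spec: SemModelSpec,
    S,
    N: int,
    start: np.ndarray | None = None,
    max_restarts: int = 5,
    rng: np.random.Generator | None = None,
) -> SemFit:
    """Fit a model to a sample covariance matrix by maximum likelihood.

    ``S`` may be a DataFrame (reordered to the spec's variables) or an
    ndarray already in spec order; ``N`` is the number of observations
    behind it.  Correlation matrices are valid input and are treated as
    covariances of standardized variables.  Non-convergence triggers up
    to ``max_restarts`` jittered restarts and is flagged, never silent.
    """
    Sarr = _as_cov_array(S, spec.observed)
    if N <= spec.n_observed:
        raise SemInputError(f"N={N} must exceed the number of observed variables")
    sign, logdet_S = np.linalg.slogdet(Sarr)
    if sign <= 0:
        raise SemInputError("sample covariance has non-positive determinant")
    rng = rng or np.random.default_rng(0)

    if spec.n_free == 0:
        theta = np.empty(0)
        fml, _ = _fml_and_grad(spec, theta, Sarr, logdet_S)
        return _finalize(spec, theta, fml, Sarr, N, converged=True, n_restarts=0)

    theta0 = np.asarray(start, dtype=float) if start is not None else _default_starts(spec, Sarr)
    best = None
    attempts = 0
    for attempt in range(max_restarts + 1):
        attempts = attempt
        x0 = theta0 if attempt == 0 else theta0 * rng.uniform(0.7, 1.3, theta0.shape) + rng.normal(0, 0.05, theta0.shape)
        res = optimize.minimize(
            lambda th: _fml_and_grad(spec, th, Sarr, logdet_S),
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-8},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        ok = res.fun < 1e11 and (res.success or gnorm < 1e-6)
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok:
            break
    res, ok = best
    return _finalize(spec, res.x, float(res.fun), Sarr, N, converged=ok, n_restarts=attempts)


def _finalize(spec, theta, fml, Sarr, N, converged, n_restarts) -> SemFit:
    fml = max(fml, 0.0)
    chisq = (N - 1) * fml
    df = spec.df
    pvalue = float(stats.chi2.sf(chisq, df)) if df > 0 else float("nan")
    warnings = []
    if not converged:
        warnings.append("optimizer did not converge; estimates unreliable")
    _, Smat = spec.build_matrices(theta)
    k = 0
    for prm in spec.params:
        val = theta[k] if prm.free else prm.value
        if prm.free:
            k += 1
        if prm.op == "~~" and prm.lhs == prm.rhs and val < 0:
            warnings.append(f"negative variance estimate for {prm.lhs} (Heywood case)")
    return SemFit(
        spec=spec,
        theta=np.asarray(theta, dtype=float),
        fml=fml,
        chisq=chisq,
        df=df,
        pvalue=pvalue,
        n_obs=int(N),
        sample_cov=Sarr,
        implied_cov=implied_covariance(spec, theta),
        converged=converged,
        n_restarts=n_restarts,
        warnings=warnings,
    )


# ---------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------

def _independence_chisq(S: np.ndarray, N: int) -> tuple[float, int]:
    """Chi-square and df of the zero-covariance baseline model."""
    p = S.shape[0]
    _, logdet = np.linalg.slogdet(S)
    f_b = float(np.log(np.diag(S)).sum() - logdet)
    return (N - 1) * max(f_b, 0.0), p * (p - 1) // 2


def rmsea_point(chisq: float, df: int, N: int) -> float:
    if df == 0:
        return float("nan")
    return float(np.sqrt(max(chisq - df, 0.0) / (df * (N - 1))))


def rmsea_ci(chisq: float, df: int, N: int, level: float = 0.90) -> tuple[float, float]:
    """Confidence interval for RMSEA by noncentral chi-square inversion.

    The lower (upper) bound solves ``P(X <= chisq | df, lam) = (1+level)/2``
    (``(1-level)/2``) for the noncentrality ``lam``, clamped at 0 when no
    root exists, then maps through ``sqrt(lam / (df (N-1)))``.
    """
    if df == 0:
        return (float("nan"), float("nan"))
    hi_q, lo_q = (1.0 - level) / 2.0, (1.0 + level) / 2.0

    def solve(target: float) -> float:
        # ncx2.cdf decreases in lam; find lam with cdf == target
        if stats.chi2.cdf(chisq, df) < target:
            return 0.0
        lo, hi = 0.0, 1.0
        while stats.ncx2.cdf(chisq, df, hi) > target:
            hi *= 2.0
            if hi > 1e8:
                return float("nan")
        return float(
            optimize.brentq(
                lambda lam: stats.ncx2.cdf(chisq, df, max(lam, 1e-12)) - target,
                lo, hi, xtol=1e-10,
            )
        )

    lam_lo = solve(lo_q)
    lam_hi = solve(hi_q)
    scale = df * (N - 1)
    return (float(np.sqrt(lam_lo / scale)), float(np.sqrt(lam_hi / scale)))


def srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Standardized root-mean-square residual, diagonal included."""
    d_s = np.sqrt(np.diag(S))
    d_m = np.sqrt(np.diag(Sigma))
    R = S / np.outer(d_s, d_s) - Sigma / np.outer(d_m, d_m)
    iu = np.triu_indices_from(R)
    return float(np.sqrt(np.mean(R[iu] ** 2)))


def fit_indices(fit: SemFit, S: np.ndarray | None = None, N: int | None = None) -> FitIndices:
    """CFI (independence baseline), RMSEA with 90% CI, and SRMR."""
    S = fit.sample_cov if S is None else _as_cov_array(S, fit.spec.observed)
    N = fit.n_obs if N is None else N
    chisq_b, df_b = _independence_chisq(S, N)
    num = max(fit.chisq - fit.df, 0.0)
    den = max(fit.chisq - fit.df, chisq_b - df_b, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    return FitIndices(
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        rmsea=rmsea_point(fit.chisq, fit.df, N),
        rmsea_ci=rmsea_ci(fit.chisq, fit.df, N),
        srmr=srmr(S, fit.implied_cov),
    )


# ---------------------------------------------------------------------
# Standardized solution and factor scores
# ---------------------------------------------------------------------

def standardized_solution(fit: SemFit) -> pd.DataFrame:
    """Parameter table with fully standardized estimates.

    Standardization rescales every variable (observed and latent) to
    unit model-implied variance: a path coefficient a_ij becomes
    a_ij * sd(j) / sd(i) and a covariance s_ij becomes a correlation.
    """
    spec = fit.spec
    V = _joint_covariance(spec, fit.theta)
    sd = np.sqrt(np.clip(np.diag(V), 1e-300, None))
    rows = []
    k = 0
    for prm in spec.params:
        val = fit.theta[k] if prm.free else prm.value
        if prm.free:
            k += 1
        i, j = spec.index(prm.lhs), spec.index(prm.rhs)
        if prm.op == "~":
            std = val * sd[j] / sd[i]
        else:
            std = val / (sd[i] * sd[j])
        rows.append((prm.lhs, prm.op, prm.rhs, prm.free, float(val), float(std)))
    return pd.DataFrame(rows, columns=["lhs", "op", "rhs", "free", "est", "std"])


def factor_scores(
    fit: SemFit,
    data,
    latent: str = "g",
) -> np.ndarray:
    """Regression-method factor scores for one latent variable.

    Weights are ``Sigma^-1 Cov(observed, latent)`` from the fitted
    model; scores are those weights applied to the centered observed
    scores, hence mean zero by construction.
    """
    spec = fit.spec
    if latent not in spec.latent:
        raise SemInputError(f"{latent!r} is not a latent variable of this model")
    if hasattr(data, "to_frame") and not isinstance(data, pd.DataFrame):
        data = data.to_frame()
    if isinstance(data, pd.DataFrame):
        X = data.loc[:, list(spec.observed)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if X.shape[1] != spec.n_observed:
            raise SemInputError("data columns do not match the model's observed set")
    V = _joint_covariance(spec, fit.theta)
    p = spec.n_observed
    cov_obs_latent = V[:p, spec.index(latent)]
    weights = np.linalg.solve(fit.implied_cov, cov_obs_latent)
    return (X - X.mean(axis=0)) @ weights
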