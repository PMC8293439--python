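"""Monte-Carlo orchestration: full simulation replications and summaries.

One iteration runs the whole pipeline — orthogonal abilities, item
sampling vectors, aggregate thetas, z-scoring, two-factor logistic
responses, number-correct scores — then fits the higher-order CFA
(model 1) and the CFA-plus-EF-predictors model (model 2) to the score
covariance matrix and decomposes the variance of the g factor scores
over the three EF test scores.  A study is ``n_iterations`` independent
replications aggregated into means and SDs.

Seeding: iteration i uses ``SeedSequence(master_seed, spawn_key=(i,))``
split into four named substreams (abilities, sampling, difficulties,
responses), so any iteration is independently re-runnable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .commonality import (
    CommonalityDecomposition,
    commonality,
    commonality_from_correlations,
)
from .process_space import SimulationConfig, generate_abilities
from .response_model import (
    aggregate_scores,
    draw_item_difficulties,
    draw_responses,
    response_probabilities,
    standardize_theta,
)
from .sampling_design import SamplingDesign, aggregate_theta, build_design, default_blueprints
from .sem_engine import (
    EF_TEST_IDS,
    FitIndices,
    SemFit,
    SemInputError,
    _joint_covariance,
    factor_scores,
    fit_indices,
    fit_ml,
    model1_spec,
    model2_spec,
    study2_spec,
)

__all__ = [
    "IterationResult",
    "StudySummary",
    "Study2Result",
    "run_iteration",
    "run_study1",
    "run_study2",
    "summarize",
    "read_correlation_matrix",
]

logger = logging.getLogger("potsim")


@dataclass
class IterationResult:
    """Everything produced by one Monte-Carlo replication."""

    iteration: int
    master_seed: int
    scores: "pd.DataFrame"
    fit1: SemFit
    fit2: SemFit
    indices1: FitIndices
    indices2: FitIndices
    decomposition: CommonalityDecomposition

    @property
    def converged(self) -> bool:
        return self.fit1.converged and self.fit2.converged

    def ef_paths_std(self) -> dict[str, float]:
        """Fully standardized EF -> g regression paths from model 2."""
        return {ef: self.fit2.standardized_path("g", ef) for ef in EF_TEST_IDS}

    def ef_structural_r2(self) -> float:
        """Variance share of g explained by the three orthogonal EF predictors.

        With mutually uncorrelated predictors this is the sum of squared
        standardized paths.
        """
        return float(sum(b**2 for b in self.ef_paths_std().values()))

    def fit_stats_rows(self) -> list[dict]:
        rows = []
        for model, fit, fi in (
            ("model1", self.fit1, self.indices1),
            ("model2", self.fit2, self.indices2),
        ):
            rows.append(
                {
                    "iteration": self.iteration,
                    "model": model,
                    "chisq": fit.chisq,
                    "df": fit.df,
                    "pvalue": fit.pvalue,
                    "cfi": fi.cfi,
                    "rmsea": fi.rmsea,
                    "rmsea_lo": fi.rmsea_ci[0],
                    "rmsea_hi": fi.rmsea_ci[1],
                    "srmr": fi.srmr,
                    "converged": fit.converged,
                    "n_warnings": len(fit.warnings),
                }
            )
        return rows

    def loading_rows(self) -> list[dict]:
        """Standardized directed paths (loadings + regressions) per model."""
        rows = []
        for model, fit in (("model1", self.fit1), ("model2", self.fit2)):
            tab = fit.estimates
            for _, r in tab[tab.op == "~"].iterrows():
                rows.append(
                    {
                        "iteration": self.iteration,
                        "model": model,
                        "lhs": r.lhs,
                        "rhs": r.rhs,
                        "std": r["std"],
                    }
                )
        return rows


def run_iteration(
    config: SimulationConfig,
    iteration: int,
    fixed_design: SamplingDesign | None = None,
) -> IterationResult:
    """Run simulation steps 1-4 plus the commonality analysis once."""
    ss = np.random.SeedSequence(config.master_seed, spawn_key=(iteration,))
    s_abil, s_sampling, s_diff, s_resp = ss.spawn(4)

    abilities = generate_abilities(config, np.random.default_rng(s_abil))
    blueprints = default_blueprints(config)
    design = (
        fixed_design
        if fixed_design is not None
        else build_design(blueprints, np.random.default_rng(s_sampling))
    )
    theta = aggregate_theta(design, abilities)
    z = standardize_theta(theta)
    bank = draw_item_difficulties(blueprints, config, np.random.default_rng(s_diff))
    P = response_probabilities(z, bank)
    responses = draw_responses(P, np.random.default_rng(s_resp), design.test_ids)
    scores = aggregate_scores(responses)
    frame = scores.to_frame()
    cov = frame.cov(ddof=1)
    N = scores.n_subjects

    fit1 = fit_ml(model1_spec(), cov, N)
    fit2 = fit_ml(model2_spec(), cov, N)
    g_scores = factor_scores(fit1, frame, latent="g")
    decomposition = commonality(
        g_scores,
        frame["inhibition"],
        frame["updating"],
        frame["shifting"],
        labels=EF_TEST_IDS,
    )
    result = IterationResult(
        iteration=iteration,
        master_seed=config.master_seed,
        scores=frame,
        fit1=fit1,
        fit2=fit2,
        indices1=fit_indices(fit1),
        indices2=fit_indices(fit2),
        decomposition=decomposition,
    )
    logger.info(
        "iteration %d: chisq1=%.2f chisq2=%.2f converged=%s",
        iteration,
        fit1.chisq,
        fit2.chisq,
        result.converged,
    )
    return result


@dataclass
class StudySummary:
    """Across-iteration means and SDs of fits, loadings and EF paths."""

    n_iterations: int
    n_converged: int
    fit_stats: pd.DataFrame          # per model: mean/sd of chi-square & indices
    loadings: pd.DataFrame           # per standardized path: mean/sd
    ef_path_mean: float              # pooled over the 3 EF->g paths
    ef_path_sd: float                # mean across-iteration SD of those paths
    ef_r2_mean: float                # structural R^2 of g on the EF predictors
    decomposition: CommonalityDecomposition
    decomposition_mean: pd.DataFrame | None = None
    warnings_tally: dict[str, int] = field(default_factory=dict)

    @property
    def unreliable(self) -> bool:
        """More than 5% nonconverged iterations."""
        return self.n_converged < 0.95 * self.n_iterations

    def to_dict(self) -> dict:
        flat = self.fit_stats.copy()
        flat.columns = [f"{stat}_{agg}" for stat, agg in flat.columns]
        d = {
            "n_iterations": self.n_iterations,
            "n_converged": self.n_converged,
            "unreliable": self.unreliable,
            "fit_stats": flat.reset_index().to_dict(orient="records"),
            "loadings": self.loadings.to_dict(orient="records"),
            "ef_path_mean": self.ef_path_mean,
            "ef_path_sd": self.ef_path_sd,
            "ef_r2_mean": self.ef_r2_mean,
            "commonality_first_iteration": self.decomposition.to_dict(),
            "warnings_tally": self.warnings_tally,
        }
        if self.decomposition_mean is not None:
            d["commonality_mean"] = self.decomposition_mean.to_dict(orient="records")
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize(
    results: Sequence[IterationResult], avg_commonality: bool = False
) -> StudySummary:
    """Aggregate iteration results (converged ones) into a study summary."""
    if not results:
        raise ValueError("no iteration results to summarize")
    converged = [r for r in results if r.converged]
    if not converged:
        raise RuntimeError("no iteration converged; nothing to aggregate")

    stats_df = pd.DataFrame(
        [row for r in converged for row in r.fit_stats_rows()]
    )
    fit_stats = (
        stats_df.drop(columns=["iteration", "converged"])
        .groupby("model")
        .agg(["mean", "std"])
    )
    load_df = pd.DataFrame([row for r in converged for row in r.loading_rows()])
    loadings = (
        load_df.groupby(["model", "lhs", "rhs"])["std"]
        .agg(["mean", "std"])
        .reset_index()
    )

    paths = pd.DataFrame([r.ef_paths_std() for r in converged])
    ef_path_mean = float(paths.to_numpy().mean())
    ef_path_sd = float(paths.std(ddof=1).mean()) if len(paths) > 1 else 0.0
    ef_r2_mean = float(np.mean([r.ef_structural_r2() for r in converged]))

    tally: dict[str, int] = {}
    for r in results:
        for w in r.fit1.warnings + r.fit2.warnings:
            key = w.split(";")[0]
            tally[key] = tally.get(key, 0) + 1

    decomposition_mean = None
    if avg_commonality:
        decomposition_mean = (
            pd.DataFrame([r.decomposition.to_dict() for r in converged])
            .agg(["mean", "std"])
            .T.reset_index()
            .rename(columns={"index": "component"})
        )
    return StudySummary(
        n_iterations=len(results),
        n_converged=len(converged),
        fit_stats=fit_stats,
        loadings=loadings,
        ef_path_mean=ef_path_mean,
        ef_path_sd=ef_path_sd,
        ef_r2_mean=ef_r2_mean,
        decomposition=results[0].decomposition,
        decomposition_mean=decomposition_mean,
        warnings_tally=tally,
    )


def run_study1(
    config: SimulationConfig,
    n_iterations: int | None = None,
    avg_commonality: bool = False,
    keep_results: bool = False,
) -> StudySummary | tuple[StudySummary, list[IterationResult]]:
    """Run the full Monte-Carlo study and aggregate it.

    ``n_iterations`` overrides the configured count (e.g. for a
    scaled-down run).  With ``keep_results`` the per-iteration results
    are returned alongside the summary.
    """
    n = n_iterations if n_iterations is not None else config.n_iterations
    fixed_design = None
    if not config.redraw_design_per_iteration:
        ss = np.random.SeedSequence(config.master_seed, spawn_key=(0,))
        _, s_sampling, _, _ = ss.spawn(4)
        fixed_design = build_design(
            default_blueprints(config), np.random.default_rng(s_sampling)
        )
    results = [run_iteration(config, i, fixed_design=fixed_design) for i in range(n)]
    summary = summarize(results, avg_commonality=avg_commonality)
    if summary.unreliable:
        logger.warning(
            "summary unreliable: only %d/%d iterations converged",
            summary.n_converged,
            summary.n_iterations,
        )
    return (summary, results) if keep_results else summary


# ---------------------------------------------------------------------
# Correlation-matrix (reanalysis) mode
# ---------------------------------------------------------------------

def read_correlation_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square correlation matrix CSV (header row + name column)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise SemInputError(
            f"correlation matrix in {path} is not square with matching names"
        )
    arr = df.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise SemInputError("correlation matrix is not symmetric")
    eig = np.linalg.eigvalsh(arr)
    if eig[0] <= 0:
        raise SemInputError(
            f"correlation matrix not positive definite (min eigenvalue {eig[0]:.4g})"
        )
    return df


@dataclass
class Study2Result:
    """Structural fit plus latent-level commonality for one dataset."""

    fit: SemFit
    indices: FitIndices
    decomposition: CommonalityDecomposition
    free_correlation_fit: SemFit

    def to_dict(self) -> dict:
        return {
            "fit": self.fit.to_dict(),
            "commonality": self.decomposition.to_dict(),
        }


def _latent_correlations(fit: SemFit, names: Sequence[str]) -> np.ndarray:
    """Model-implied correlations among a set of variables (any kind)."""
    V = _joint_covariance(fit.spec, fit.theta)
    idx = [fit.spec.index(n) for n in names]
    sub = V[np.ix_(idx, idx)]
    d = np.sqrt(np.diag(sub))
    return sub / np.outer(d, d)


def run_study2(
    matrix, N: int, structure: Mapping | str | Path
) -> Study2Result:
    """Fit the three-EF-factor -> g model to a correlation matrix.

    ``matrix`` is a DataFrame or CSV path; ``structure`` maps factors to
    indicators (dict or YAML path).  The structural fit uses orthogonal
    EF factors (matching the simulation); the commonality decomposition
    is computed at the latent level from a companion fit with free EF
    factor correlations, via subset R-squared on the implied latent
    correlations.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = read_correlation_matrix(matrix)
    if isinstance(structure, (str, Path)):
        with open(structure) as fh:
            structure = yaml.safe_load(fh)
    structure = dict(structure)

    spec = study2_spec(structure)
    fit = fit_ml(spec, matrix, N)

    free_structure = {**structure, "ef_covariances": "free"}
    free_fit = fit_ml(study2_spec(free_structure), matrix, N)
    factor_names = list(structure["factors"])
    criterion = "g" if "indicators" in structure.get("g", {}) else structure["g"]["composite"]
    R = _latent_correlations(free_fit, factor_names + [criterion])
    decomposition = commonality_from_correlations(
        R[:3, :3], R[:3, 3], labels=tuple(factor_names)
    )
    return Study2Result(
        fit=fit,
        indices=fit_indices(fit),
        decomposition=decomposition,
        free_correlation_fit=free_fit,
    )
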