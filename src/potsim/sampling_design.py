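"""Item-level process sampling and aggregate ability parameters.

Each test item draws a binary "sampling vector" over two process pools:
a domain-general pool (executive attention) and a domain-specific pool.
The person's aggregate ability on the item within a pool is the plain
sum of the sampled process abilities, so an item tapping k processes has
cross-person theta variance k under orthogonal standard-normal
abilities.  Sampling vectors are item properties shared by all persons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .process_space import (
    AbilityMatrix,
    ConfigurationError,
    SimulationConfig,
)

__all__ = [
    "TestBlueprint",
    "SamplingDesign",
    "ThetaArray",
    "default_blueprints",
    "draw_sampling_vector",
    "build_design",
    "aggregate_theta",
]

TEST_CLASSES = (
    "fluid",
    "verbal",
    "spatial",
    "ef-inhibition",
    "ef-updating",
    "ef-shifting",
)


@dataclass(frozen=True)
class TestBlueprint:
    """Sampling recipe for one test.

    ``general_pool`` / ``specific_pool`` are global column indices into
    the ability matrix.  Broad-ability tests use the full executive
    attention block as their general pool; EF tests use only the
    "common" EA sub-pool as general and their own EA sub-pool as
    specific, so an EF item samples on average
    ``10 * 0.28 = 2.8`` specific and ``10 * 0.12 = 1.2`` common
    processes under the defaults.
    """

    test_id: str
    test_class: str
    n_items: int
    general_pool: np.ndarray
    specific_pool: np.ndarray
    p_general: float
    p_specific: float

    def __post_init__(self) -> None:
        if self.test_class not in TEST_CLASSES:
            raise ConfigurationError(
                f"unknown test class {self.test_class!r}; expected one of {TEST_CLASSES}"
            )
        if self.n_items < 1:
            raise ConfigurationError("n_items must be >= 1")
        for name in ("p_general", "p_specific"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0,1]")
        if np.intersect1d(self.general_pool, self.specific_pool).size:
            raise ConfigurationError(
                f"general and specific pools overlap for test {self.test_id!r}"
            )

    @property
    def is_ef(self) -> bool:
        return self.test_class.startswith("ef-")


def default_blueprints(config: SimulationConfig) -> list[TestBlueprint]:
    """The standard 12-test battery: 3 fluid, 3 verbal, 3 spatial, 3 EF.

    Broad tests pair their own 50-process domain block with the full
    50-process EA block; each EF test pairs its 10-process EA sub-pool
    with the 10 common EA processes (the same EA processes also sampled,
    at the full-block level, by every broad test).
    """
    tax = config.taxonomy
    ea_full = tax.domain_indices("ea")
    ea_common = tax.ea_subblock_indices("common")
    blueprints: list[TestBlueprint] = []
    for domain in ("fluid", "verbal", "spatial"):
        pg, ps = config.sampling_probs[domain]
        for k in range(1, 4):
            blueprints.append(
                TestBlueprint(
                    test_id=f"{domain}{k}",
                    test_class=domain,
                    n_items=config.n_items_per_test,
                    general_pool=ea_full,
                    specific_pool=tax.domain_indices(domain),
                    p_general=pg,
                    p_specific=ps,
                )
            )
    pg, ps = config.sampling_probs["ef"]
    for sub in ("inhibition", "updating", "shifting"):
        blueprints.append(
            TestBlueprint(
                test_id=sub,
                test_class=f"ef-{sub}",
                n_items=config.n_items_per_test,
                general_pool=ea_common,
                specific_pool=tax.ea_subblock_indices(sub),
                p_general=pg,
                p_specific=ps,
            )
        )
    return blueprints


def draw_sampling_vector(
    pool_size: int, p: float, rng: np.random.Generator
) -> np.ndarray:
    """One binary Bernoulli(p) sampling vector over a process pool.

    All-zero vectors are legitimate draws (an item that happens to tap
    no process from a pool); they propagate a constant zero theta that
    the standardization step maps to z = 0.
    """
    if pool_size < 1:
        raise ConfigurationError("pool_size must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"sampling probability {p} outside [0,1]")
    return (rng.random(pool_size) < p).astype(np.int8)


@dataclass(frozen=True)
class SamplingDesign:
    """Per-(test, item) sampling vectors for a whole battery.

    ``general[t]`` is the (n_items x |general pool|) binary matrix of
    b-vectors for test t; ``specific[t]`` the matching c-vectors.
    """

    blueprints: list[TestBlueprint]
    general: list[np.ndarray] = field(repr=False)
    specific: list[np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if not (len(self.blueprints) == len(self.general) == len(self.specific)):
            raise ConfigurationError("design lists must align with blueprints")
        for bp, B, C in zip(self.blueprints, self.general, self.specific):
            if B.shape != (bp.n_items, bp.general_pool.size):
                raise ConfigurationError(
                    f"general vectors for {bp.test_id!r} have shape {B.shape}"
                )
            if C.shape != (bp.n_items, bp.specific_pool.size):
                raise ConfigurationError(
                    f"specific vectors for {bp.test_id!r} have shape {C.shape}"
                )

    @property
    def n_tests(self) -> int:
        return len(self.blueprints)

    @property
    def test_ids(self) -> list[str]:
        return [bp.test_id for bp in self.blueprints]

    def to_sparse_frame(self) -> pd.DataFrame:
        """Long-format audit table: one row per sampled process."""
        rows = []
        for bp, B, C in zip(self.blueprints, self.general, self.specific):
            for pool_name, mat, pool in (
                ("general", B, bp.general_pool),
                ("specific", C, bp.specific_pool),
            ):
                items, cols = np.nonzero(mat)
                for i, c in zip(items, cols):
                    rows.append((bp.test_id, int(i), pool_name, int(pool[c])))
        return pd.DataFrame(rows, columns=["test", "item", "pool", "process"])


def build_design(
    blueprints: list[TestBlueprint], rng: np.random.Generator
) -> SamplingDesign:
    """Draw the full set of per-item sampling vectors for a battery."""
    general, specific = [], []
    for bp in blueprints:
        B = np.vstack(
            [draw_sampling_vector(bp.general_pool.size, bp.p_general, rng)
             for _ in range(bp.n_items)]
        )
        C = np.vstack(
            [draw_sampling_vector(bp.specific_pool.size, bp.p_specific, rng)
             for _ in range(bp.n_items)]
        )
        general.append(B)
        specific.append(C)
    return SamplingDesign(blueprints=blueprints, general=general, specific=specific)


@dataclass(frozen=True)
class ThetaArray:
    """Aggregate ability parameters, persons x tests x items."""

    theta_g: np.ndarray
    theta_s: np.ndarray
    test_ids: list[str]

    def __post_init__(self) -> None:
        if self.theta_g.shape != self.theta_s.shape:
            raise ConfigurationError("theta_g and theta_s shapes differ")
        if self.theta_g.ndim != 3 or self.theta_g.shape[1] != len(self.test_ids):
            raise ConfigurationError(
                f"theta array shape {self.theta_g.shape} inconsistent with "
                f"{len(self.test_ids)} tests"
            )
        if not (np.all(np.isfinite(self.theta_g)) and np.all(np.isfinite(self.theta_s))):
            raise ConfigurationError("theta arrays contain non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.theta_g.shape


def aggregate_theta(design: SamplingDesign, abilities: AbilityMatrix) -> ThetaArray:
    """Sum sampled process abilities into per-item thetas.

    For person p, test t, item i:
    theta_g = sum_n b[t,i,n] * ability[p, general_pool[n]] and
    theta_s likewise over the specific pool — a matrix product of the
    pool-restricted ability block with the transposed sampling matrix.
    """
    n_subjects = abilities.n_subjects
    n_tests = design.n_tests
    n_items = design.blueprints[0].n_items
    for bp in design.blueprints:
        if bp.n_items != n_items:
            raise ConfigurationError("tests with unequal item counts not supported")
        hi = max(bp.general_pool.max(), bp.specific_pool.max())
        if hi >= abilities.values.shape[1]:
            raise ConfigurationError(
                f"pool index {hi} out of range for ability matrix with "
                f"{abilities.values.shape[1]} processes"
            )
    theta_g = np.empty((n_subjects, n_tests, n_items))
    theta_s = np.empty((n_subjects, n_tests, n_items))
    for t, (bp, B, C) in enumerate(
        zip(design.blueprints, design.general, design.specific)
    ):
        theta_g[:, t, :] = abilities.columns(bp.general_pool) @ B.T.astype(float)
        theta_s[:, t, :] = abilities.columns(bp.specific_pool) @ C.T.astype(float)
    return ThetaArray(theta_g=theta_g, theta_s=theta_s, test_ids=design.test_ids)
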