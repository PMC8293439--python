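"""Process taxonomy and orthogonal person x process ability generation.

The simulator posits a fixed pool of elementary cognitive processes,
partitioned into domains (fluid, verbal, spatial, executive attention),
with the executive-attention (EA) block further split into sub-pools
(inhibition, updating, shifting, unspecified, common).  Every simulated
person has an independent standard-normal ability on every process, so
the process abilities are orthogonal by construction: any general factor
that later emerges from test scores is produced purely by overlapping
sampling, not by a latent general ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ProcessTaxonomy",
    "SimulationConfig",
    "AbilityMatrix",
    "generate_abilities",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


#: EA sub-pool names in declaration order (fixed so that column indices
#: of the ability matrix are deterministic).
EA_SUBBLOCKS = ("inhibition", "updating", "shifting", "unspecified", "common")

#: Domain blocks in declaration order.
DOMAINS = ("fluid", "verbal", "spatial", "ea")


@dataclass(frozen=True)
class ProcessTaxonomy:
    """Partition of the process pool into domains and EA sub-pools.

    Defaults give 200 processes: 50 fluid, 50 verbal, 50 spatial and 50
    executive attention, the latter split 10/10/10/10/10 into
    inhibition, updating, shifting, unspecified and common processes.
    """

    domain_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"fluid": 50, "verbal": 50, "spatial": 50, "ea": 50}
    )
    ea_subblock_sizes: Mapping[str, int] = field(
        default_factory=lambda: {name: 10 for name in EA_SUBBLOCKS}
    )

    def __post_init__(self) -> None:
        if set(self.domain_sizes) != set(DOMAINS):
            raise ConfigurationError(
                f"taxonomy domains must be exactly {DOMAINS}, got {tuple(self.domain_sizes)}"
            )
        if set(self.ea_subblock_sizes) != set(EA_SUBBLOCKS):
            raise ConfigurationError(
                f"EA sub-blocks must be exactly {EA_SUBBLOCKS}, got {tuple(self.ea_subblock_sizes)}"
            )
        for name, size in {**self.domain_sizes, **self.ea_subblock_sizes}.items():
            if int(size) != size or size < 1:
                raise ConfigurationError(f"block {name!r} has non-positive size {size}")
        if sum(self.ea_subblock_sizes.values()) != self.domain_sizes["ea"]:
            raise ConfigurationError(
                "EA sub-block sizes must sum to the EA domain size "
                f"({sum(self.ea_subblock_sizes.values())} != {self.domain_sizes['ea']})"
            )

    @property
    def n_processes(self) -> int:
        return int(sum(self.domain_sizes.values()))

    def domain_indices(self, domain: str) -> np.ndarray:
        """Column indices of a domain block in declaration order."""
        if domain not in self.domain_sizes:
            raise ConfigurationError(f"unknown domain {domain!r}")
        start = 0
        for name in DOMAINS:
            if name == domain:
                return np.arange(start, start + self.domain_sizes[name])
            start += self.domain_sizes[name]
        raise AssertionError("unreachable")

    def ea_subblock_indices(self, subblock: str) -> np.ndarray:
        """Column indices of one EA sub-pool (global column space)."""
        if subblock not in self.ea_subblock_sizes:
            raise ConfigurationError(f"unknown EA sub-block {subblock!r}")
        start = int(self.domain_indices("ea")[0])
        for name in EA_SUBBLOCKS:
            if name == subblock:
                return np.arange(start, start + self.ea_subblock_sizes[name])
            start += self.ea_subblock_sizes[name]
        raise AssertionError("unreachable")

    def column_labels(self) -> list[str]:
        """One label per process column, e.g. ``ea_updating_003``."""
        labels: list[str] = []
        for domain in DOMAINS:
            if domain == "ea":
                for sub in EA_SUBBLOCKS:
                    labels += [
                        f"ea_{sub}_{k:03d}" for k in range(self.ea_subblock_sizes[sub])
                    ]
            else:
                labels += [f"{domain}_{k:03d}" for k in range(self.domain_sizes[domain])]
        return labels


#: Sampling probabilities (p_general, p_specific) per test class.  Fluid
#: tests draw executive-attention processes more densely than their own
#: specific processes; verbal/spatial tests do the reverse; executive
#: function (EF) tests draw from their own small EA sub-pool plus the
#: common EA pool.
DEFAULT_SAMPLING_PROBS: dict[str, tuple[float, float]] = {
    "fluid": (0.28, 0.12),
    "verbal": (0.12, 0.28),
    "spatial": (0.12, 0.28),
    "ef": (0.12, 0.28),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration for one Monte-Carlo study.

    Parameters
    ----------
    n_subjects:
        Number of simulated persons (default 1000).
    taxonomy:
        Process taxonomy; defaults to the 200-process partition.
    n_items_per_test:
        Items per test (default 100); test scores range 0..this value.
    sampling_probs:
        Mapping test class -> ``(p_general, p_specific)`` Bernoulli
        sampling probabilities.
    difficulty_sd_broad, difficulty_sd_ef:
        SD of the normal item-difficulty distributions for broad-ability
        and EF tests.  The small EF value (0.05) encodes the relative
        stability of performance on executive tasks.
    discrimination:
        Common logistic slope of the item response function.
    n_iterations:
        Monte-Carlo replications of the whole pipeline.
    master_seed:
        Root of the deterministic seed tree.
    redraw_design_per_iteration:
        Whether item sampling vectors are drawn fresh in every
        Monte-Carlo iteration (default) or held fixed across iterations.
    """

    n_subjects: int = 1000
    taxonomy: ProcessTaxonomy = field(default_factory=ProcessTaxonomy)
    n_items_per_test: int = 100
    sampling_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_PROBS)
    )
    difficulty_sd_broad: float = 1.0
    difficulty_sd_ef: float = 0.05
    discrimination: float = 1.0
    n_iterations: int = 200
    master_seed: int = 0
    redraw_design_per_iteration: bool = True

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_items_per_test", "n_iterations"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v}")
        for cls, pair in self.sampling_probs.items():
            pg, ps = pair
            if not (0.0 <= pg <= 1.0 and 0.0 <= ps <= 1.0):
                raise ConfigurationError(
                    f"sampling probabilities for {cls!r} must lie in [0,1], got {pair}"
                )
        for name in ("difficulty_sd_broad", "difficulty_sd_ef", "discrimination"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["taxonomy"] = {
            "domain_sizes": dict(self.taxonomy.domain_sizes),
            "ea_subblock_sizes": dict(self.taxonomy.ea_subblock_sizes),
        }
        d["sampling_probs"] = {k: list(v) for k, v in self.sampling_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "taxonomy" in d and not isinstance(d["taxonomy"], ProcessTaxonomy):
            d["taxonomy"] = ProcessTaxonomy(**d["taxonomy"])
        if "sampling_probs" in d:
            d["sampling_probs"] = {
                k: tuple(v) for k, v in dict(d["sampling_probs"]).items()
            }
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a configuration from a YAML (or JSON) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})


@dataclass(frozen=True)
class AbilityMatrix:
    """Persons x processes matrix of orthogonal process abilities."""

    values: np.ndarray
    taxonomy: ProcessTaxonomy

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != self.taxonomy.n_processes:
            raise ConfigurationError(
                f"ability matrix shape {self.values.shape} does not match "
                f"taxonomy with {self.taxonomy.n_processes} processes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("ability matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def columns(self, indices: Sequence[int]) -> np.ndarray:
        return self.values[:, np.asarray(indices)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.taxonomy.column_labels())

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="subject")


def generate_abilities(
    config: SimulationConfig, rng: np.random.Generator | int
) -> AbilityMatrix:
    """Draw the persons x processes ability matrix.

    A standardized multivariate normal with identity covariance is
    equivalent to i.i.d. univariate standard-normal draws per cell, so
    the matrix is filled directly from ``rng.standard_normal``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = rng.standard_normal((config.n_subjects, config.taxonomy.n_processes))
    return AbilityMatrix(values=values, taxonomy=config.taxonomy)
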