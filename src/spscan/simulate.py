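"""Synthetic-data generators for the canonical Simpson's-paradox layouts,
plus the random-table prevalence study.

``gen_archetype`` produces bivariate samples matching the qualitative
structures in which aggregation reverses or masks within-unit trends:

- ``two_cluster``: two clusters whose centroids rise along one direction
  while the within-cluster slope runs the other way (drug dosage vs.
  recovery split by sex; coffee vs. neuroticism in two halves).
- ``k_cluster``: the same layout with K clusters (default three).
- ``within_person``: many subjects, each with a negative within-subject
  slope, whose subject means rise (typing speed vs. error rate across
  vs. within people).
- ``orthogonal``: equal-mean clusters with opposite slopes — subgroup
  structure with no group-level association and homoscedastic residuals.
- ``homogeneous``: one cluster, the null control.

All axes are in arbitrary units: within-unit x is Gaussian with SD 1.2,
noise_sd defaults to 1, and centroid spacing is expressed in noise-SD
units.

``sp_prevalence`` reproduces the random-table experiment: draw 2x2x2
probability tables uniformly from the 8-cell simplex (symmetric
Dirichlet(1)) and count how often both strata's association signs
strictly oppose a strictly nonzero amalgamated sign. The exact
answer for the uniform case is 1/60 ~ 1.67%.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .contingency import StratifiedTable, StratumTable
from .errors import ConfigError
from .regress import BivariateSample

__all__ = [
    "GeneratorSpec",
    "RandomTableSpec",
    "PrevalenceResult",
    "gen_archetype",
    "sample_dirichlet_222",
    "sp_prevalence",
]

ARCHETYPES = ("two_cluster", "k_cluster", "within_person", "orthogonal", "homogeneous")

#: default number of units per archetype
_DEFAULT_UNITS = {
    "two_cluster": 2,
    "k_cluster": 3,
    "within_person": 10,
    "orthogonal": 2,
    "homogeneous": 1,
}
#: within-unit Gaussian x spread (arbitrary units); Gaussian so that each
#: unit is an elliptical cluster, the shape mixture clustering models
_X_SD = 1.2


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic archetype.

    ``separation`` is the distance between consecutive unit centroids in
    noise-SD units, along a diagonal whose slope sign is
    ``group_slope_sign``; ``within_slope`` is the slope of the
    relationship inside each unit. ``n_per_unit`` defaults to 100 except
    for the within-person design (20 observations per subject).
    """

    archetype: str
    n_per_unit: int | None = None
    units: int | None = None
    group_slope_sign: int = 1
    within_slope: float = -1.0
    separation: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ConfigError(
                f"unknown archetype {self.archetype!r}; choose from {ARCHETYPES}"
            )
        if self.units is None:
            object.__setattr__(self, "units", _DEFAULT_UNITS[self.archetype])
        if self.n_per_unit is None:
            n = 20 if self.archetype == "within_person" else 100
            object.__setattr__(self, "n_per_unit", n)
        if self.n_per_unit < 3 or self.units < 1:
            raise ConfigError("need n_per_unit >= 3 and units >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.separation < 0:
            raise ConfigError("separation must be >= 0")
        if self.group_slope_sign not in (-1, 1):
            raise ConfigError("group_slope_sign must be -1 or +1")


@dataclass(frozen=True)
class RandomTableSpec:
    """Parameters of the random 2x2x2 table sampler."""

    n_tables: int = 1_000_000
    dirichlet_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tables < 1:
            raise ConfigError("n_tables must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be > 0")


@dataclass(frozen=True)
class PrevalenceResult:
    """Monte-Carlo estimate of the full-reversal fraction."""

    prevalence: float
    se: float
    n_tables: int
    n_reversals: int
    concentration: float
    seed: int


def _centroids(spec: GeneratorSpec) -> np.ndarray:
    """Unit centroids along the group-trend diagonal, centered at origin."""
    K = spec.units
    if spec.archetype in ("orthogonal", "homogeneous"):
        return np.zeros((K, 2))
    step = spec.separation * spec.noise_sd
    t = (np.arange(K) - (K - 1) / 2.0) * step
    direction = np.array([1.0, float(spec.group_slope_sign)]) / np.sqrt(2.0)
    return t[:, None] * direction[None, :]


def gen_archetype(spec: GeneratorSpec) -> BivariateSample:
    """Generate one bivariate sample from an archetype specification.

    Within each unit, x ~ N(centroid_x, 1.2) and
    y = centroid_y + within_slope * (x - centroid_x) + N(0, noise_sd),
    so every unit is an elliptical Gaussian cluster.
    The ``orthogonal`` archetype alternates the within-slope sign across
    its equal-mean units. Cluster archetypes attach group labels
    ("c1", "c2", ...); the within-person archetype attaches subject ids
    ("s01", ...). Deterministic at fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    centroids = _centroids(spec)
    xs, ys, unit_ids = [], [], []
    for u in range(spec.units):
        slope = spec.within_slope
        if spec.archetype == "orthogonal":
            slope = abs(spec.within_slope) * (1 if u % 2 == 0 else -1)
        dx = rng.normal(0.0, _X_SD, spec.n_per_unit)
        noise = rng.normal(0.0, spec.noise_sd, spec.n_per_unit)
        xs.append(centroids[u, 0] + dx)
        ys.append(centroids[u, 1] + slope * dx + noise)
        unit_ids.append(np.full(spec.n_per_unit, u))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    units = np.concatenate(unit_ids)
    if spec.archetype == "within_person":
        width = len(str(spec.units))
        subject = np.array([f"s{u + 1:0{width}d}" for u in units])
        return BivariateSample(x=x, y=y, subject=subject)
    group = np.array([f"c{u + 1}" for u in units])
    return BivariateSample(x=x, y=y, group=group)


def _draw_cells(spec: RandomTableSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    alpha = np.full(8, spec.dirichlet_concentration)
    return rng.dirichlet(alpha, size=size)


def sample_dirichlet_222(spec: RandomTableSpec) -> Iterator[StratifiedTable]:
    """Stream random 2x2x2 probability tables, one StratifiedTable per draw.

    Each draw places 8 Dirichlet cell probabilities into two strata;
    concentration 1 is the uniform distribution on the simplex.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_tables):
        c = _draw_cells(spec, rng, 1)[0]
        yield StratifiedTable(
            (
                StratumTable("stratum1", c[0], c[1], c[2], c[3]),
                StratumTable("stratum2", c[4], c[5], c[6], c[7]),
            )
        )


def _reversal_mask(cells: np.ndarray) -> np.ndarray:
    """Vectorized full-reversal classifier on (n, 8) cell arrays.

    Association signs via the 2x2 determinant n11*n22 - n12*n21; a full
    reversal requires both strata's signs strictly opposite to a strictly
    nonzero amalgamated sign (ties count as no reversal).
    """
    a, b = cells[:, :4], cells[:, 4:]
    agg = a + b

    def det(t: np.ndarray) -> np.ndarray:
        return np.sign(t[:, 0] * t[:, 3] - t[:, 1] * t[:, 2])

    sa, sb, sg = det(a), det(b), det(agg)
    return (sg != 0) & (sa == -sg) & (sb == -sg)


def sp_prevalence(spec: RandomTableSpec, chunk: int = 200_000) -> PrevalenceResult:
    """Monte-Carlo estimate of the full-reversal prevalence among random
    2x2x2 probability tables, with its binomial standard error.

    Processes draws in chunks so memory stays flat at any n_tables.
    """
    if spec.n_tables < 10_000:
        _warnings.warn(
            f"n_tables={spec.n_tables} < 10000: prevalence estimate will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    hits = 0
    left = spec.n_tables
    while left > 0:
        m = min(chunk, left)
        hits += int(_reversal_mask(_draw_cells(spec, rng, m)).sum())
        left -= m
    p = hits / spec.n_tables
    se = float(np.sqrt(p * (1.0 - p) / spec.n_tables))
    return PrevalenceResult(
        prevalence=p,
        se=se,
        n_tables=spec.n_tables,
        n_reversals=hits,
        concentration=spec.dirichlet_concentration,
        seed=spec.seed,
    )
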