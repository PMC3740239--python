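"""Three-stage Simpson's-paradox detection for bivariate continuous data.

Stage 1 finds subgroups: latent (Gaussian-mixture BIC clustering on the
(x, y) plane), manifest (a supplied grouping or subject column), or
feature-based (mixture clustering on external covariates). Stage 2 fits
an OLS regression in every subgroup and in the pooled sample. Stage 3
asks, for each subgroup, whether its slope deviates from the pooled
slope more than a same-sized random subset of the data would — a
size-matched permutation null that respects the dependency between a
cluster and the full dataset it is part of, and corrects for unequal
cluster sizes by matching each null draw to the cluster's n.

A cluster whose slope deviates significantly triggers a warning; if its
slope sign additionally opposes the pooled sign, the warning escalates
to a sign-reversal (Simpson's paradox) alert. Warning strings are fixed
templates rendered byte-for-byte in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterAssignment, MixtureModel, assign, select_k
from .errors import ConfigError, DataError
from .regress import BivariateSample, RegressionFit, fit_ols

__all__ = [
    "PermutationNull",
    "ClusterFinding",
    "SkippedCluster",
    "SPReport",
    "permutation_null",
    "compare_cluster",
    "detect_sp",
    "WARN_DEVIATION",
    "WARN_REVERSAL",
]

WARN_DEVIATION = (
    "Warning: Beta regression estimate in cluster {X} is significantly "
    "different compared to the group!"
)
WARN_REVERSAL = (
    "Sign reversal: Simpson's Paradox! Cluster {X} is significantly "
    "different and in the opposite direction compared to the group!"
)

#: fixed caveat strings attached to every report
CAVEATS = (
    "Clustering cannot decide whether a third variable is a confounder or a "
    "mediator; whether conditioning on the discovered subgroups is "
    "appropriate requires causal background knowledge.",
    "The number of mixture components selected by BIC tends to grow with "
    "sample size and under distributional misspecification; inspect the "
    "clusters before interpreting them as subpopulations.",
)


@dataclass(frozen=True)
class PermutationNull:
    """Null distribution of slopes from size-matched random subsets."""

    slopes: np.ndarray
    subset_size: int
    n_redraws: int


@dataclass(frozen=True)
class ClusterFinding:
    cluster_id: int  # 1-based, ordered by descending cluster size
    n: int
    fit: RegressionFit
    p_perm: float
    significant: bool
    sign_reversed: bool


@dataclass(frozen=True)
class SkippedCluster:
    cluster_id: int
    n: int
    reason: str


@dataclass(frozen=True)
class SPReport:
    """Full outcome of one detection run, sufficient to reproduce it."""

    group_fit: RegressionFit
    mode: str  # latent | manifest | features
    model: MixtureModel | None
    findings: tuple[ClusterFinding, ...]
    skipped: tuple[SkippedCluster, ...]
    warnings: tuple[str, ...]
    caveats: tuple[str, ...]
    alpha: float
    B: int
    k_max: int
    min_cluster_size: int
    seed: int
    cluster_labels: np.ndarray = field(repr=False)


def _subset_slopes(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """OLS slope for each row of subset indices (vectorized cov/var form)."""
    xs = x[idx]
    ys = y[idx]
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    dx = xs - xm
    return np.sum(dx * (ys - ym), axis=1) / np.sum(dx * dx, axis=1)


def permutation_null(
    sample: BivariateSample, subset_size: int, B: int, seed: int
) -> PermutationNull:
    """Slopes of B uniform random subsets of exactly ``subset_size`` points.

    Subsets are drawn without replacement from the full sample; a draw
    whose x values are constant (slope undefined) is redrawn and the
    redraw count reported. Slopes are computed in the closed cov/var
    form, identical to :func:`spscan.regress.fit_ols` on each subset.
    """
    n = sample.n
    # two points with distinct x already define a slope
    if not (2 <= subset_size <= n):
        raise DataError(f"subset_size must be in [2, {n}], got {subset_size}")
    if B < 1:
        raise DataError("B must be >= 1")
    rng = np.random.default_rng(seed)
    # rank of iid uniforms gives a uniform random subset per row
    keys = rng.random((B, n))
    idx = np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]
    n_redraws = 0
    constant = np.ptp(sample.x[idx], axis=1) == 0
    while constant.any():
        m = int(constant.sum())
        n_redraws += m
        keys = rng.random((m, n))
        idx[constant] = np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]
        constant = np.ptp(sample.x[idx], axis=1) == 0
    slopes = _subset_slopes(sample.x, sample.y, idx)
    return PermutationNull(slopes=slopes, subset_size=subset_size, n_redraws=n_redraws)


def compare_cluster(
    group_fit: RegressionFit,
    cluster_fit: RegressionFit,
    null: PermutationNull | np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, bool, bool]:
    """Two-sided permutation comparison of a cluster slope to the group slope.

    p = (1 + #{null slopes at least as far from the group slope as the
    cluster's}) / (B + 1); the add-one keeps p >= 1/(B+1). The null must
    have been generated at the cluster's own size.
    """
    slopes = null.slopes if isinstance(null, PermutationNull) else np.asarray(null)
    if slopes.size == 0:
        raise DataError("empty permutation null")
    dev = abs(cluster_fit.slope - group_fit.slope)
    count = int(np.sum(np.abs(slopes - group_fit.slope) >= dev))
    p_perm = (1 + count) / (slopes.size + 1)
    significant = p_perm <= alpha
    gs = np.sign(group_fit.slope)
    cs = np.sign(cluster_fit.slope)
    sign_reversed = bool(significant and gs != 0 and cs == -gs)
    return p_perm, significant, sign_reversed


def _labels_for_mode(
    sample: BivariateSample, mode: str, k_max: int, seed: int
) -> tuple[np.ndarray, MixtureModel | None]:
    if mode == "latent":
        model = select_k(sample.xy, k_max=k_max, seed=seed)
        return assign(model, sample.xy).labels, model
    if mode == "manifest":
        col = sample.group if sample.group is not None else sample.subject
        if col is None:
            raise ConfigError("manifest mode requires a group or subject column")
        return np.asarray(col), None
    if mode == "features":
        if sample.features is None:
            raise ConfigError("features mode requires a feature block")
        model = select_k(sample.features, k_max=k_max, seed=seed)
        return assign(model, sample.features).labels, model
    raise ConfigError(f"unknown mode {mode!r}")


def detect_sp(
    sample: BivariateSample,
    mode: str = "latent",
    alpha: float = 0.05,
    B: int = 1000,
    k_max: int = 5,
    seed: int = 0,
    min_cluster_size: int = 10,
) -> SPReport:
    """Run the full cluster / regress / permutation-compare pipeline.

    Clusters are numbered 1..K by descending size (ties by first
    appearance); each cluster with at least ``min_cluster_size``
    observations is tested, smaller ones are listed as skipped. All
    randomness (clustering restarts, permutation draws) derives from
    ``seed``, so reports are bit-identical across runs.
    """
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0,1), got {alpha}")
    ss = np.random.SeedSequence(seed)
    cluster_seed, perm_root = (int(s) for s in ss.generate_state(2) % (2**31))

    group_fit = fit_ols(sample)
    labels, model = _labels_for_mode(sample, mode, k_max, cluster_seed)

    uniq, first_pos = np.unique(labels, return_index=True)
    sizes = np.array([np.sum(labels == u) for u in uniq])
    order = np.lexsort((first_pos, -sizes))  # descending size, stable
    perm_seeds = np.random.SeedSequence(perm_root).generate_state(len(uniq)) % (2**31)

    findings: list[ClusterFinding] = []
    skipped: list[SkippedCluster] = []
    warnings: list[str] = []
    for rank, j in enumerate(order, start=1):
        members = labels == uniq[j]
        n_c = int(sizes[j])
        if n_c < min_cluster_size:
            skipped.append(
                SkippedCluster(rank, n_c, f"cluster smaller than {min_cluster_size}")
            )
            continue
        try:
            cfit = fit_ols(sample.take(members))
        except DataError as exc:
            skipped.append(SkippedCluster(rank, n_c, str(exc)))
            continue
        null = permutation_null(sample, n_c, B, int(perm_seeds[rank - 1]))
        p_perm, significant, sign_reversed = compare_cluster(
            group_fit, cfit, null, alpha
        )
        findings.append(ClusterFinding(rank, n_c, cfit, p_perm, significant, sign_reversed))
        if sign_reversed:
            warnings.append(WARN_REVERSAL.format(X=rank))
        elif significant:
            warnings.append(WARN_DEVIATION.format(X=rank))

    return SPReport(
        group_fit=group_fit,
        mode=mode,
        model=model,
        findings=tuple(findings),
        skipped=tuple(skipped),
        warnings=tuple(warnings),
        caveats=CAVEATS,
        alpha=alpha,
        B=B,
        k_max=k_max,
        min_cluster_size=min_cluster_size,
        seed=seed,
        cluster_labels=labels,
    )
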