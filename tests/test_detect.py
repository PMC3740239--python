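"""Permutation nulls, slope comparison, and the full detection pipeline."""

import itertools

import numpy as np
import pytest

from spscan.detect import (
    WARN_DEVIATION,
    WARN_REVERSAL,
    compare_cluster,
    detect_sp,
    permutation_null,
)
from spscan.errors import ConfigError, DataError
from spscan.regress import BivariateSample, fit_ols
from spscan.simulate import GeneratorSpec, gen_archetype


@pytest.fixture
def noisy_line(rng):
    x = rng.uniform(0, 10, 100)
    y = 0.7 * x + rng.normal(0, 1, 100)
    return BivariateSample(x=x, y=y)


class TestPermutationNull:
    def test_full_sample_subset_reproduces_group_slope(self, noisy_line):
        group = fit_ols(noisy_line)
        null = permutation_null(noisy_line, subset_size=noisy_line.n, B=20, seed=0)
        assert null.slopes == pytest.approx(np.full(20, group.slope), rel=1e-12)

    def test_pairs_enumeration_on_four_points(self, four_points):
        # brute-force oracle: slopes of all C(4,2) index pairs
        pts = list(zip(four_points.x, four_points.y))
        expected = sorted(
            (y2 - y1) / (x2 - x1)
            for (x1, y1), (x2, y2) in itertools.combinations(pts, 2)
        )
        assert expected == pytest.approx([-1.0, 0.5, 0.5, 1.0, 2.0, 2.0])
        null = permutation_null(four_points, subset_size=2, B=6000, seed=1)
        # Monte-Carlo frequencies converge to uniform over the 6 pairs
        values, counts = np.unique(np.round(null.slopes, 9), axis=0, return_counts=True)
        assert sorted(values) == pytest.approx([-1.0, 0.5, 1.0, 2.0])
        freq = dict(zip(values.tolist(), (counts / 6000).tolist()))
        assert freq[-1.0] == pytest.approx(1 / 6, abs=0.03)
        assert freq[0.5] == pytest.approx(2 / 6, abs=0.03)
        assert freq[1.0] == pytest.approx(1 / 6, abs=0.03)
        assert freq[2.0] == pytest.approx(2 / 6, abs=0.03)

    def test_slopes_match_fit_ols_per_subset(self, noisy_line):
        null = permutation_null(noisy_line, subset_size=10, B=5, seed=3)
        redo = permutation_null(noisy_line, subset_size=10, B=5, seed=3)
        assert np.array_equal(null.slopes, redo.slopes)  # deterministic
        # same machinery via fit_ols on explicitly drawn subsets
        rng = np.random.default_rng(99)
        for _ in range(5):
            idx = rng.choice(noisy_line.n, 10, replace=False)
            sub = noisy_line.take(idx)
            direct = fit_ols(sub).slope
            one = permutation_null(sub, subset_size=10, B=1, seed=0).slopes[0]
            assert one == pytest.approx(direct, rel=1e-10)

    def test_variance_shrinks_with_subset_size(self, noisy_line):
        variances = [
            permutation_null(noisy_line, m, B=2000, seed=11).slopes.var()
            for m in (5, 10, 20, 50)
        ]
        assert variances == sorted(variances, reverse=True)

    def test_constant_x_subsets_redrawn(self):
        x = np.array([0.0] * 8 + [1.0, 2.0, 3.0])
        s = BivariateSample(x=x, y=np.arange(11.0))
        null = permutation_null(s, subset_size=3, B=300, seed=5)
        assert np.isfinite(null.slopes).all()
        assert null.n_redraws > 0

    def test_subset_size_bounds(self, noisy_line):
        with pytest.raises(DataError):
            permutation_null(noisy_line, subset_size=1, B=10, seed=0)
        with pytest.raises(DataError):
            permutation_null(noisy_line, subset_size=noisy_line.n + 1, B=10, seed=0)


class TestCompareCluster:
    def test_zero_deviation_gives_p_one(self, noisy_line):
        group = fit_ols(noisy_line)
        null = permutation_null(noisy_line, 20, B=999, seed=0)
        p, sig, rev = compare_cluster(group, group, null)
        assert p == 1.0 and not sig and not rev

    def test_p_floor_is_one_over_b_plus_one(self, noisy_line):
        group = fit_ols(noisy_line)
        null = permutation_null(noisy_line, 20, B=199, seed=0)
        far = fit_ols(
            BivariateSample(x=noisy_line.x[:20], y=-50 * noisy_line.x[:20]
                            + np.arange(20) * 0.01)
        )
        p, sig, rev = compare_cluster(group, far, null)
        assert p == pytest.approx(1 / 200)
        assert sig and rev

    def test_empty_null_errors(self, noisy_line):
        group = fit_ols(noisy_line)
        with pytest.raises(DataError):
            compare_cluster(group, group, np.array([]))

    def test_observation_relabeling_leaves_p_stable(self, rng):
        sample = gen_archetype(GeneratorSpec("two_cluster", seed=4))
        perm = rng.permutation(sample.n)
        shuffled = sample.take(perm)
        group = fit_ols(sample)
        cl = fit_ols(sample.take(np.asarray(sample.group) == "c1"))
        B = 4000
        p1 = compare_cluster(group, cl, permutation_null(sample, cl.n, B, seed=1))[0]
        p2 = compare_cluster(group, cl, permutation_null(shuffled, cl.n, B, seed=2))[0]
        assert abs(p1 - p2) <= 2 / np.sqrt(B) + 1e-9


class TestDetectSp:
    def test_manifest_single_group_is_trivial(self, noisy_line):
        s = BivariateSample(
            x=noisy_line.x, y=noisy_line.y, group=np.repeat("all", noisy_line.n)
        )
        rep = detect_sp(s, mode="manifest", seed=0, B=200)
        assert len(rep.findings) == 1
        assert rep.findings[0].p_perm == 1.0
        assert rep.warnings == ()

    def test_within_person_archetype_reverses_every_subject(self):
        sample = gen_archetype(GeneratorSpec("within_person", seed=8))
        rep = detect_sp(sample, mode="manifest", seed=8, B=1000)
        assert fit_ols(sample).slope > 0
        assert len(rep.findings) == 10
        assert all(f.sign_reversed for f in rep.findings)
        assert all(w.startswith("Sign reversal") for w in rep.warnings)

    def test_latent_two_cluster_emits_verbatim_reversal_warnings(self):
        sample = gen_archetype(GeneratorSpec("two_cluster", seed=2))
        rep = detect_sp(sample, mode="latent", seed=2, B=1000)
        assert rep.model is not None and rep.model.K == 2
        assert rep.warnings == (
            WARN_REVERSAL.format(X=1),
            WARN_REVERSAL.format(X=2),
        )
        assert "Sign reversal: Simpson's Paradox!" in rep.warnings[0]

    def test_small_clusters_skipped(self, rng):
        x = rng.uniform(0, 10, 60)
        y = x + rng.normal(0, 1, 60)
        group = np.array(["big"] * 55 + ["tiny"] * 5)
        rep = detect_sp(
            BivariateSample(x=x, y=y, group=group), mode="manifest", seed=0, B=100
        )
        assert len(rep.findings) == 1
        assert len(rep.skipped) == 1 and rep.skipped[0].n == 5

    def test_mode_requirements(self, noisy_line):
        with pytest.raises(ConfigError):
            detect_sp(noisy_line, mode="manifest", seed=0)
        with pytest.raises(ConfigError):
            detect_sp(noisy_line, mode="features", seed=0)
        with pytest.raises(ConfigError):
            detect_sp(noisy_line, mode="nope", seed=0)
        with pytest.raises(ConfigError):
            detect_sp(noisy_line, mode="latent", seed=0, alpha=1.5)

    def test_features_mode_uses_covariate_block(self, rng):
        # two feature blobs define opposite x-y slopes (manifest-by-proxy)
        n = 80
        f1 = rng.normal(-4, 1, (n, 2))
        f2 = rng.normal(4, 1, (n, 2))
        x = rng.uniform(0, 10, 2 * n)
        slope = np.repeat([1.0, -1.0], n)
        y = slope * x + rng.normal(0, 0.5, 2 * n)
        s = BivariateSample(x=x, y=y, features=np.vstack([f1, f2]))
        rep = detect_sp(s, mode="features", seed=0, B=500, k_max=3)
        assert rep.model is not None and rep.model.K == 2
        assert len(rep.findings) == 2
        assert any(f.significant for f in rep.findings)
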