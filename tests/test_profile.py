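"""Thickness profiles, sigmoid interface, gelatin correlation, clustering."""

import numpy as np
import pytest

from dyescan.classify import EXCLUDED, SHADE1, SHADE2
from dyescan.profile import (
    DegenerateClusterError, LayerProfile, UndefinedCorrelationError,
    build_profile, cluster_pairs, correlate_gelatin, fit_sigmoid,
    label_regime,
)
from dyescan.synthetic import generate_profile

from conftest import make_classmap


def profile_from(f2, f1=None, weights=None):
    f2 = np.asarray(f2, dtype=float)
    f1 = np.zeros_like(f2) if f1 is None else np.asarray(f1, dtype=float)
    return LayerProfile(n_layers=f2.size, fractions_shade1=f1,
                        fractions_shade2=f2, gelatin_weight=weights)


class TestBuildProfile:
    def test_fraction_is_count_over_total(self):
        labels = np.full((10, 10), EXCLUDED)
        labels.ravel()[:50] = SHADE1
        prof = build_profile([make_classmap(labels)])
        assert prof.fractions_shade1[0] == 0.5
        assert prof.fractions_shade2[0] == 0.0

    def test_all_excluded_gives_zero_fractions(self):
        maps = [make_classmap(np.full((5, 5), EXCLUDED), i, 3)
                for i in (1, 2, 3)]
        prof = build_profile(maps)
        assert not prof.fractions_shade1.any()
        assert not prof.fractions_shade2.any()

    def test_missing_layer_is_sequencing_error(self):
        maps = [make_classmap(np.full((5, 5), EXCLUDED), i, 3)
                for i in (1, 3)]
        with pytest.raises(ValueError, match="gaps"):
            build_profile(maps)

    def test_invariant_under_pixel_duplication(self):
        rng = np.random.default_rng(3)
        labels = rng.choice([EXCLUDED, SHADE1, SHADE2], size=(20, 20))
        doubled = np.repeat(np.repeat(labels, 2, axis=0), 2, axis=1)
        p1 = build_profile([make_classmap(labels)])
        p2 = build_profile([make_classmap(doubled)])
        assert p1.fractions_shade1[0] == p2.fractions_shade1[0]
        assert p1.fractions_shade2[0] == p2.fractions_shade2[0]


class TestFitSigmoid:
    def test_flat_profile(self):
        fit = fit_sigmoid(profile_from([0.3] * 8))
        assert fit.lower == pytest.approx(0.3, abs=1e-9)
        assert fit.upper == pytest.approx(0.3, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.interface_free

    def test_exact_logistic_recovered(self):
        y = generate_profile(16, "sigmoid", lower=0.1, upper=0.6,
                             midpoint=8.5, steepness=0.8)
        fit = fit_sigmoid(profile_from(y))
        assert fit.lower == pytest.approx(0.1, abs=1e-4)
        assert fit.upper == pytest.approx(0.6, abs=1e-4)
        assert fit.midpoint == pytest.approx(8.5, abs=1e-4)
        assert fit.steepness == pytest.approx(0.8, abs=1e-4)
        assert not fit.interface_free

    def test_thin_uniform_profile_flagged_interface_free(self):
        fit = fit_sigmoid(profile_from([0.25] * 4))
        assert fit.interface_free

    def test_reversal_reflects_midpoint_and_negates_steepness(self):
        y = generate_profile(16, "sigmoid", lower=0.1, upper=0.6,
                             midpoint=7.0, steepness=0.9)
        fwd = fit_sigmoid(profile_from(y))
        rev = fit_sigmoid(profile_from(y[::-1]))
        assert rev.steepness == pytest.approx(-fwd.steepness, abs=1e-6)
        assert rev.midpoint == pytest.approx(17.0 - fwd.midpoint, abs=1e-6)
        assert rev.lower == pytest.approx(fwd.lower, abs=1e-6)
        assert rev.upper == pytest.approx(fwd.upper, abs=1e-6)

    def test_too_few_layers_rejected(self):
        with pytest.raises(ValueError, match="4 layers"):
            fit_sigmoid(profile_from([0.1, 0.2, 0.3]))


class TestCorrelateGelatin:
    def test_exact_proportionality(self):
        w = np.array([1.0, 2.0, 3.0, 4.0])
        prof = profile_from([0] * 4, f1=0.1 * w, weights=w)
        res = correlate_gelatin(prof)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(0.1, rel=1e-9)

    def test_reversed_weights_give_minus_one(self):
        w = np.array([4.0, 3.0, 2.0, 1.0])
        prof = profile_from([0] * 4, f1=[0.1, 0.2, 0.3, 0.4], weights=w)
        assert correlate_gelatin(prof).r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(5)
        f1 = rng.uniform(0.05, 0.4, 12)
        w = rng.uniform(1, 5, 12)
        res = correlate_gelatin(profile_from([0] * 12, f1=f1, weights=w))
        # closed-form oracle, symmetric in its arguments
        def pearson(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return float((xc * yc).sum()
                         / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
        assert res.r == pytest.approx(pearson(w, f1), abs=1e-12)
        assert pearson(w, f1) == pytest.approx(pearson(f1, w), abs=1e-15)

    def test_coupled_noisy_profiles_correlate_strongly(self):
        """fraction = k w + noise (sd 10% of range) keeps r >= 0.8."""
        ok = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            w = rng.uniform(1.0, 5.0, 32)
            f1 = np.clip(0.08 * w + rng.normal(0, 0.1 * 0.08 * 4, 32), 0, 1)
            res = correlate_gelatin(profile_from([0] * 32, f1=f1, weights=w))
            ok += res.r >= 0.8
        assert ok / reps >= 0.95

    def test_zero_variance_rejected(self):
        prof = profile_from([0] * 4, f1=[0.2] * 4, weights=[1, 2, 3, 4])
        with pytest.raises(UndefinedCorrelationError):
            correlate_gelatin(prof)


class TestClusterPairs:
    @staticmethod
    def blob_profiles(seed=0):
        """Main cloud of 18 pairs plus 14 planted high-weight outliers."""
        rng = np.random.default_rng(seed)
        w_main = rng.normal(2.0, 0.2, 18)
        f_main = np.clip(rng.normal(0.15, 0.02, 18), 0, 1)
        w_out = rng.normal(6.0, 0.3, 14)
        f_out = np.clip(rng.normal(0.45, 0.03, 14), 0, 1)
        prof = profile_from([0] * 32,
                            f1=np.concatenate([f_main, f_out]),
                            weights=np.concatenate([w_main, w_out]))
        return prof

    def test_separated_blobs_recovered_exactly(self):
        prof = self.blob_profiles()
        result = cluster_pairs([prof])
        assert result.labels[:18] == ("main",) * 18
        assert result.labels[18:] == ("outlier",) * 14
        assert result.centroid_outlier[0] > result.centroid_main[0]

    def test_single_blob_outlier_at_most_half(self):
        rng = np.random.default_rng(2)
        w = rng.normal(2.0, 0.1, 12)
        f = np.clip(rng.normal(0.2, 0.01, 12), 0, 1)
        prof = profile_from([0] * 12, f1=f, weights=w)
        result = cluster_pairs([prof])
        assert sum(l == "outlier" for l in result.labels) <= 6

    def test_deterministic_and_permutation_invariant(self):
        prof = self.blob_profiles(seed=7)
        base = cluster_pairs([prof])
        assert cluster_pairs([prof]) == base
        perm = np.random.default_rng(1).permutation(32)
        shuffled = profile_from([0] * 32, f1=prof.fractions_shade1[perm],
                                weights=prof.gelatin_weight[perm])
        permuted = cluster_pairs([shuffled])
        assert tuple(np.array(permuted.labels)) == tuple(
            np.array(base.labels)[perm])

    def test_identical_points_degenerate(self):
        prof = profile_from([0] * 6, f1=[0.2] * 6, weights=[3.0] * 6)
        with pytest.raises(DegenerateClusterError):
            cluster_pairs([prof])

    def test_too_few_pairs_rejected(self):
        prof = profile_from([0] * 4, f1=[0.1, 0.2, 0.3, 0.4],
                            weights=[1, 2, 3, 4])
        with pytest.raises(ValueError, match="at least 6"):
            cluster_pairs([prof])


class TestLabelRegime:
    @pytest.mark.parametrize("mode", ["uniform", "sigmoid", "edge_peaked"])
    def test_clean_profiles_labeled_correctly(self, mode):
        y = generate_profile(16, mode)
        assert label_regime(y) == mode

    def test_edge_peaked_symmetry(self):
        y = generate_profile(32, "edge_peaked")
        assert y[0] == y[-1] == y.max()
        assert y.argmin() in (15, 16)
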