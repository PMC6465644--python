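"""Behavioral readouts: HDIs, survival posteriors, deviational
ellipses, migration CIs, and tropism classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from zfpdx.atlas import REGION_NAMES
from zfpdx.behavior import (
    EmbryoCohort,
    EmbryoRecord,
    FocusRecord,
    assign_regions,
    bootstrap_ellipse,
    classify_distribution,
    compare_dispersion,
    compare_hdi,
    deviational_ellipse,
    engraftment_efficiency,
    hdi,
    mean_migration,
    preferred_regions,
    region_probabilities,
    summarize_cohort,
    survival_posterior,
)


# ---------------------------------------------------------------------------
# HDI
# ---------------------------------------------------------------------------


class TestHdi:
    def test_symmetric_beta_interval_symmetric_about_half(self):
        lo, hi = hdi(stats.beta(2, 2))
        assert lo + hi == pytest.approx(1.0, abs=1e-6)

    def test_gamma_matches_grid_search_oracle(self):
        dist = stats.gamma(21, scale=1 / 5)
        lo, hi = hdi(dist)
        grid = np.linspace(0.0, 0.05, 50_001)
        widths = dist.ppf(grid + 0.95) - dist.ppf(grid)
        a = grid[np.argmin(widths)]
        assert lo == pytest.approx(dist.ppf(a), abs=1e-4)
        assert hi == pytest.approx(dist.ppf(a + 0.95), abs=1e-4)

    def test_full_mass_gives_full_support(self):
        assert hdi(stats.beta(3, 5), mass=1.0) == (0.0, 1.0)

    def test_mass_inside_interval_by_quadrature(self):
        for dist in (stats.gamma(21, scale=1 / 5), stats.beta(5, 115), stats.gamma(1, 2)):
            lo, hi = hdi(dist)
            mass, _ = integrate.quad(dist.pdf, lo, hi)
            assert mass == pytest.approx(0.95, abs=1e-6)

    def test_flat_density_returns_central_interval(self):
        lo, hi = hdi(stats.uniform(0, 1))
        assert lo == pytest.approx(0.025, abs=1e-6)
        assert hi == pytest.approx(0.975, abs=1e-6)

    def test_sample_based_hdi_close_to_analytic(self, rng):
        dist = stats.gamma(21, scale=1 / 5)
        draws = dist.rvs(size=100_000, random_state=rng)
        lo_s, hi_s = hdi(draws)
        lo, hi = hdi(dist)
        assert lo_s == pytest.approx(lo, abs=0.05)
        assert hi_s == pytest.approx(hi, abs=0.05)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="1,000"):
            hdi(rng.normal(size=100))


class TestCompareHdi:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 1), (2, 3), "different"),
            ((0, 2), (1, 3), "not-different"),
            ((0, 1), (1, 2), "not-different"),  # touching endpoints, closed intervals
        ],
    )
    def test_disjointness_rule(self, a, b, expected):
        assert compare_hdi(a, b) == expected

    @given(
        vals=st.lists(st.floats(min_value=-100, max_value=100), min_size=4, max_size=4)
    )
    def test_symmetry(self, vals):
        a = (min(vals[0], vals[1]), max(vals[0], vals[1]))
        b = (min(vals[2], vals[3]), max(vals[2], vals[3]))
        assert compare_hdi(a, b) == compare_hdi(b, a)


# ---------------------------------------------------------------------------
# Survival posterior
# ---------------------------------------------------------------------------


class TestSurvivalPosterior:
    def test_conjugate_update_identity(self):
        s = survival_posterior([5, 5, 5, 5])
        assert (s.a, s.b) == (21.0, 5.0)
        assert s.mean == pytest.approx(4.2)

    def test_all_zero_counts_hdi_starts_at_zero(self):
        s = survival_posterior([0, 0, 0, 0])
        assert (s.a, s.b) == (1.0, 5.0)
        assert s.hdi95[0] == pytest.approx(0.0, abs=1e-9)

    def test_posterior_mass_inside_hdi(self):
        s = survival_posterior([3, 1, 4, 1, 5])
        dist = stats.gamma(s.a, scale=1 / s.b)
        mass, _ = integrate.quad(dist.pdf, *s.hdi95)
        assert mass == pytest.approx(0.95, abs=1e-6)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            survival_posterior([])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative integers"):
            survival_posterior([1.5, 2.0])


# ---------------------------------------------------------------------------
# Engraftment
# ---------------------------------------------------------------------------


def tiny_cohort(n_with_foci, n_total, sample_id="S"):
    embryos = []
    for i in range(n_total):
        foci = {}
        if i < n_with_foci:
            foci[1] = [FocusRecord(f"e{i}", sample_id, 1, 0.0, 0.0)]
        embryos.append(EmbryoRecord(f"e{i}", engrafted=i < n_with_foci, foci=foci))
    return EmbryoCohort(sample_id=sample_id, embryos=embryos, n_injected=n_total)


class TestEngraftment:
    def test_simple_fraction(self):
        assert engraftment_efficiency(tiny_cohort(21, 24)) == 87.5

    def test_no_foci_gives_zero(self):
        assert engraftment_efficiency(tiny_cohort(0, 24)) == 0.0

    def test_zero_injected_rejected(self):
        cohort = EmbryoCohort(sample_id="S", embryos=[], n_injected=0)
        with pytest.raises(ValueError, match="n_injected"):
            engraftment_efficiency(cohort)


# ---------------------------------------------------------------------------
# Migration and ellipse
# ---------------------------------------------------------------------------


class TestMeanMigration:
    def test_single_focus_at_origin(self):
        m_ap, m_dv, _, _ = mean_migration([(0.0, 0.0)], n_boot=0)
        assert (m_ap, m_dv) == (0.0, 0.0)

    def test_symmetric_pair(self):
        m_ap, m_dv, _, _ = mean_migration([(3.0, 0.0), (-3.0, 0.0)], n_boot=0)
        assert (m_ap, m_dv) == (3.0, 0.0)

    def test_bootstrap_ci_coverage(self, rng):
        """Percentile-bootstrap coverage for the mean |x| at n=50 sits
        near (slightly under) the nominal 95%."""
        true_m = np.sqrt(2 / np.pi)  # E|Z| for standard normal
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            pts = rng.normal(size=(50, 2))
            _, _, ci_ap, _ = mean_migration(pts, n_boot=400, seed=int(rng.integers(2**31)))
            hits += ci_ap[0] <= true_m <= ci_ap[1]
        assert 0.90 <= hits / n_rep <= 0.99


class TestDeviationalEllipse:
    def test_symmetric_cross_is_circular(self):
        e = deviational_ellipse([(1, 0), (-1, 0), (0, 1), (0, -1)])
        assert e.center == (0.0, 0.0)
        assert e.semi_major == pytest.approx(e.semi_minor)

    def test_collinear_points_zero_minor_axis(self):
        e = deviational_ellipse([(-2, 0), (-1, 0), (1, 0), (2, 0)])
        assert e.theta == pytest.approx(0.0)
        assert e.semi_minor == pytest.approx(0.0, abs=1e-12)

    @given(angle=st.floats(min_value=0.0, max_value=np.pi))
    def test_rotation_equivariance(self, angle):
        rng = np.random.default_rng(99)
        pts = rng.normal(size=(30, 2)) * [3.0, 1.0]
        base = deviational_ellipse(pts)
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        rotated = deviational_ellipse(pts @ rot.T)
        assert rotated.semi_major == pytest.approx(base.semi_major, rel=1e-9)
        assert rotated.semi_minor == pytest.approx(base.semi_minor, rel=1e-9)
        dtheta = (rotated.theta - base.theta - angle) % np.pi
        assert min(dtheta, np.pi - dtheta) == pytest.approx(0.0, abs=1e-6)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            deviational_ellipse([(0.0, 0.0)])


class TestBootstrapEllipse:
    def test_identical_points_zero_width_cis(self):
        pts = [(5.0, 5.0)] * 8
        e = bootstrap_ellipse(pts, n_boot=200, seed=1)
        for lo, hi in e.ci.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_fixed_seed_reproducible(self, rng):
        pts = rng.normal(size=(20, 2))
        e1 = bootstrap_ellipse(pts, n_boot=500, seed=7)
        e2 = bootstrap_ellipse(pts, n_boot=500, seed=7)
        assert e1.ci == e2.ci

    def test_semi_major_ci_coverage(self, rng):
        """Coverage for the semi-major axis of an anisotropic Gaussian
        at n=40 stays within a few points of the nominal 95%."""
        true_major = np.sqrt(2 * 4.0)  # cov diag(4, 1)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            pts = rng.normal(size=(40, 2)) * [2.0, 1.0]
            e = bootstrap_ellipse(pts, n_boot=600, seed=int(rng.integers(2**31)))
            lo, hi = e.ci["semi_major"]
            hits += lo <= true_major <= hi
        assert abs(hits / n_rep - 0.95) <= 0.04

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            bootstrap_ellipse([(0, 0)] * 4, n_boot=10, seed=0)


class TestCompareDispersion:
    def test_same_points_not_different(self, rng):
        pts = rng.normal(size=(50, 2)) * 100
        assert compare_dispersion(pts, pts, n_boot=300, seed=1) == "not-different"

    def test_distant_tight_clusters_different(self, rng):
        a = rng.normal(size=(50, 2)) * 20
        b = a + [1000.0, 0.0]
        assert compare_dispersion(a, b, n_boot=300, seed=1) == "different"

    def test_false_positive_rate_controlled(self, rng):
        """Two draws from one distribution: not-different in >=90% of
        replicates."""
        hits = 0
        for _ in range(100):
            a = rng.normal(size=(50, 2)) * 100
            b = rng.normal(size=(50, 2)) * 100
            hits += compare_dispersion(a, b, n_boot=200,
                                       seed=int(rng.integers(2**31))) == "not-different"
        assert hits >= 90

    def test_permutation_alternative_detects_shift(self, rng):
        a = rng.normal(size=(30, 2)) * 20
        b = a + [1000.0, 0.0]
        assert compare_dispersion(a, b, n_boot=200, seed=2,
                                  method="permutation") == "different"


# ---------------------------------------------------------------------------
# Tropism
# ---------------------------------------------------------------------------


class TestTropism:
    def test_conjugate_posterior_mean_identity(self):
        counts = np.zeros(10, dtype=int)
        counts[REGION_NAMES.index("CHT")] = 10
        prof = region_probabilities(counts)
        cht = prof.prob_mean[REGION_NAMES.index("CHT")]
        assert cht == pytest.approx(11 / 20)
        assert cht == prof.prob_mean.max()

    def test_prob_mean_sums_to_one(self, rng):
        counts = rng.integers(0, 30, size=10)
        counts[0] += 1  # ensure non-empty
        prof = region_probabilities(counts)
        assert prof.prob_mean.sum() == pytest.approx(1.0, abs=1e-9)

    def test_equal_counts_give_equal_means(self):
        prof = region_probabilities(np.full(10, 7))
        assert np.allclose(prof.prob_mean, 0.1)

    def test_marginal_hdi_mass_by_quadrature(self):
        prof = region_probabilities(np.array([30, 5, 2, 1, 0, 0, 8, 3, 1, 0]))
        total = prof.alpha.sum()
        for a, (lo, hi) in zip(prof.alpha, prof.hdi95):
            dist = stats.beta(a, total - a)
            mass, _ = integrate.quad(dist.pdf, lo, hi)
            assert mass == pytest.approx(0.95, abs=1e-6)

    def test_tiny_spread_sample_is_random(self):
        counts = np.zeros(10, dtype=int)
        counts[:5] = 1  # 5 foci over 5 regions: HDIs wide, all overlap
        prof = region_probabilities(counts)
        assert classify_distribution(prof) == "random"

    def test_concentrated_sample_is_clumped(self):
        counts = np.full(10, 50 / 9)
        counts = np.array([150] + [round(c) for c in counts[1:]])
        prof = region_probabilities(counts)
        assert classify_distribution(prof) == "clumped"

    def test_symmetric_counts_are_random(self):
        prof = region_probabilities(np.full(10, 20))
        assert classify_distribution(prof) == "random"

    def test_preferred_regions_empty_under_uniformity(self):
        prof = region_probabilities(np.full(10, 20))
        assert preferred_regions(prof) == ()

    def test_preferred_regions_detects_dominant_region(self):
        counts = np.zeros(10, dtype=int)
        counts[REGION_NAMES.index("CHT")] = 150
        counts += 5
        prof = region_probabilities(counts)
        assert preferred_regions(prof) == ("CHT",)

    def test_all_in_one_region_large_n(self):
        counts = np.zeros(10, dtype=int)
        counts[REGION_NAMES.index("PCV")] = 500
        prof = region_probabilities(counts)
        assert preferred_regions(prof) == ("PCV",)


# ---------------------------------------------------------------------------
# Region assignment and full summary
# ---------------------------------------------------------------------------


class TestAssignRegions:
    def test_generator_labels_recovered(self, atlas, rng):
        """Coordinate-based labels agree with the generative region for
        nearly all foci.  With 10 um Gaussian jitter the expected
        crossing fraction is (interior edge length x 2 x sd/sqrt(2 pi))
        / atlas area ~ 1.8% for the default geometry, so agreement sits
        just above 98%."""
        from zfpdx.synthdata import SampleProfile, StudyConfig, gen_embryo_cohort

        prof = SampleProfile(sample_id="S", engraft_prob=1.0, foci_mean=25.0)
        cfg = StudyConfig(profiles=[prof], n_embryos_per_sample=420, n_embryos_scored=6)
        cohort = gen_embryo_cohort(prof, cfg, rng, atlas)
        truth = [f.region for f in cohort.all_foci()]
        assert len(truth) >= 10_000
        assign_regions(cohort, atlas)
        recovered = [f.region for f in cohort.all_foci()]
        agreement = np.mean([t == r for t, r in zip(truth, recovered)])
        assert agreement >= 0.975


class TestSummarizeCohort:
    def test_summary_has_all_readouts(self, small_study, atlas):
        cohort = small_study.cohorts["LPZ13"]
        s = summarize_cohort(cohort, atlas, n_boot=200, seed=3)
        assert 0 <= s.engraftment_pct <= 100
        assert 1 in s.survival and 2 in s.survival
        assert s.tropism is not None
        assert s.tropism.classification in ("random", "clumped")
        assert s.ellipse is not None and s.ellipse.ci is not None
        assert s.mean_ap >= 0 and s.mean_dv >= 0
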