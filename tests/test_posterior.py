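"""Posterior summaries: KDE grids, MDEs, range probabilities, credible
intervals, and suspect-fit flags."""

import numpy as np
import pytest

from weanabc import (
    ParticleSystem,
    WeaningParams,
    credible_interval,
    density_grids,
    flag_suspect_fit,
    mde,
    range_probability,
    summarize,
)
from weanabc.posterior import Grid1D, PosteriorSummary
from weanabc.forward_model import Trajectory


def make_ps(particles, weights=None, names=("t1", "t2", "enrichment", "d15n_wnfood")):
    particles = np.asarray(particles, dtype=float)
    n = len(particles)
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    return ParticleSystem(
        particles=particles,
        weights=w / w.sum(),
        distances=np.zeros(n),
        tolerance=0.1,
        tolerance_history=(np.inf, 0.1),
        acceptance_history=(1.0, 0.5),
        param_names=names,
    )


@pytest.fixture(scope="module")
def gaussian_cloud():
    """Standard-normal particles in each of the four coordinates,
    shifted to a known center."""
    rng = np.random.default_rng(0)
    center = np.array([1.0, 3.0, 2.0, 9.0])
    pts = rng.normal(0.0, 1.0, size=(30_000, 4)) + center
    return make_ps(pts)


class TestDensityGrids:
    def test_masses_are_probability_distributions(self, gaussian_cloud):
        grids = density_grids(gaussian_cloud)
        for mass in (
            grids.joint_ages.mass,
            grids.enrichment.mass,
            grids.wnfood.mass,
        ):
            assert np.all(mass >= 0)
            assert mass.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("half_width", [1.0, 1.96])
    def test_gaussian_mass_matches_cdf_oracle(self, gaussian_cloud, half_width):
        """Mass of a central window of a standard-normal cloud equals the
        normal CDF mass of the included cells (0.683-ish for +-1 sd,
        0.95-ish for +-1.96 sd)."""
        from scipy.stats import norm

        grids = density_grids(gaussian_cloud)
        g = grids.enrichment
        mu = 2.0
        p = range_probability(g, (mu - half_width, mu + half_width))
        included = g.centers[
            (g.centers >= mu - half_width - 1e-9)
            & (g.centers <= mu + half_width + 1e-9)
        ]
        expected = (
            norm.cdf(included.max() + 0.05 - mu) - norm.cdf(included.min() - 0.05 - mu)
        )
        assert p == pytest.approx(expected, abs=0.02)

    def test_degenerate_cloud_concentrates(self):
        pts = np.tile([1.0, 3.0, 2.4, 9.0], (500, 1))
        grids = density_grids(make_ps(pts))
        p = range_probability(grids.enrichment, (2.35, 2.45))
        assert p >= 0.99

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal([1.0, 3.0, 2.0, 9.0], 0.5, size=(2000, 4))
        w = rng.random(2000)
        a = density_grids(make_ps(pts, weights=w))
        b = density_grids(make_ps(pts, weights=2.0 * w))
        assert np.allclose(a.enrichment.mass, b.enrichment.mass)
        assert np.allclose(a.joint_ages.mass, b.joint_ages.mass)


class TestMde:
    def test_known_mode_recovered(self):
        """A unimodal cloud centered at known values yields an MDE within
        one grid cell of the center (a tight cloud, so the discretized
        mode is unambiguous)."""
        rng = np.random.default_rng(5)
        center = np.array([1.0, 3.0, 2.0, 9.0])
        pts = rng.normal(center, 0.25, size=(20_000, 4))
        point, _tied = mde(density_grids(make_ps(pts)))
        assert point.t1 == pytest.approx(1.0, abs=0.1 + 1e-9)
        assert point.t2 == pytest.approx(3.0, abs=0.1 + 1e-9)
        assert point.enrichment == pytest.approx(2.0, abs=0.1 + 1e-9)
        assert point.d15n_wnfood == pytest.approx(9.0, abs=0.1 + 1e-9)

    def test_uniform_grid_breaks_ties_low_and_flags(self):
        from weanabc.posterior import PosteriorGrids, Grid2D

        centers = np.arange(0, 5) * 0.1
        flat1d = Grid1D("enrichment", centers, np.full(5, 0.2))
        joint = Grid2D("t1", "t2", centers, centers, np.full((5, 5), 0.04))
        grids = PosteriorGrids(joint, flat1d, Grid1D("d15n_wnfood", centers, np.full(5, 0.2)))
        point, tied = mde(grids)
        assert tied
        assert point.t1 == 0.0 and point.t2 == 0.0
        assert point.enrichment == 0.0

    def test_degenerate_posterior_returns_the_point(self):
        pts = np.tile([0.8, 2.1, 2.4, 8.7], (100, 1))
        point, _ = mde(density_grids(make_ps(pts)))
        assert np.allclose(point.as_array(), [0.8, 2.1, 2.4, 8.7], atol=1e-9)


class TestRangeProbability:
    def test_full_support_is_one(self, gaussian_cloud):
        grids = density_grids(gaussian_cloud)
        g = grids.wnfood
        assert range_probability(
            g, (g.centers[0], g.centers[-1])
        ) == pytest.approx(1.0)

    def test_disjoint_halves_sum_to_one(self, gaussian_cloud):
        g = density_grids(gaussian_cloud).wnfood
        split = 9.05
        left = range_probability(g, (g.centers[0], split))
        right = range_probability(g, (split + 1e-6, g.centers[-1]))
        assert left + right == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_central_95(self, gaussian_cloud):
        g = density_grids(gaussian_cloud).wnfood
        p = range_probability(g, (9.0 - 1.96, 9.0 + 1.96))
        assert p == pytest.approx(0.95, abs=0.02)

    def test_empty_range_warns_and_returns_zero(self, gaussian_cloud):
        g = density_grids(gaussian_cloud).wnfood
        with pytest.warns(UserWarning):
            assert range_probability(g, (999.0, 999.5)) == 0.0

    def test_monotone_under_inclusion(self, gaussian_cloud):
        g = density_grids(gaussian_cloud).enrichment
        narrow = range_probability(g, (1.5, 2.5))
        wide = range_probability(g, (1.0, 3.0))
        assert wide >= narrow


class TestCredibleInterval:
    def test_full_level_spans_particle_range(self):
        ps = make_ps(np.column_stack([np.linspace(0, 1, 50)] * 4))
        lo, hi = credible_interval(ps, "t1", 1.0)
        assert lo == pytest.approx(0.0) and hi == pytest.approx(1.0)

    def test_uniform_weights_match_linear_quantiles(self):
        vals = np.arange(1.0, 101.0)
        ps = make_ps(np.column_stack([vals] * 4))
        lo, hi = credible_interval(ps, "enrichment", 0.5)
        assert lo == pytest.approx(25.75)
        assert hi == pytest.approx(75.25)

    def test_nested_levels(self, fitted):
        inner = credible_interval(fitted, "t2", 0.5)
        outer = credible_interval(fitted, "t2", 0.9)
        assert outer[0] <= inner[0] and inner[1] <= outer[1]

    def test_invalid_level_rejected(self, fitted):
        with pytest.raises(ValueError):
            credible_interval(fitted, "t1", 1.5)


class TestSummaryAndFlags:
    def _summary(self, joint=0.01, marg_e=0.2, marg_w=0.2, delta=-0.5, e=2.4):
        traj = Trajectory(np.array([0.0]), np.array([9.0]), np.array([9.0]))
        return PosteriorSummary(
            mde=WeaningParams(1.0, 3.0, e, 9.0),
            mde_tied=False,
            mde_joint_prob_ages=joint,
            mde_marginal_prob_e=marg_e,
            mde_marginal_prob_wnfood=marg_w,
            delta_wnfood=delta,
            credible_intervals={},
            fitted=traj,
            level=0.95,
        )

    def test_low_joint_probability_flagged(self):
        flags = flag_suspect_fit(self._summary(joint=0.001))
        assert "low_joint_probability" in flags

    def test_low_marginal_probability_flagged(self):
        flags = flag_suspect_fit(self._summary(marg_e=0.04))
        assert "low_marginal_probability" in flags

    def test_implausible_weaning_food_flagged(self):
        flags = flag_suspect_fit(self._summary(delta=-3.0, e=2.4))
        assert "implausible_delta_wnfood" in flags

    def test_flags_do_not_mutate_summary(self):
        s = self._summary(joint=0.001)
        before = s.to_dict()
        flag_suspect_fit(s)
        assert s.to_dict() == before

    def test_summarize_on_fit(self, fixture_population, fitted):
        _, pop = fixture_population
        s = summarize(fitted, pop)
        assert s.delta_wnfood == pytest.approx(
            s.mde.d15n_wnfood - pop.adult_all_mean
        )
        for name in fitted.param_names:
            lo, hi = s.credible_intervals[name]
            assert lo <= hi
        # the MDE of each parameter lies inside its 95% interval
        for name, value in zip(
            fitted.param_names, s.mde.as_array()
        ):
            lo, hi = s.credible_intervals[name]
            assert lo - 1e-9 <= value <= hi + 1e-9
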