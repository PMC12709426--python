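import numpy as np
import pytest

from memsense.distributions import CurvatureDistribution
from memsense.errors import AnalysisError, InputError
from memsense.io import SelectionSpec, Trajectory
from memsense.sensing import (
    depth_curvature_correlation,
    leaflet_agreement,
    log_slope,
    mean_sensed_curvature,
    reweight,
    sample_peptide_curvature,
    slope_difference_test,
)
from memsense.surface import accessible_curvature, curvature_field
from memsense.synthetic import place_peptide, sample_biased_positions, true_mean_curvature

EDGES = np.arange(-0.15, 0.1501, 0.005)
CREST_H = -0.04934802200544679  # -A k^2 / 2 for A=1, lambda=20


def _dist(weights, kind="sampled", mask=None, leaflet="both"):
    w = np.asarray(weights, float)
    return CurvatureDistribution(
        np.arange(len(w) + 1, dtype=float), w / w.sum(), kind, leaflet, mask=mask
    )


class TestSamplePeptideCurvature:
    PHOS = SelectionSpec("po4", bead_names={"PO4"})
    PEP = SelectionSpec("pep", molecule_names={"PEP"})

    def _pinned_traj(self, buckled_frame, leaflet):
        # peptide pinned at x = lambda/4 (crest of the buckle)
        frame = place_peptide(
            buckled_frame, leaflet, 0.3, 90.0, center_xy=(5.0, buckled_frame.box[1] / 2)
        )
        return Trajectory([frame])

    def test_crest_curvature_on_upper_leaflet(self, buckled_frame, config):
        samples, skipped = sample_peptide_curvature(
            self._pinned_traj(buckled_frame, "upper"), self.PHOS, self.PEP, config, "upper"
        )
        assert skipped == 0
        assert samples[0] == pytest.approx(CREST_H, abs=1e-6)

    def test_crest_curvature_on_lower_leaflet_flips_sign(self, buckled_frame, config):
        samples, _ = sample_peptide_curvature(
            self._pinned_traj(buckled_frame, "lower"), self.PHOS, self.PEP, config, "lower"
        )
        assert samples[0] == pytest.approx(-CREST_H, abs=1e-6)

    def test_planar_membrane_samples_are_zero(self, planar_frame, config):
        frame = place_peptide(planar_frame, "upper", 0.3, 90.0)
        samples, _ = sample_peptide_curvature(
            Trajectory([frame]), self.PHOS, self.PEP, config, "upper"
        )
        assert abs(samples[0]) < 1e-3


class TestReweight:
    def test_identity_case_is_flat(self):
        w = np.array([0.1, 0.2, 0.3, 0.4])
        rw = reweight(_dist(w), _dist(w, "accessible"))
        active = rw.weights[~rw.mask]
        np.testing.assert_allclose(active, active[0], atol=1e-12)

    def test_scale_invariance(self):
        s = np.array([0.1, 0.5, 0.4])
        a = np.array([0.2, 0.3, 0.5])
        r1 = reweight(_dist(s), _dist(a, "accessible"))
        r2 = reweight(_dist(10 * s), _dist(3 * a, "accessible"))
        np.testing.assert_allclose(r1.weights, r2.weights, atol=1e-12)

    def test_zero_accessible_bin_masked_with_warning(self):
        s = np.array([0.2, 0.3, 0.5])
        a = np.array([0.5, 0.0, 0.5])
        with pytest.warns(UserWarning, match="masked"):
            rw = reweight(_dist(s), _dist(a, "accessible"))
        assert rw.mask[1]
        assert rw.weights.sum() == pytest.approx(1.0)

    def test_disjoint_supports_raise(self):
        s = np.array([1.0, 0.0])
        a = np.array([0.0, 1.0])
        with pytest.raises(AnalysisError, match="disjoint"):
            with pytest.warns(UserWarning):
                reweight(_dist(s), _dist(a, "accessible"))

    def test_binning_mismatch_rejected(self):
        s = _dist([0.5, 0.5])
        a = CurvatureDistribution(np.array([0.0, 0.5, 1.0]), [0.5, 0.5], "accessible")
        with pytest.raises(InputError):
            reweight(s, a)

    def test_bias_recovery_end_to_end(self, buckled_surfaces, buckled_traj):
        """Headline property: positions biased by exp(a*H) yield a reweighted
        distribution whose log-slope in H recovers a within 10%."""
        gt = buckled_traj.ground_truth
        surf = {
            "amplitude": gt["buckle_amplitude"],
            "wavelength": gt["buckle_wavelength"],
            "box_xy": gt["box_xy"],
        }
        model = buckled_surfaces["upper"]
        xy, truth = sample_biased_positions(surf, 10.0, 100000, seed=21)
        H = curvature_field(model, xy[:, 0], xy[:, 1])[0]
        sampled = CurvatureDistribution.from_samples(H, EDGES, "sampled")
        acc = accessible_curvature(model, 2048, 16, EDGES)
        rw = reweight(sampled, acc)
        assert log_slope(rw) == pytest.approx(truth["bias"], rel=0.10)


class TestSummaryStatistics:
    def test_mean_of_symmetric_distribution_is_zero(self):
        edges = np.linspace(-0.1, 0.1, 11)
        w = np.array([1, 2, 3, 4, 5, 5, 4, 3, 2, 1], float)
        d = CurvatureDistribution(edges, w / w.sum(), "reweighted")
        assert mean_sensed_curvature(d) == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_delta_distribution(self):
        # edges chosen so -0.05 is exactly a bin center
        edges = -0.0525 + 0.005 * np.arange(22)
        w = np.zeros(len(edges) - 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        w[np.argmin(np.abs(centers + 0.05))] = 1.0
        d = CurvatureDistribution(edges, w, "reweighted")
        assert mean_sensed_curvature(d) == pytest.approx(-0.05, abs=1e-9)

    def test_mean_matches_quadrature_of_generating_density(self, buckled_surfaces):
        """The reweighted mean from the Monte-Carlo pipeline matches the same
        statistic computed by direct quadrature of the known sampling
        density over the surface (the generator's density is the oracle)."""
        a = 10.0
        model = buckled_surfaces["upper"]
        surf = {"amplitude": 1.0, "wavelength": 20.0, "box_xy": [model.box[0], model.box[1]]}
        xy, _ = sample_biased_positions(surf, a, 100000, seed=22)
        H = curvature_field(model, xy[:, 0], xy[:, 1])[0]
        sampled = CurvatureDistribution.from_samples(H, EDGES, "sampled")
        rw = reweight(sampled, accessible_curvature(model, 2048, 16, EDGES))
        # quadrature oracle: exact bin weights from the closed-form density
        x = np.linspace(0.0, 20.0, 200001)
        k = 2 * np.pi / 20.0
        area = np.sqrt(1 + (k * np.cos(k * x)) ** 2)
        Hx = true_mean_curvature(x, 1.0, 20.0)
        which = np.digitize(Hx, EDGES) - 1
        nb = len(EDGES) - 1
        acc_w = np.bincount(which, weights=area, minlength=nb)[:nb]
        smp_w = np.bincount(which, weights=area * np.exp(a * Hx), minlength=nb)[:nb]
        ok = acc_w / acc_w.sum() >= 1e-4
        ratio = np.zeros(nb)
        ratio[ok] = (smp_w[ok] / smp_w.sum()) / (acc_w[ok] / acc_w.sum())
        ratio /= ratio.sum()
        centers = 0.5 * (EDGES[:-1] + EDGES[1:])
        oracle = float(np.sum(ratio * centers))
        assert mean_sensed_curvature(rw) == pytest.approx(oracle, rel=0.05)

    def test_leaflet_agreement_bounds(self):
        d1 = _dist([1.0, 0.0], "reweighted")
        d2 = _dist([0.0, 1.0], "reweighted")
        assert leaflet_agreement(d1, d1) == 0.0
        assert leaflet_agreement(d1, d2) == 1.0

    def test_independent_samples_of_same_process_agree(self):
        surf = {"amplitude": 1.0, "wavelength": 20.0, "box_xy": [20.0, 20.0]}
        dists = []
        for seed in (31, 32):
            xy, _ = sample_biased_positions(surf, 5.0, 10000, seed=seed)
            H = true_mean_curvature(xy[:, 0], 1.0, 20.0)
            dists.append(CurvatureDistribution.from_samples(H, EDGES, "sampled"))
        assert leaflet_agreement(dists[0], dists[1]) < 0.05


class TestCorrelationAndSlopes:
    def test_collinear_decreasing_points(self):
        r, p = depth_curvature_correlation([(0, 2), (1, 1), (2, 0)])
        assert r == pytest.approx(-1.0)

    def test_symmetric_tent_has_zero_correlation(self):
        r, _ = depth_curvature_correlation([(0, 0), (1, 1), (2, 0)])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_pearson_matches_covariance_formula(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        r, _ = depth_curvature_correlation(np.column_stack([x, y]))
        direct = np.cov(x, y, ddof=0)[0, 1] / (x.std() * y.std())
        assert r == pytest.approx(direct, abs=1e-12)

    def test_noisy_linear_model_within_parametric_band(self):
        rng = np.random.default_rng(6)
        depths = np.linspace(0.1, 0.6, 6)
        rs = []
        for _ in range(200):
            curv = -0.05 * depths + rng.normal(0, 0.001, 6)
            rs.append(depth_curvature_correlation(np.column_stack([depths, curv]))[0])
        # parametric oracle: replicate the generating model
        assert np.percentile(rs, 97.5) < -0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            depth_curvature_correlation([(1, 0), (1, 1), (1, 2)])

    def test_identical_series_give_null_result(self):
        x = np.arange(5.0)
        y = 2.0 * x + np.array([0.1, -0.2, 0.0, 0.15, -0.05])
        res = slope_difference_test((x, y), (x, y))
        assert res.t == 0.0
        assert res.p == 1.0

    def test_clearly_different_slopes_are_significant(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 1, 20)
        res = slope_difference_test(
            (x, 1.0 * x + rng.normal(0, 1e-4, 20)),
            (x, 2.0 * x + rng.normal(0, 1e-4, 20)),
        )
        assert res.p < 1e-6

    def test_type_one_error_calibrated(self):
        """Under equal true slopes the test rejects at ~alpha = 0.05."""
        rng = np.random.default_rng(9)
        x = np.linspace(0, 1, 10)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            ya = x + rng.normal(0, 0.1, 10)
            yb = x + rng.normal(0, 0.1, 10)
            if slope_difference_test((x, ya), (x, yb)).p < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)
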