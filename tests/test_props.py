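import numpy as np
import pytest

from memsense.errors import AnalysisError
from memsense.io import BeadFrame, SelectionSpec, Trajectory
from memsense.props import (
    area_per_lipid,
    defect_constant,
    defect_constant_loglinear,
    density_profile,
    detect_defects,
    local_maps,
    scc_of_vectors,
    scc_order,
)
from memsense.synthetic import (
    SyntheticBilayerParams,
    gen_defect_areas,
    gen_planar_bilayer,
    place_peptide,
)

DENSE = SyntheticBilayerParams(n_per_leaflet=100, target_apl=65.0, seed=1)
TILE_RADIUS = 0.6  # nm; exceeds lattice-spacing/sqrt(2) so heads tile the plane


def _drop_lipids(frame: BeadFrame, mol_ids) -> BeadFrame:
    keep = ~np.isin(frame.molecule_ids, mol_ids)
    return BeadFrame(
        frame.positions[keep],
        frame.box,
        frame.molecule_ids[keep],
        frame.molecule_names[keep],
        frame.bead_names[keep],
    )


class TestAreaPerLipid:
    def test_arithmetic(self):
        frame = BeadFrame(
            positions=[[1, 1, 1]],
            box=[6.0, 6.0, 10.0],
            molecule_ids=[1],
            molecule_names=["POPC"],
            bead_names=["PO4"],
        )
        mean, sd = area_per_lipid(Trajectory([frame]), 50)
        assert mean == pytest.approx(72.0)
        assert sd == 0.0

    def test_generator_contract(self, planar_traj):
        mean, sd = area_per_lipid(planar_traj, 92)
        assert mean == pytest.approx(65.0)
        assert sd == 0.0


class TestOrderParameter:
    def test_bonds_along_z(self):
        assert scc_of_vectors(np.tile([0.0, 0.0, 1.2], (10, 1))) == pytest.approx(1.0)

    def test_bonds_in_plane(self):
        assert scc_of_vectors(np.tile([0.7, -0.7, 0.0], (10, 1))) == pytest.approx(-0.5)

    def test_isotropic_orientations_average_to_zero(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(100000, 3))
        assert scc_of_vectors(v) == pytest.approx(0.0, abs=0.005)

    def test_synthetic_lipid_tails_are_fully_ordered(self, planar_traj):
        """Generator tails are vertical columns, so every bond has S = 1."""
        profile = scc_order(planar_traj)
        np.testing.assert_allclose(profile.s_cc, 1.0, atol=1e-12)
        assert profile.n_samples == 184


class TestDensityProfile:
    GROUPS = {
        "po4": SelectionSpec("po4", bead_names={"PO4"}),
        "nc3": SelectionSpec("nc3", bead_names={"NC3"}),
        "tails": SelectionSpec("tails", bead_names={"C1A", "C2A", "C3A"}),
    }

    def test_single_bead_lands_in_its_bin(self):
        frame = BeadFrame(
            positions=[[1.0, 1.0, 6.0], [1.0, 1.0, 4.0]],
            box=[5.0, 5.0, 10.0],
            molecule_ids=[1, 2],
            molecule_names=["X", "Y"],
            bead_names=["A", "B"],
        )
        df = density_profile(
            Trajectory([frame]), {"a": SelectionSpec("a", bead_names={"A"})}, bin_width=0.2
        )
        # membrane COM recentred: bead A sits at +1 relative to the COM (z=5)
        occupied = df[df["a"] > 0]
        assert len(occupied) == 1
        assert occupied["z_nm"].iloc[0] == pytest.approx(1.0, abs=0.2)

    def test_symmetric_bilayer_profile_symmetric(self, planar_traj):
        # 0.3 nm bins keep the ±2.0 nm phosphate planes off bin edges, so
        # the half-open histogram convention cannot break mirror symmetry
        df = density_profile(planar_traj, {"po4": self.GROUPS["po4"]}, bin_width=0.3)
        rho = df["po4"].to_numpy()
        np.testing.assert_allclose(rho, rho[::-1], atol=1e-9)

    def test_partition_identity(self, planar_traj):
        df = density_profile(planar_traj, dict(self.GROUPS), bin_width=0.25)
        all_beads = density_profile(
            planar_traj, {"all": SelectionSpec("all")}, bin_width=0.25
        )
        total = df["po4"] + df["nc3"] + df["tails"]
        np.testing.assert_allclose(total, all_beads["all"], atol=1e-9)


class TestDefectDetection:
    def test_continuous_carpet_has_no_defects(self):
        frame = gen_planar_bilayer(DENSE).frames[0]
        assert len(detect_defects(frame, "upper", bead_radius=TILE_RADIUS)) == 0

    def test_single_deleted_lipid_yields_one_defect(self):
        """One vacancy in the jitter-free lattice: exactly one defect whose
        area equals an independent brute-force count of uncovered cells."""
        frame = _drop_lipids(gen_planar_bilayer(DENSE).frames[0], [45])
        areas = detect_defects(frame, "upper", bead_radius=TILE_RADIUS)
        assert len(areas) == 1

        # brute-force oracle: count grid cells not covered by any upper bead
        upper = frame.positions[:, 2] > frame.box[2] / 2
        pos = frame.positions[upper]
        lx, ly = frame.box[0], frame.box[1]
        nx = int(round(lx / 0.1))
        ny = int(round(ly / 0.1))
        cx = (np.arange(nx) + 0.5) * lx / nx
        cy = (np.arange(ny) + 0.5) * ly / ny
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        covered = np.zeros((nx, ny), dtype=bool)
        for px, py, _ in pos:
            dx = gx - px
            dy = gy - py
            dx -= lx * np.round(dx / lx)
            dy -= ly * np.round(dy / ly)
            covered |= dx**2 + dy**2 <= TILE_RADIUS**2
        oracle = np.sum(~covered) * (lx / nx) * (ly / ny) * 100.0
        assert areas[0] == pytest.approx(oracle, rel=1e-9)
        assert oracle > 0

    def test_two_separated_holes_are_two_defects(self):
        frame = _drop_lipids(gen_planar_bilayer(DENSE).frames[0], [45, 47])
        areas = detect_defects(frame, "upper", bead_radius=TILE_RADIUS)
        assert len(areas) == 2

    def test_protruding_tail_bead_is_a_defect(self):
        """A tail bead replacing the headgroup cover counts as a defect cell."""
        frame = gen_planar_bilayer(DENSE).frames[0]
        # remove lipid 45's head beads only -> its tails are exposed
        names = frame.bead_names.astype(str)
        drop = (frame.molecule_ids == 45) & np.isin(names, ["PO4", "NC3"])
        frame2 = BeadFrame(
            frame.positions[~drop],
            frame.box,
            frame.molecule_ids[~drop],
            frame.molecule_names[~drop],
            frame.bead_names[~drop],
        )
        areas = detect_defects(frame2, "upper", bead_radius=TILE_RADIUS)
        assert len(areas) == 1

    def test_grid_origin_shift_changes_area_within_discretization_bound(self):
        frame = _drop_lipids(gen_planar_bilayer(DENSE).frames[0], [45])
        a0 = detect_defects(frame, "upper", bead_radius=TILE_RADIUS)[0]
        shifted = frame.translated([0.05, 0.05, 0.0]).wrapped()
        a1 = detect_defects(shifted, "upper", bead_radius=TILE_RADIUS)[0]
        # perimeter ~ 2*pi*0.6 nm; bound = perimeter * grid_step in Å^2
        assert abs(a1 - a0) <= 2 * np.pi * 0.9 * 0.1 * 100.0


class TestDefectConstant:
    def test_mle_recovery(self):
        sample = gen_defect_areas(30.0, 10000, seed=7)
        pi, ci = defect_constant(sample.areas, a_min=15.0)
        assert pi == pytest.approx(30.0, abs=1.5)

    def test_a_min_invariance_for_exponential_data(self):
        """Memorylessness: the estimate is threshold-independent within CI."""
        sample = gen_defect_areas(30.0, 20000, seed=8)
        fits = {a: defect_constant(sample.areas, a_min=a) for a in (15.0, 20.0, 25.0)}
        for pi, ci in fits.values():
            assert abs(pi - 30.0) < 3 * ci

    def test_loglinear_cross_check_agrees(self):
        sample = gen_defect_areas(25.0, 20000, seed=9)
        pi_mle, _ = defect_constant(sample.areas, a_min=15.0)
        pi_lls, se = defect_constant_loglinear(sample.areas, a_min=15.0)
        assert abs(pi_lls - pi_mle) < 3 * max(se, 0.5)

    def test_all_equal_areas_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            pi, ci = defect_constant(np.full(100, 30.0), a_min=15.0)
        assert pi == 0.0

    def test_insufficient_data_rejected(self):
        with pytest.raises(AnalysisError):
            defect_constant(np.array([20.0, 30.0]), a_min=15.0)

    def test_ci_coverage_near_68_percent(self):
        """π/sqrt(n) is a 1-sigma interval: coverage ≈ 68%."""
        true_pi = 30.0
        hits = 0
        reps = 1000
        for rep in range(reps):
            sample = gen_defect_areas(true_pi, 400, seed=1000 + rep)
            pi, ci = defect_constant(sample.areas, a_min=15.0)
            hits += abs(pi - true_pi) <= ci
        assert hits / reps == pytest.approx(0.683, abs=0.05)


class TestLocalMaps:
    EDGES = np.array([0.0, 1.0, 2.0, 3.0])

    def test_homogeneous_bilayer_thickness(self, planar_frame):
        frame = place_peptide(planar_frame, "upper", 0.0, 90.0)
        df = local_maps(Trajectory([frame]), SelectionSpec("pep", molecule_names={"PEP"}), self.EDGES)
        valid = df["thickness_nm"].dropna()
        np.testing.assert_allclose(valid, 4.0, atol=1e-9)

    def test_programmed_thinning_recovered(self):
        params = SyntheticBilayerParams(
            n_per_leaflet=144, target_apl=65.0, thinning_amplitude=0.4, thinning_sigma=1.0, seed=3
        )
        frame = place_peptide(gen_planar_bilayer(params).frames[0], "upper", 0.0, 90.0)
        df = local_maps(
            Trajectory([frame]), SelectionSpec("pep", molecule_names={"PEP"}),
            np.array([0.0, 0.7, 4.0, 5.0]),
        )
        assert df["thickness_nm"].iloc[0] < 3.8  # thinned near the peptide
        assert df["thickness_nm"].iloc[1] == pytest.approx(4.0, abs=0.1)  # far field

    def test_xy_translation_invariance(self, planar_frame):
        frame = place_peptide(planar_frame, "upper", 0.2, 90.0)
        spec = SelectionSpec("pep", molecule_names={"PEP"})
        df0 = local_maps(Trajectory([frame]), spec, self.EDGES)
        moved = frame.translated([2.3, 1.1, 0.0]).wrapped()
        df1 = local_maps(Trajectory([moved]), spec, self.EDGES)
        np.testing.assert_allclose(
            df0["thickness_nm"], df1["thickness_nm"], atol=1e-9, equal_nan=True
        )
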