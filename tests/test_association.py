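"""Contact-patch geometry, 2D circumference coverage, and the 2D->3D
extensive-association calibration."""

import numpy as np
import pandas as pd
import pytest
import trimesh

from perisoma.association import (
    CalibrationModel,
    classify_association,
    contact_patch,
    coverage_2d,
    coverage_2d_volume,
    fit_calibration,
    map_threshold,
)
from perisoma.simulate import simulate_volume
from perisoma.surfaces import build_surfaces

from conftest import icosphere_surface, pair_config
from oracles import pixel_coverage_2d_oracle, voxel_coverage_oracle


class TestContactPatch:
    def test_disjoint_spheres_have_zero_contact(self):
        a = icosphere_surface(3.0, (0, 0, 0))
        b = icosphere_surface(3.0, (0, 0, 16.0), cell_id=2, cell_class="microglia_soma")
        assert contact_patch(a, b) == (0.0, 0.0)

    def test_half_embedded_sphere_covers_half(self):
        """A sphere half sunk into a large slab: half its faces touch."""
        ball = icosphere_surface(3.0, (0, 0, 0), subdivisions=4)
        slab = trimesh.creation.box(extents=(40, 40, 20))
        slab.apply_translation([0, 0, -10])  # top face at z = 0, through the centre
        slab_surf = icosphere_surface(3.0, (0, 0, 0), cell_id=2)
        slab_surf.mesh = slab
        slab_surf.area = float(slab.area)
        _, cov = contact_patch(ball, slab_surf, delta_contact=0.05)
        assert abs(cov - 0.5) < 0.03

    def test_simulated_pair_matches_voxel_adjacency_oracle(self):
        cfg = pair_config(seed=77, coverage=0.30)
        vol, _, truth = simulate_volume(cfg)
        n = build_surfaces(vol, "neuron")[0]
        m = build_surfaces(vol, "microglia")[0]
        _, cov = contact_patch(n, m)
        assert 0.27 <= cov <= 0.33
        assert abs(cov - voxel_coverage_oracle(vol, 1, 1)) <= 0.03

    def test_monotone_in_contact_distance(self):
        cfg = pair_config(seed=78, coverage=0.2)
        vol, _, _ = simulate_volume(cfg)
        n = build_surfaces(vol, "neuron")[0]
        m = build_surfaces(vol, "microglia")[0]
        covs = [contact_patch(n, m, d)[1] for d in (0.1, 0.2, 0.4, 0.8)]
        assert all(b >= a for a, b in zip(covs, covs[1:]))

    def test_open_mesh_rejected(self):
        a = icosphere_surface(3.0, (0, 0, 0))
        b = icosphere_surface(3.0, (0, 0, 4.0), cell_id=2)
        b.mesh = trimesh.Trimesh(
            vertices=b.mesh.vertices, faces=b.mesh.faces[:-10], process=False
        )
        with pytest.raises(ValueError, match="closed"):
            contact_patch(a, b)


class TestCoverage2D:
    def _disk(self, shape, center, r, pixel):
        yy, xx = np.meshgrid(
            (np.arange(shape[0]) + 0.5) * pixel[0],
            (np.arange(shape[1]) + 0.5) * pixel[1],
            indexing="ij",
        )
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r

    def test_absent_microglia_gives_zero(self):
        px = (0.2, 0.2)
        neuron = self._disk((100, 100), (10, 10), 4.0, px)
        assert coverage_2d(neuron, np.zeros_like(neuron), px) == 0.0

    def test_surrounding_annulus_gives_one(self):
        px = (0.2, 0.2)
        neuron = self._disk((120, 120), (12, 12), 4.0, px)
        outer = self._disk((120, 120), (12, 12), 6.0, px)
        annulus = outer & ~self._disk((120, 120), (12, 12), 4.05, px)
        assert coverage_2d(neuron, annulus, px) == pytest.approx(1.0, abs=0.01)

    def test_half_moon_apposition_matches_pixel_oracle(self):
        px = (0.2, 0.2)
        neuron = self._disk((120, 120), (12, 12), 4.0, px)
        moon = self._disk((120, 120), (12, 12), 4.6, px)
        yy = np.arange(120)[:, None] * px[0] + px[0] / 2
        moon = moon & ~neuron & np.broadcast_to(yy < 12.0, moon.shape)
        cov = coverage_2d(neuron, moon, px)
        assert abs(cov - 0.5) < 0.05
        assert abs(cov - pixel_coverage_2d_oracle(neuron, moon, px)) < 0.05

    def test_neuron_absent_raises(self):
        with pytest.raises(ValueError, match="absent"):
            coverage_2d(np.zeros((10, 10), bool), np.ones((10, 10), bool), (0.2, 0.2))

    def test_equatorial_slice_coverage_positive_for_apposed_pair(self):
        cfg = pair_config(seed=79, coverage=0.3)
        vol, _, _ = simulate_volume(cfg)
        n = build_surfaces(vol, "neuron")[0]
        assert coverage_2d_volume(vol, n, 1) >= 0.0


class TestCalibration:
    def test_exact_line_recovers_printed_coefficients(self):
        x = np.array([5.0, 10, 20, 25, 40, 60])
        y = 0.545 * x - 0.355
        model = fit_calibration(x, y)
        assert model.slope == pytest.approx(0.545, abs=1e-9)
        assert model.intercept == pytest.approx(-0.355, abs=1e-9)
        assert model.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_response_gives_zero_slope(self):
        model = fit_calibration([1.0, 2, 3, 4], [7.0, 7, 7, 7])
        assert model.slope == pytest.approx(0.0, abs=1e-12)

    def test_ols_equals_normal_equations(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 60, 10)
        y = 0.5 * x + rng.normal(0, 2, 10)
        model = fit_calibration(x, y)
        A = np.c_[np.ones(10), x]
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.intercept == pytest.approx(beta[0], rel=1e-9)
        assert model.slope == pytest.approx(beta[1], rel=1e-9)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_calibration([3.0, 3, 3], [1.0, 2, 3])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_calibration([1.0, 2], [1.0, 2])

    @pytest.mark.parametrize(
        "slope, intercept, x, expected",
        [
            (0.545, -0.355, 25.0, 13.27),
            (1.0, 0.0, 25.0, 25.0),
            (2.0, 0.0, 10.0, 20.0),
        ],
    )
    def test_threshold_mapping(self, slope, intercept, x, expected):
        model = CalibrationModel(slope=slope, intercept=intercept, r2=1.0, n_cells=3)
        assert map_threshold(model, x) == expected


class TestClassifyAssociation:
    def test_three_of_ten_is_thirty_percent(self):
        df = pd.DataFrame(
            {
                "coverage_3d": [0.2] * 3 + [0.05] * 7,
                "region": ["M1"] * 10,
                "animal_id": [1] * 10,
            }
        )
        _, summary = classify_association(df, by=("region", "animal_id"))
        assert summary["percent_extensive"].iloc[0] == pytest.approx(30.0)

    def test_threshold_boundary_is_inclusive(self):
        df = pd.DataFrame({"coverage_3d": [0.1327, 0.13269, 0.1328]})
        out = classify_association(df)
        assert out["extensive_3d"].tolist() == [True, False, True]

    def test_empty_group_cell_is_missing_not_zero(self):
        df = pd.DataFrame(
            {"coverage_3d": [0.2, 0.05], "region": ["M1", "M1"], "animal_id": [1, 1]}
        )
        _, summary = classify_association(df, by=("region", "animal_id"))
        assert len(summary) == 1  # no fabricated (region, animal) rows

    def test_recovered_association_fraction_in_binomial_band(self):
        from perisoma.simulate import simulate_cohort
        from perisoma.stats import proportion_summary

        df = simulate_cohort(n_animals=5, pairs_per_animal=100, p_assoc=0.3, seed=14)
        flagged = classify_association(df)
        _, summary = proportion_summary(flagged, "extensive_3d")
        assert 25.0 <= summary["mean_percent"].iloc[0] <= 35.0


class TestCalibrationRoundTrip:
    def test_mapped_threshold_reproduces_2d_classification(self):
        """Simulate a bimodal cohort (apposed vs lightly-touching microglia,
        as in tissue), calibrate 2D->3D, and check the mapped 3D threshold
        reproduces the 2D classification (>= 90 % concordance)."""
        rows = []
        rng = np.random.default_rng(3)
        for i in range(20):
            if i % 2:
                cov = float(np.clip(rng.normal(0.25, 0.05), 0.15, 0.45))
            else:
                cov = float(np.clip(rng.normal(0.05, 0.02), 0.02, 0.10))
            cfg = pair_config(seed=500 + i, coverage=cov)
            vol, _, _ = simulate_volume(cfg)
            n = build_surfaces(vol, "neuron")[0]
            m = build_surfaces(vol, "microglia")[0]
            _, cov3 = contact_patch(n, m)
            # best-plane 2D coverage: the experimenter picks the slice that
            # shows the apposition, not a random equator
            cov2 = coverage_2d_volume(vol, n, 1, mode="max")
            rows.append((cov2 * 100, cov3 * 100))
        df = pd.DataFrame(rows, columns=["cov2", "cov3"])
        model = fit_calibration(df.cov2, df.cov3)
        t3 = map_threshold(model, 25.0)
        call_2d = df.cov2 > 25.0
        call_3d = df.cov3 >= t3
        assert (call_2d == call_3d).mean() >= 0.9
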