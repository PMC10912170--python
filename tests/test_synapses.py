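"""Punctum detection, signed-distance classification and per-pair tallies."""

import numpy as np
import pandas as pd
import pytest

from perisoma.simulate import _stamp_gaussians, simulate_volume
from perisoma.surfaces import build_surfaces
from perisoma.synapses import classify_spots, detect_spots, tally_pair

from conftest import icosphere_surface, pair_config

VOXEL = (0.5, 0.2, 0.2)
SIGMA_UM = np.array([1.0, 0.5, 0.5]) / 2.355


def render(centers, shape=(40, 100, 100), noise=0.02, seed=0):
    img = np.zeros(shape, np.float32)
    _stamp_gaussians(img, np.asarray(centers, float).reshape(-1, 3), SIGMA_UM, np.asarray(VOXEL))
    img += np.random.default_rng(seed).normal(0, noise, shape).astype(np.float32)
    return img


class TestDetectSpots:
    def test_single_punctum_localised_within_150_nm(self):
        truth = np.array([10.3, 9.7, 10.2])
        spots = detect_spots(render([truth]), VOXEL)
        assert len(spots) == 1
        got = spots[["z_um", "y_um", "x_um"]].to_numpy()[0]
        assert np.linalg.norm(got - truth) <= 0.15

    def test_two_puncta_two_microns_apart_resolved(self):
        centers = [(10, 10, 9), (10, 10, 11)]
        spots = detect_spots(render(centers), VOXEL)
        assert len(spots) == 2

    def test_blank_volume_gives_no_spots(self):
        assert len(detect_spots(np.zeros((20, 40, 40), np.float32), VOXEL)) == 0

    def test_recovers_simulated_puncta_count(self):
        cfg = pair_config(seed=41, coverage=0.25, engulf_rate=0.0)
        _, intensities, truth = simulate_volume(cfg)
        spots = detect_spots(intensities["puncta"], VOXEL)
        n_true = len(truth.puncta)
        assert abs(len(spots) - n_true) <= max(2, 0.1 * n_true)


class TestClassifySpots:
    def setup_method(self):
        self.neuron = icosphere_surface(4.0, (0, 0, 0), cell_id=1)
        self.microglia = icosphere_surface(3.0, (0, 0, 8.0), cell_id=1,
                                           cell_class="microglia_soma")

    def _classify(self, points):
        df = pd.DataFrame(points, columns=["z_um", "y_um", "x_um"])
        return classify_spots(df, self.neuron, self.microglia)

    def test_spot_inside_band_is_on_neuron(self):
        out = self._classify([(0, 0, -4.3)])  # 0.3 um outside the neuron
        assert out.spot_class.iloc[0] == "on_neuron"

    def test_spot_outside_band_is_other(self):
        out = self._classify([(0, 4.7, 0)])  # 0.7 um outside both
        assert out.spot_class.iloc[0] == "other"

    def test_spot_inside_microglia_is_engulfed(self):
        out = self._classify([(0, 0, 7.0)])  # 1 um deep in the microglia
        assert out.spot_class.iloc[0] == "engulfed"
        assert out.dist_microglia.iloc[0] < 0

    def test_engulfed_matches_label_mask_oracle(self):
        cfg = pair_config(seed=43, coverage=0.25, engulf_rate=4.0)
        vol, _, truth = simulate_volume(cfg)
        n = build_surfaces(vol, "neuron")[0]
        m = build_surfaces(vol, "microglia")[0]
        out = classify_spots(truth.puncta, n, m)
        interior = truth.puncta.host == "microglia_interior"
        # every planted-interior punctum sits in the microglia label voxel
        idx = (truth.puncta.loc[interior, ["z_um", "y_um", "x_um"]].to_numpy()
               / np.asarray(VOXEL)).astype(int)
        assert (vol.labels["microglia"][idx[:, 0], idx[:, 1], idx[:, 2]] > 0).all()
        assert (out.loc[interior.to_numpy(), "spot_class"] == "engulfed").all()

    def test_band_widening_never_loses_on_counts(self):
        cfg = pair_config(seed=44, coverage=0.25)
        vol, _, truth = simulate_volume(cfg)
        n = build_surfaces(vol, "neuron")[0]
        m = build_surfaces(vol, "microglia")[0]
        counts = []
        for band in (0.25, 0.5, 1.0, 2.0):
            out = classify_spots(truth.puncta, n, m, band=band)
            c = out.spot_class.value_counts()
            counts.append(c.get("on_neuron", 0) + c.get("on_microglia", 0))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_open_mesh_rejected(self):
        import trimesh

        broken = icosphere_surface(3.0, (0, 0, 8.0), cell_id=2)
        broken.mesh = trimesh.Trimesh(
            vertices=broken.mesh.vertices, faces=broken.mesh.faces[:-5], process=False
        )
        with pytest.raises(ValueError, match="closed"):
            classify_spots(
                pd.DataFrame([(0, 0, 0)], columns=["z_um", "y_um", "x_um"]),
                self.neuron,
                broken,
            )


class TestTallyPair:
    def test_no_spots_gives_zero_tally(self):
        neuron = icosphere_surface(4.0, (0, 0, 0))
        mg = icosphere_surface(3.0, (0, 0, 9.0), cell_id=1, cell_class="microglia_soma")
        empty = pd.DataFrame(columns=["z_um", "y_um", "x_um"])
        classified = classify_spots(empty, neuron, mg)
        tally = tally_pair(classified, neuron, mg, contact_area=0.0)
        assert (tally.n_on_neuron, tally.n_on_microglia, tally.n_engulfed) == (0, 0, 0)
        assert tally.density_outside_contact == 0.0

    def test_density_arithmetic(self):
        """10 on-neuron spots, none in contact, soma 300 um2, contact 50 um2
        -> 0.04 per um2."""
        neuron = icosphere_surface(4.0, (0, 0, 0))
        neuron.area = 300.0
        mg = icosphere_surface(3.0, (0, 0, 30.0), cell_id=1, cell_class="microglia_soma")
        pts = np.array([(0, 0, -4.2)] * 10)
        classified = classify_spots(pd.DataFrame(pts, columns=["z_um", "y_um", "x_um"]), neuron, mg)
        tally = tally_pair(classified, neuron, mg, contact_area=50.0)
        assert tally.n_on_neuron == 10
        assert tally.density_outside_contact == pytest.approx(0.04)

    def test_full_contact_density_is_missing(self):
        neuron = icosphere_surface(4.0, (0, 0, 0))
        mg = icosphere_surface(3.0, (0, 0, 30.0), cell_id=1, cell_class="microglia_soma")
        empty = classify_spots(pd.DataFrame(columns=["z_um", "y_um", "x_um"]), neuron, mg)
        tally = tally_pair(empty, neuron, mg, contact_area=neuron.area)
        assert np.isnan(tally.density_outside_contact)

    def test_relocate_pair_total_matches_planted_draw(self):
        """Conservation through the full pipeline: pair total equals the
        pre-displacement Poisson draw in relocate mode."""
        cfg = pair_config(seed=45, coverage=0.3, engulf_rate=0.0)
        vol, _, truth = simulate_volume(cfg)
        n = build_surfaces(vol, "neuron")[0]
        m = build_surfaces(vol, "microglia")[0]
        classified = classify_spots(truth.puncta, n, m)
        from perisoma.association import contact_patch

        area, _ = contact_patch(n, m)
        tally = tally_pair(classified, n, m, contact_area=area)
        row = truth.pairs.iloc[0]
        planted_total = row.puncta_on_neuron + row.puncta_relocated
        assert tally.n_pair_total == planted_total
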