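"""Ground-truth consistency of the tissue, trajectory and signal simulators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from perisoma._geometry import Ellipsoid
from perisoma.simulate import (
    TissueConfig,
    simulate_calcium,
    simulate_cohort,
    simulate_coculture_tracks,
    simulate_lfp,
    simulate_volume,
)

from conftest import pair_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"p_assoc": 1.5},
            {"coverage_assoc": 0.02, "coverage_nonassoc": 0.05},
            {"puncta_density": 0.0},
            {"displacement_mode": "vanish"},
            {"snr": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, overrides):
        with pytest.raises(ValueError):
            TissueConfig(**overrides).validate()

    def test_volume_too_small_for_soma(self):
        cfg = TissueConfig(volume_shape=(10, 30, 30))
        with pytest.raises(ValueError, match="truncation"):
            cfg.validate()


class TestSimulateVolume:
    def test_no_association_means_no_relocation(self):
        cfg = pair_config(seed=11, coverage=0.25, p_assoc=0.0, coverage_nonassoc=0.0)
        _, _, truth = simulate_volume(cfg)
        assert not truth.pairs["associated"].any()
        assert truth.pairs["puncta_relocated"].sum() == 0
        assert (truth.puncta["host"] != "microglia_surface").all()

    def test_fixed_seed_is_bit_identical(self):
        cfg1, cfg2 = pair_config(seed=21), pair_config(seed=21)
        vol1, inten1, truth1 = simulate_volume(cfg1)
        vol2, inten2, truth2 = simulate_volume(cfg2)
        for role in vol1.labels:
            np.testing.assert_array_equal(vol1.labels[role], vol2.labels[role])
        np.testing.assert_array_equal(inten1["puncta"], inten2["puncta"])
        pd.testing.assert_frame_equal(truth1.pairs, truth2.pairs)
        pd.testing.assert_frame_equal(truth1.puncta, truth2.puncta)

    def test_infeasible_coverage_raises(self):
        cfg = pair_config(
            seed=5, coverage=0.6, microglia_radius_um=(2.5, 0.01), volume_shape=(56, 140, 140)
        )
        with pytest.raises(RuntimeError, match="coverage"):
            simulate_volume(cfg)

    def test_labels_disjoint_and_positive(self, demo_specimen):
        _, vol, _, _ = demo_specimen
        overlap = (vol.labels["neuron"] > 0) & (vol.labels["microglia"] > 0)
        assert not overlap.any()

    def test_puncta_lie_on_their_host_surfaces(self, demo_specimen):
        """Surface-host puncta within 0.25 um of the surface; engulfed strictly interior."""
        _, _, _, truth = demo_specimen
        cells = truth.cells.set_index(["cell_class", "cell_id"])

        def ellipsoid(klass, cid):
            row = cells.loc[(klass, cid)]
            rot = np.array([[row[f"rot_{a}{b}"] for b in range(3)] for a in range(3)])
            return Ellipsoid(
                np.array([row.z_um, row.y_um, row.x_um]),
                np.array([row.radius_z_um, row.radius_y_um, row.radius_x_um]),
                rot,
            )

        for _, p in truth.puncta.iterrows():
            pt = np.array([[p.z_um, p.y_um, p.x_um]])
            if p.host == "neuron_surface":
                e = ellipsoid("neuron_soma", p.neuron_id)
            else:
                e = ellipsoid("microglia_soma", p.microglia_id)
            s = np.linalg.norm(e.scaled_coords(pt))
            if p.host == "microglia_interior":
                assert s < 1.0
            else:
                assert abs(s - 1.0) * e.radii.max() <= 0.25

    def test_relocate_mode_conserves_puncta(self, demo_specimen):
        """Per pair: on-neuron + relocated = pre-displacement draw, and the
        puncta table matches the per-pair counts exactly."""
        _, _, _, truth = demo_specimen
        by_pair = truth.puncta.groupby(["microglia_id", "host"]).size().unstack(fill_value=0)
        for _, row in truth.pairs.iterrows():
            counts = by_pair.loc[row.microglia_id] if row.microglia_id in by_pair.index else {}
            assert counts.get("neuron_surface", 0) == row.puncta_on_neuron
            assert counts.get("microglia_surface", 0) == row.puncta_relocated
            assert counts.get("microglia_interior", 0) == row.puncta_engulfed

    def test_suppress_mode_deletes_displaced(self):
        cfg = pair_config(seed=31, coverage=0.3, displacement_mode="suppress")
        _, _, truth = simulate_volume(cfg)
        assert (truth.puncta["host"] != "microglia_surface").all()
        row = truth.pairs.iloc[0]
        n_surface = (truth.puncta["host"] == "neuron_surface").sum()
        assert n_surface == row.puncta_on_neuron
        assert row.puncta_relocated > 0  # displaced counted even though deleted


class TestCohort:
    def test_pair_total_independent_of_association(self):
        df = simulate_cohort(n_animals=4, pairs_per_animal=200, seed=3)
        means = df.groupby("associated_true")["n_pair_total"].mean()
        assert abs(means[True] - means[False]) / means.mean() < 0.05

    def test_displaced_fraction_tracks_coverage(self):
        df = simulate_cohort(n_animals=4, pairs_per_animal=200, seed=4)
        assoc = df[df.associated_true]
        frac = assoc.n_on_microglia.sum() / assoc.n_pre.sum()
        assert abs(frac - assoc.coverage_3d.mean()) < 0.02

    def test_suppress_mode_zeroes_on_microglia(self):
        df = simulate_cohort(displacement_mode="suppress", seed=5)
        assert (df.n_on_microglia == 0).all()


class TestCoculture:
    def test_unbiased_walk_has_zero_mean_radial_drift(self):
        tracks, geom = simulate_coculture_tracks(
            n_microglia=300, drift=0.0, speed_gain=0.0, duration=30, dt=1.0, seed=8
        )
        r0 = tracks.groupby("microglia_id").first()
        r1 = tracks.groupby("microglia_id").last()
        d0 = np.hypot(r0.x_um, r0.y_um)
        d1 = np.hypot(r1.x_um, r1.y_um)
        # mean signed radial displacement ~ 0 (reflection at soma adds tiny +bias)
        assert abs((d1 - d0).mean()) < 1.0

    def test_positive_drift_approaches_in_expectation(self):
        tracks, geom = simulate_coculture_tracks(
            n_microglia=250, drift=0.5, speed_gain=1.0, duration=30, dt=1.0, seed=9
        )
        r0 = tracks.groupby("microglia_id").first()
        r1 = tracks.groupby("microglia_id").last()
        d0 = np.hypot(r0.x_um, r0.y_um)
        d1 = np.hypot(r1.x_um, r1.y_um)
        assert (d1 - d0).mean() < -5.0

    def test_single_interval_gives_two_frames(self):
        tracks, _ = simulate_coculture_tracks(n_microglia=3, duration=10.0, dt=10.0, seed=1)
        assert (tracks.groupby("microglia_id").size() == 2).all()

    def test_invalid_sampling_rejected(self):
        with pytest.raises(ValueError):
            simulate_coculture_tracks(dt=0.0)
        with pytest.raises(ValueError):
            simulate_coculture_tracks(duration=1.0, dt=2.0)


class TestCalcium:
    def test_silent_noiseless_trace_is_constant(self):
        trace, events = simulate_calcium(rate=0.0, noise_sd=0.0, seed=2)
        assert len(events) == 0
        np.testing.assert_allclose(trace, 1.0)

    def test_four_minutes_at_imaging_rate_gives_1800_frames(self):
        trace, _ = simulate_calcium(fs=7.5, duration=240.0, seed=2)
        assert len(trace) == 1800

    def test_planted_event_count_within_poisson_band(self):
        lam = 3.0 * 240.0 / 60.0  # 12 expected
        _, events = simulate_calcium(rate=3.0, duration=240.0, seed=12)
        lo, hi = sps.poisson.ppf([0.005, 0.995], lam)
        assert lo <= len(events) <= hi


class TestLfp:
    def test_fixed_seed_reproducible(self):
        a = simulate_lfp(duration=10, seed=4)
        b = simulate_lfp(duration=10, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="fs/2"):
            simulate_lfp(fs=150.0, gamma_band=(30, 100))

    def test_gamma_injection_is_additive_on_same_background(self):
        base = simulate_lfp(duration=20, gamma_power=0.0, seed=6)
        plus = simulate_lfp(duration=20, gamma_power=50.0, seed=6)
        inj = plus - base
        assert abs(np.var(inj) - 50.0) / 50.0 < 0.01
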