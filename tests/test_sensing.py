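"""Sensing-model tests: partition geometry, visibility signatures, streams."""

import numpy as np
import pytest

from pirwatch.sensing import (
    ACTIVITIES,
    ActivityScript,
    ConfigurationError,
    ImpulseResponse,
    PartitionConfig,
    ThermalSource,
    build_partition,
    cell_signals,
    generate_dataset,
    quantize,
    simulate_stream,
)


class TestPartition:
    def test_default_counts(self, default_partition):
        part, v = default_partition
        assert part.n_cells == 17
        assert v.shape == (7, 17)

    def test_visibility_signatures_match_enumeration(self, default_partition):
        """Each cell's column must equal the signature derived from geometry:
        one fan bit for its sector, ring bits for every ring that covers its
        outer radius; the central cell sees no fan but every ring."""
        cfg = PartitionConfig()
        part, v = default_partition
        expected = np.zeros_like(v)
        expected[4:, 0] = 1  # central disk: all rings, no fan
        for s in range(4):
            for b in range(4):
                col = 1 + s * 4 + b
                expected[s, col] = 1
                hi = part.band_edges[b + 1]
                for k, ring in enumerate(cfg.ring_radii):
                    if hi <= ring:
                        expected[4 + k, col] = 1
        np.testing.assert_array_equal(v, expected)
        assert len({tuple(col) for col in v.T}) == 17
        assert not np.any((v == 0).all(axis=0))

    def test_sectors_only_partition_is_identity(self):
        cfg = PartitionConfig(ring_radii=(), center_radius=0.0)
        part, v = build_partition(cfg)
        assert part.n_cells == 4
        np.testing.assert_array_equal(v, np.eye(4, dtype=v.dtype))

    def test_partition_is_exact_on_fine_grid(self, default_partition):
        """Every in-FOV point belongs to exactly one cell (rasterized check)."""
        part, _ = default_partition
        g = np.linspace(-3.2, 3.2, 161)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        idx = part.cell_index(pts)
        r = np.hypot(pts[:, 0], pts[:, 1])
        inside = r <= 3.0
        assert np.all(idx[inside] >= 0)
        assert np.all(idx[~inside] == -1)
        assert set(np.unique(idx[inside])) == set(range(17))

    @pytest.mark.parametrize("kwargs", [
        {"ring_radii": (1.6, 2.4, 0.8)},          # not decreasing
        {"ring_radii": (2.4, 1.6), "center_radius": 1.7},
        {"n_fan_masks": 0},
        {"sampling_rate": 0.0},
        {"ring_radii": (3.5, 1.0)},               # exceeds FOV
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            PartitionConfig(**kwargs)


class TestCellSignals:
    def test_contained_footprint_hits_single_cell(self, default_partition):
        part, _ = default_partition
        # deep inside sector 0, band 3: r ~ 2.7, theta ~ pi/4
        pos = 2.7 * np.array([np.cos(np.pi / 4), np.sin(np.pi / 4)])
        src = ThermalSource(positions=np.tile(pos, (5, 1)), intensity=np.full(5, 2.0),
                            extent_radius=0.05)
        s = cell_signals(src, part)
        nz = np.nonzero(s[:, 0])[0]
        assert list(nz) == [1 + 0 * 4 + 3]
        assert s[nz[0], 0] == pytest.approx(2.0)

    def test_symmetric_straddle_splits_evenly(self, default_partition):
        part, _ = default_partition
        # footprint centered on the sector boundary along +y (pi/2)
        src = ThermalSource(positions=np.array([[0.0, 1.2]]), intensity=[1.0],
                            extent_radius=0.2)
        s = cell_signals(src, part)[:, 0]
        nz = np.nonzero(s)[0]
        assert len(nz) == 2
        assert s[nz[0]] == pytest.approx(s[nz[1]], abs=1e-12)

    def test_conservation_along_random_trajectory(self, default_partition, rng):
        part, _ = default_partition
        pos = rng.uniform(-3.5, 3.5, (200, 2))
        src = ThermalSource(positions=pos, intensity=np.ones(200), extent_radius=0.25)
        frac = cell_signals(src, part).sum(axis=0)
        assert np.all(frac <= 1 + 1e-9)
        fully_inside = np.hypot(pos[:, 0], pos[:, 1]) <= 3.0 - 0.25
        assert np.allclose(frac[fully_inside], 1.0)
        fully_outside = np.hypot(pos[:, 0], pos[:, 1]) >= 3.0 + 0.25
        assert np.allclose(frac[fully_outside], 0.0)


class TestImpulseResponse:
    def test_zero_dc_response(self):
        h = ImpulseResponse()
        y = h.apply(np.full(500, 3.7), 25.0)
        assert np.abs(y).max() < 1e-12  # steady-state init: constant in, zero out

    def test_peak_gain_normalized(self):
        import scipy.signal as sig
        h = ImpulseResponse(gain=1.0)
        sos, scale = h.sos(25.0)
        _, resp = sig.sosfreqz(sos, worN=4096, fs=25.0)
        assert np.max(np.abs(resp)) * scale == pytest.approx(1.0, rel=1e-9)


class TestSimulateStream:
    def test_stationary_source_reads_zero(self, default_partition):
        part, v = default_partition
        script = ActivityScript(activity="walking", duration=2.0,
                                start=(1.0, 0.5), speed=0.0)
        st = simulate_stream(script, part, v, noise_sd=0.0, seed=0)
        assert np.abs(st.values).max() == 0

    def test_walking_crosses_sectors(self, default_partition):
        """A path through two sectors puts energy on both fan channels and
        leaves untouched sectors at the noise floor."""
        part, v = default_partition
        # walk along +x at y=0.7: crosses sector 1 ([90,180)) then sector 0
        script = ActivityScript(activity="walking", duration=5.0,
                                start=(-2.5, 0.7), heading=0.0, speed=1.0)
        st = simulate_stream(script, part, v, noise_sd=0.0, seed=0)
        energy = (st.values.astype(float) ** 2).sum(axis=1)
        assert energy[0] > 0 and energy[1] > 0       # visited fan sectors
        assert energy[2] == 0 and energy[3] == 0     # untouched fan sectors

    def test_determinism(self, default_partition):
        part, v = default_partition
        script = ActivityScript(activity="jogging", duration=2.0,
                                start=(-3.0, 0.0), speed=2.0, seed=9)
        a = simulate_stream(script, part, v, noise_sd=0.05, seed=9)
        b = simulate_stream(script, part, v, noise_sd=0.05, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            ActivityScript(activity="walking", duration=0.0)

    def test_quantize_range_and_rounding(self):
        q = quantize(np.array([-5.0, 0.0, 5.0]), full_scale=1.0, bits=8)
        assert q.tolist() == [-127, 0, 127]
        # half-to-even at the code midpoint: 0.5/127 full-scale units
        q2 = quantize(np.array([0.5, 1.5, 2.5]) / 127, full_scale=1.0, bits=8)
        assert q2.tolist() == [0, 2, 2]


class TestGenerateDataset:
    def test_default_shape_counts(self):
        streams = generate_dataset(n_subjects=2, reps_per_activity=3, seed=0)
        assert len(streams) == 2 * 5 * 3
        falls = [s for s in streams if s.metadata["activity"] == "falling"]
        assert len(falls) == 6

    def test_single_stream(self):
        streams = generate_dataset(n_subjects=1, activities=("walking",),
                                   reps_per_activity=1, seed=0)
        assert len(streams) == 1

    def test_seed_changes_data_not_counts(self):
        a = generate_dataset(n_subjects=1, reps_per_activity=2, seed=1)
        b = generate_dataset(n_subjects=1, reps_per_activity=2, seed=2)
        assert len(a) == len(b)
        assert any(x.values.shape != y.values.shape or not np.array_equal(x.values, y.values)
                   for x, y in zip(a, b))

    def test_identical_seed_identical_bytes(self):
        a = generate_dataset(n_subjects=1, reps_per_activity=2, seed=3)
        b = generate_dataset(n_subjects=1, reps_per_activity=2, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_unknown_activity_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dataset(activities=("moonwalking",))
        assert set(ACTIVITIES) == {"falling", "sitting_down", "standing_up",
                                   "walking", "jogging"}
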