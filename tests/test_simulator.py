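"""Generative-model checks: Poisson statistics, photophysics, determinism."""

import numpy as np
import pytest

from simpull.simulator import (ChannelModel, SimulationConfig, field_shape_for_area,
                               simulate_field, simulate_trace)


def test_default_geometry_matches_imaging_area_convention():
    cfg = SimulationConfig()
    # one field of view = one 5000 um^2 imaging area at 150 nm/px,
    # so the 2-px colocalization radius is ~300 nm (diffraction limited)
    assert cfg.pixel_size_nm == 150.0
    assert abs(cfg.area_um2 - 5000.0) / 5000.0 < 0.002
    h, w = field_shape_for_area(5000.0, 150.0)
    assert (h, w) == (cfg.field_height_px, cfg.field_width_px)


def test_empty_field_is_pure_background():
    cfg = SimulationConfig(field_height_px=64, field_width_px=64, n_frames=5,
                           surface_density=0.0, nonspecific_density=0.0)
    stacks, truth = simulate_field(cfg, rng=0)
    assert len(truth.molecules) == 0
    frames = stacks["A"].frames
    assert frames.min() >= 0
    assert abs(frames.mean() - cfg.background_level) < 0.5


def test_molecule_count_is_poisson_with_expected_mean():
    # density chosen for expected count 100; Monte-Carlo mean over 200 seeds
    area = 32 * 32 * 0.15 ** 2
    cfg = SimulationConfig(field_height_px=32, field_width_px=32, n_frames=1,
                           surface_density=100.0 / area,
                           background_level=0.0, read_noise_sd=0.0)
    counts = np.array([len(simulate_field(cfg, rng=seed)[1].channel_entries("A"))
                       for seed in range(200)])
    sem = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - 100.0) < 2 * sem


def test_shot_noise_variance_matches_mean():
    # Poisson property: per-pixel variance ~ mean on constant background
    cfg = SimulationConfig(field_height_px=64, field_width_px=64, n_frames=10,
                           surface_density=0.0, background_level=50.0,
                           read_noise_sd=0.0)
    stacks, _ = simulate_field(cfg, rng=3)
    vals = stacks["A"].frames.ravel()  # 40960 samples of Poisson(50)
    assert abs(vals.var(ddof=1) / vals.mean() - 1.0) < 0.05


def test_integrated_monomer_intensity_recovers_unit_intensity():
    # isolated matured monomer: background-subtracted 5-sigma aperture sum
    # over pre-bleach frames = unit_intensity within 3 s.e.m.
    cfg = SimulationConfig(field_height_px=64, field_width_px=64, n_frames=200,
                           background_level=50.0, read_noise_sd=2.0,
                           bleach_prob_per_frame=0.0)
    from conftest import make_truth, render_stack
    truth = make_truth([{"x_px": 31.3, "y_px": 30.7,
                         "bleach_frames": [10 ** 6]}])
    stack = render_stack(cfg, truth, seed=5)
    r = int(np.ceil(5 * cfg.psf_sigma_px))
    yy, xx = np.mgrid[:64, :64]
    ap = np.hypot(yy - 30.7, xx - 31.3) <= r
    bg = np.hypot(yy - 30.7, xx - 31.3) > 3 * r
    per_frame = stack.frames[:, ap].sum(axis=1) - ap.sum() * \
        stack.frames[:, bg].mean(axis=1)
    sem = per_frame.std(ddof=1) / np.sqrt(len(per_frame))
    unit = cfg.channels[0].unit_intensity
    assert abs(per_frame.mean() - unit) < 3 * sem


def test_same_seed_is_bit_identical():
    cfg = SimulationConfig(field_height_px=48, field_width_px=48, n_frames=8,
                           surface_density=0.05)
    s1, t1 = simulate_field(cfg, rng=11)
    s2, t2 = simulate_field(cfg, rng=11)
    assert np.array_equal(s1["A"].frames, s2["A"].frames)
    assert t1.molecules.equals(t2.molecules)


def test_overlap_regime_and_bad_dimensions_rejected():
    with pytest.raises(ValueError, match="overlap"):
        simulate_field(SimulationConfig(field_height_px=16, field_width_px=16,
                                        surface_density=1e5))
    with pytest.raises(ValueError):
        SimulationConfig(field_width_px=0)
    with pytest.raises(ValueError):
        ChannelModel(copy_number_dist={1: 0.5, 2: 0.4})  # doesn't sum to 1


def test_two_channel_truth_shares_co_complex_positions():
    cfg = SimulationConfig(
        field_height_px=128, field_width_px=128, n_frames=2,
        surface_density=0.5, co_complex_fraction=1.0,
        channels=(ChannelModel("A"), ChannelModel("B")))
    _, truth = simulate_field(cfg, rng=2)
    a = truth.channel_entries("A").set_index("molecule_id")
    b = truth.channel_entries("B").set_index("molecule_id")
    assert len(b) == len(a)  # f = 1: every bait complex carries the partner
    joined = a.join(b, lsuffix="_a", rsuffix="_b")
    assert np.allclose(joined["x_px_a"], joined["x_px_b"])
    assert np.allclose(joined["y_px_a"], joined["y_px_b"])
    # matured copies never exceed true copies
    m = truth.molecules
    assert (m["n_fluorescent"] <= m["n_copies"]).all()


def test_noiseless_trace_is_exact_staircase():
    cfg = SimulationConfig(n_frames=200, bleach_prob_per_frame=0.02)
    tr0 = simulate_trace(0, cfg, rng=0)
    assert np.all(tr0.values == 0.0)

    cfg = SimulationConfig(n_frames=2000, bleach_prob_per_frame=0.02)
    tr = simulate_trace(3, cfg, rng=1)
    unit = cfg.channels[0].unit_intensity
    drops = np.diff(tr.values)
    down = drops[drops < 0]
    bleach = tr.meta["bleach_frames"]
    assert len(down) <= 3 and np.all(down % unit == 0)
    assert tr.values[0] == 3 * unit
    # each distinct in-movie bleach frame produces one downward step
    assert len(down) == len(set(bleach[bleach < cfg.n_frames]))
    if (bleach < cfg.n_frames).all():
        assert tr.values[-1] == 0.0


def test_first_bleach_time_of_dimer_matches_minimum_of_geometrics():
    # min of two Geometric(p = 0.02): mean = 1 / (1 - 0.98^2) ~ 25.25
    cfg = SimulationConfig(n_frames=2000, bleach_prob_per_frame=0.02)
    rng = np.random.default_rng(42)
    firsts = [simulate_trace(2, cfg, rng=rng).meta["bleach_frames"][0]
              for _ in range(10_000)]
    firsts = np.asarray(firsts, dtype=float)
    expected = 1.0 / (1.0 - 0.98 ** 2)
    sem = firsts.std(ddof=1) / np.sqrt(firsts.size)
    assert abs(firsts.mean() - expected) < 3 * sem
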