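"""Trace photometry and staircase step counting against exhaustive oracles."""

import itertools

import numpy as np
import pytest

from conftest import make_truth, render_stack
from simpull.detection import Spot
from simpull.photobleaching import (IntensityTrace, RejectionReason,
                                    SpotNearBorderError,
                                    build_step_distribution, count_steps,
                                    extract_trace)
from simpull.simulator import SimulationConfig
from simpull.validation import exact_staircase_fit


def staircase(levels, frames, total):
    """Piecewise-constant trace: levels[i] holds until frames[i]."""
    y = np.full(total, float(levels[-1]))
    bounds = [0] + list(frames) + [total]
    for lv, a, b in zip(levels, bounds[:-1], bounds[1:]):
        y[a:b] = lv
    return y


# ---------------------------------------------------------------- photometry

def test_trace_on_pure_background_is_zero_mean():
    cfg = SimulationConfig(field_height_px=64, field_width_px=64, n_frames=100,
                           surface_density=0.0)
    from simpull.simulator import simulate_field
    stacks, _ = simulate_field(cfg, rng=0)
    tr = extract_trace(stacks["A"], Spot(32.0, 32.0, 1.0, 1.0))
    sem = tr.values.std(ddof=1) / np.sqrt(len(tr))
    assert abs(tr.values.mean()) < 3 * sem


def test_trace_of_noiseless_monomer_steps_at_bleach_frame():
    cfg = SimulationConfig(field_height_px=64, field_width_px=64, n_frames=100,
                           background_level=20.0, read_noise_sd=0.0,
                           shot_noise=False)
    stack = render_stack(cfg, make_truth(
        [{"x_px": 30.0, "y_px": 28.0, "bleach_frames": [50]}]), seed=0)
    tr = extract_trace(stack, Spot(30.0, 28.0, 1.0, 1.0))
    unit = cfg.channels[0].unit_intensity
    # aperture of radius 3 px captures ~99% of a sigma=1 px PSF
    assert np.allclose(tr.values[:50], unit, rtol=0.02)
    assert np.allclose(tr.values[50:], 0.0, atol=1e-3 * unit)


def test_trace_of_matured_dimer_has_twice_unit_intensity():
    cfg = SimulationConfig(field_height_px=64, field_width_px=64, n_frames=120)
    stack = render_stack(cfg, make_truth(
        [{"x_px": 31.5, "y_px": 30.5, "bleach_frames": [10 ** 6] * 2}]), seed=4)
    tr = extract_trace(stack, Spot(31.5, 30.5, 1.0, 1.0))
    unit = cfg.channels[0].unit_intensity
    sem = tr.values.std(ddof=1) / np.sqrt(len(tr))
    assert abs(tr.values.mean() - 2 * unit) < 3 * sem + 0.02 * 2 * unit


def test_trace_near_border_is_rejected_with_reason():
    cfg = SimulationConfig(field_height_px=32, field_width_px=32, n_frames=10,
                           surface_density=0.0)
    from simpull.simulator import simulate_field
    stacks, _ = simulate_field(cfg, rng=1)
    with pytest.raises(SpotNearBorderError):
        extract_trace(stacks["A"], Spot(2.0, 16.0, 1.0, 1.0))


# ------------------------------------------------------------- step counting

def test_constant_trace_rejected_as_no_full_bleach():
    fit = count_steps(IntensityTrace(np.full(100, 50.0)))
    assert fit.n_steps == 0
    assert not fit.accepted
    assert fit.rejection_reason is RejectionReason.NO_FULL_BLEACH


def test_noiseless_two_step_staircase_fit_exactly():
    y = staircase([200.0, 100.0, 0.0], [40, 120], 200)
    fit = count_steps(IntensityTrace(y))
    assert fit.accepted
    assert fit.n_steps == 2
    assert fit.step_frames == [40, 120]
    assert fit.step_sizes == pytest.approx([-100.0, -100.0])
    assert fit.plateau_levels == pytest.approx([200.0, 100.0, 0.0])


def test_upward_step_rejected_as_blinking():
    y = staircase([100.0, 0.0, 100.0, 0.0], [50, 100, 150], 200)
    fit = count_steps(IntensityTrace(y))
    assert not fit.accepted
    assert fit.rejection_reason is RejectionReason.UPWARD_STEP


def test_incomplete_bleach_rejected():
    y = staircase([200.0, 100.0], [100], 200)  # never reaches zero
    rng = np.random.default_rng(0)
    fit = count_steps(IntensityTrace(y + rng.normal(0, 5, 200)))
    assert not fit.accepted
    assert fit.rejection_reason is RejectionReason.NO_FULL_BLEACH


def test_noisy_two_step_recovery_rate_and_oracle_rss():
    # SNR 5 staircase: recover both steps in >= 95% of seeds, frames +/- 2,
    # and greedy RSS within 1% of the exhaustive optimum
    true = staircase([200.0, 100.0, 0.0], [40, 120], 200)
    n_exact = 0
    n_rss_ok = 0
    n_trials = 200
    for seed in range(n_trials):
        rng = np.random.default_rng(1000 + seed)
        y = true + rng.normal(0, 20.0, true.size)
        fit = count_steps(IntensityTrace(y))
        if fit.n_steps == 2 and all(abs(f - t) <= 2 for f, t
                                    in zip(fit.step_frames, [40, 120])):
            n_exact += 1
        k = fit.n_steps
        rss_opt, _ = exact_staircase_fit(y, k, min_dwell=2)
        if fit.rss <= 1.01 * rss_opt + 1e-9:
            n_rss_ok += 1
    assert n_exact / n_trials >= 0.95
    assert n_rss_ok / n_trials >= 0.99


def test_exact_staircase_fit_matches_brute_force_enumeration():
    # the DP oracle itself, verified against full enumeration on a tiny trace
    rng = np.random.default_rng(5)
    y = staircase([30.0, 15.0, 0.0], [4, 9], 14) + rng.normal(0, 2.0, 14)

    def rss_for(cps):
        bounds = [0] + list(cps) + [len(y)]
        return sum(((y[a:b] - y[a:b].mean()) ** 2).sum()
                   for a, b in zip(bounds[:-1], bounds[1:]))

    for k in (1, 2, 3):
        brute = min(rss_for(c) for c in itertools.combinations(range(1, 14), k))
        dp_rss, dp_cps = exact_staircase_fit(y, k, min_dwell=1)
        assert dp_rss == pytest.approx(brute, rel=1e-9)
        assert dp_rss == pytest.approx(rss_for(dp_cps), rel=1e-9)


def test_conservation_and_distribution_construction():
    fits = []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        n = rng.integers(0, 3)
        frames = sorted(rng.choice(np.arange(20, 180), n, replace=False))
        levels = [100.0 * (n - i) for i in range(n + 1)]
        y = staircase(levels, frames, 200) + rng.normal(0, 10.0, 200)
        fits.append(count_steps(IntensityTrace(y)))
    dist = build_step_distribution(fits)
    assert dist.total_accepted + dist.total_rejected == len(fits)
    assert sum(dist.counts.values()) == dist.total_accepted


def test_distribution_of_pure_one_step_fits():
    y = staircase([100.0, 0.0], [60], 150)
    fits = [count_steps(IntensityTrace(
        y + np.random.default_rng(s).normal(0, 10, 150))) for s in range(10)]
    dist = build_step_distribution([f for f in fits if f.accepted])
    assert dist.counts == {1: dist.total_accepted}
    assert dist.fraction(1) == 1.0


def test_simulated_monomers_fall_in_one_step_bin():
    # 200 matured monomer traces at SNR 5: >= 90% of accepted in the 1-step bin
    from simpull.simulator import simulate_trace
    cfg = SimulationConfig(n_frames=300, bleach_prob_per_frame=0.01)
    unit = cfg.channels[0].unit_intensity
    rng = np.random.default_rng(2)
    fits = []
    for _ in range(200):
        tr = simulate_trace(1, cfg, rng=rng, noise_sd=unit / 5.0)
        fits.append(count_steps(IntensityTrace(tr.values)))
    dist = build_step_distribution(fits)
    assert dist.total_accepted > 100
    assert dist.fraction(1) >= 0.90
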