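"""Spot detection, per-imaging-area quantification and specificity checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_truth, render_stack
from simpull.detection import (Spot, compare_to_control, detect_spots,
                               normalize_by_dilution, quantify_fields)
from simpull.simulator import SimulationConfig, simulate_field
from simpull.validation import brute_force_match

NEVER = [10 ** 6]  # bleach frame far beyond any movie


def test_single_noiseless_monomer_localized_to_half_pixel():
    cfg = SimulationConfig(field_height_px=96, field_width_px=96, n_frames=12,
                           background_level=0.0, read_noise_sd=0.0,
                           shot_noise=False)
    stack = render_stack(cfg, make_truth(
        [{"x_px": 40.0, "y_px": 60.0, "bleach_frames": NEVER}]), seed=0)
    spots = detect_spots(stack, projection_frames=12)
    assert len(spots) == 1
    assert abs(spots[0].x_px - 40.0) < 0.5
    assert abs(spots[0].y_px - 60.0) < 0.5
    assert spots[0].intensity > 0


def test_pure_background_yields_at_most_one_false_spot_per_field():
    cfg = SimulationConfig(surface_density=0.0, n_frames=10)
    false_counts = []
    for seed in range(3):
        stacks, _ = simulate_field(cfg, rng=seed)
        false_counts.append(len(detect_spots(stacks["A"], threshold_factor=5.0)))
    assert np.mean(false_counts) <= 1.0


def test_recall_and_precision_on_well_separated_molecules():
    # 100 matured monomers on a 5-px jittered grid, SNR >> 5
    cfg = SimulationConfig(n_frames=10, bleach_prob_per_frame=0.0)
    rng = np.random.default_rng(7)
    grid = np.linspace(15, 455, 10)
    xs, ys = np.meshgrid(grid, grid)
    xs = xs.ravel() + rng.uniform(-2, 2, 100)
    ys = ys.ravel() + rng.uniform(-2, 2, 100)
    truth = make_truth([{"x_px": x, "y_px": y, "bleach_frames": NEVER}
                        for x, y in zip(xs, ys)])
    stack = render_stack(cfg, truth, seed=8)
    spots = detect_spots(stack)
    found = np.array([[s.x_px, s.y_px] for s in spots])
    matches = brute_force_match(np.c_[xs, ys], found, radius=2.0)
    recall = len(matches) / 100
    precision = len(matches) / len(found)
    assert recall >= 0.98
    assert precision >= 0.98


def test_detection_is_translation_equivariant():
    cfg = SimulationConfig(field_height_px=128, field_width_px=128, n_frames=8,
                           bleach_prob_per_frame=0.0)
    truth = make_truth([{"x_px": x, "y_px": y, "bleach_frames": NEVER}
                        for x, y in [(30.2, 40.7), (80.5, 25.3), (60.0, 100.0)]])
    stack = render_stack(cfg, truth, seed=1)
    shifted = stack.__class__(np.roll(stack.frames, (7, -5), axis=(1, 2)),
                              channel="A", pixel_size_nm=150.0)
    s0 = sorted(detect_spots(stack, projection_frames=8),
                key=lambda s: (s.y_px, s.x_px))
    s1 = sorted(detect_spots(shifted, projection_frames=8),
                key=lambda s: (s.y_px, s.x_px))
    assert len(s0) == len(s1) == 3
    for a, b in zip(s0, s1):
        assert abs((a.y_px + 7) - b.y_px) < 0.05
        assert abs((a.x_px - 5) - b.x_px) < 0.05


def test_detect_rejects_empty_and_short_stacks():
    from simpull.simulator import ImageStack
    with pytest.raises(ValueError):
        detect_spots(ImageStack(np.zeros((2, 32, 32)), "A", 150.0),
                     projection_frames=10)


@pytest.mark.parametrize("counts, mean, sd", [
    ([5, 5, 5], 5.0, 0.0),
    ([4, 6], 5.0, np.sqrt(2.0)),
])
def test_quantify_fields_closed_form(counts, mean, sd):
    fields = [[Spot(1.0, 1.0, 10.0, 5.0)] * c for c in counts]
    q = quantify_fields(fields, field_area_um2=5000.0)
    assert q.mean == pytest.approx(mean)
    assert q.sd == pytest.approx(sd)
    assert q.n_areas == len(counts)


def test_quantify_rescales_to_5000_um2():
    q = quantify_fields([[Spot(1.0, 1.0, 10.0, 5.0)] * 10],
                        field_area_um2=2500.0)
    assert q.counts[0] == pytest.approx(20.0)


def test_field_counts_recover_poisson_density():
    # 20 simulated imaging areas at expected 80 visible molecules
    cfg = SimulationConfig(n_frames=10, bleach_prob_per_frame=0.0)
    density = (80.0 / cfg.channels[0].maturation_prob) / cfg.area_um2
    cfg = SimulationConfig(n_frames=10, bleach_prob_per_frame=0.0,
                           surface_density=density)
    fields = []
    for seed in range(20):
        stacks, _ = simulate_field(cfg, rng=100 + seed)
        fields.append(detect_spots(stacks["A"]))
    q = quantify_fields(fields, field_area_um2=cfg.area_um2)
    assert abs(q.mean - 80.0) < 3 * q.sem


def test_specificity_report():
    q_hi = quantify_fields([[Spot(1, 1, 10, 5)] * 100], field_area_um2=5000.0)
    q_lo = quantify_fields([[Spot(1, 1, 10, 5)] * 10], field_area_um2=5000.0)
    rep = compare_to_control(q_hi, q_lo)
    assert rep.ratio == pytest.approx(10.0)
    assert rep.passes_specificity
    rep_eq = compare_to_control(q_lo, q_lo)
    assert rep_eq.ratio == pytest.approx(1.0)
    assert not rep_eq.passes_specificity
    empty = quantify_fields([[]], field_area_um2=5000.0)
    rep0 = compare_to_control(q_hi, empty)
    assert rep0.control_floored and rep0.passes_specificity


@given(factor=st.floats(min_value=1e-3, max_value=1e4,
                        allow_nan=False, allow_infinity=False))
@settings(max_examples=50, deadline=None)
def test_dilution_normalization_scales_linearly(factor):
    q = quantify_fields([[Spot(1, 1, 10, 5)] * 50, [Spot(1, 1, 10, 5)] * 40],
                        field_area_um2=5000.0)
    nq = normalize_by_dilution(q, factor)
    assert nq.mean == pytest.approx(q.mean * factor)
    assert nq.sd == pytest.approx(q.sd * factor)
    if factor == 1.0:
        assert nq == q


def test_dilution_rejects_nonpositive_factor():
    q = quantify_fields([[Spot(1, 1, 10, 5)]], field_area_um2=5000.0)
    with pytest.raises(ValueError):
        normalize_by_dilution(q, 0.0)


def test_dilution_makes_different_dilutions_comparable():
    # same per-volume concentration, 200x vs 800x dilution: after
    # normalization the means agree within 3 s.e.m.
    lysate = 12.8  # surface-equivalent density of the undiluted lysate, /um^2
    quants = []
    for dilution, seeds in ((200.0, range(8)), (800.0, range(8, 16))):
        dcfg = SimulationConfig(n_frames=10, bleach_prob_per_frame=0.0,
                                surface_density=lysate / dilution)
        fields = [detect_spots(simulate_field(dcfg, rng=s)[0]["A"])
                  for s in seeds]
        quants.append(normalize_by_dilution(
            quantify_fields(fields, field_area_um2=dcfg.area_um2), dilution))
    sem = np.hypot(quants[0].sem, quants[1].sem)
    assert abs(quants[0].mean - quants[1].mean) < 3 * sem
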