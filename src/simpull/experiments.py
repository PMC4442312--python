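"""Parameter-recovery experiments on synthetic ground truth.

Each function simulates a SiMPull regime with known generative parameters,
runs the corresponding analysis stage(s), and reports how well the truth is
recovered. These are the package's validation battery: the same experiments
back the acceptance test suite and the ``scripts/acceptance.py`` report.

Problem sizes are chosen to give stable statistics on a single CPU in a few
minutes: 500 traces per step-count condition, 1000 traces per stoichiometry
population, 20 imaging areas per colocalization condition, 100 replicate
field pairs for specificity.
"""

from __future__ import annotations

import numpy as np

from .colocalization import (colocalize, compare_conditions,
                             expected_chance_colocalization)
from .detection import Spot, compare_to_control, detect_spots, quantify_fields
from .photobleaching import count_steps
from .pipeline import run_pipeline
from .simulator import ChannelModel, SimulationConfig, simulate_field, simulate_trace
from .stoichiometry import (co_complex_fraction_correction, infer_stoichiometry,
                            visible_step_pmf)
from .validation import exact_staircase_fit

__all__ = [
    "step_recovery_experiment",
    "stoichiometry_recovery_experiment",
    "colocalization_recovery_experiment",
    "colocalization_attenuation_experiment",
    "chance_colocalization_experiment",
    "counting_linearity_experiment",
    "specificity_experiment",
    "demo_monomer_experiment",
    "demo_dimer_subpopulation_experiment",
    "demo_scaffold_loss_experiment",
]


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------- criterion 1

def step_recovery_experiment(seed: int = 0, n_traces: int = 500,
                             n_frames: int = 300, snr: float = 5.0,
                             oracle_subset: int = 200) -> dict:
    """Step-count recovery on noisy staircases with 1-3 true steps.

    Traces are geometric-bleach staircases at the given step/noise SNR,
    conditioned on complete bleaching within the movie. Recovery is exact
    agreement of the fitted step count with the number of distinct bleach
    frames (simultaneous bleaching of two fluorophores *is* one step).
    The greedy fit's RSS is compared against the exact dynamic-programming
    optimum at the same step count.
    """
    cfg = SimulationConfig(n_frames=n_frames, bleach_prob_per_frame=0.005,
                           channels=(ChannelModel("A", {1: 1.0}, 1.0,
                                                  unit_intensity=100.0),))
    noise_sd = cfg.channels[0].unit_intensity / snr
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    per_condition = {}
    rss_checked = rss_ok = 0
    for n_true in (1, 2, 3):
        n_exact = 0
        produced = 0
        while produced < n_traces:
            tr = simulate_trace(n_true, cfg, rng=rng, noise_sd=noise_sd)
            bleach = tr.meta["bleach_frames"]
            if bleach.size and bleach.max() >= n_frames:
                continue  # incomplete bleaching: not a countable trace
            produced += 1
            truth_steps = len(set(bleach.tolist()))
            fit = count_steps(tr)
            if fit.n_steps == truth_steps:
                n_exact += 1
            if rss_checked < oracle_subset * n_true and fit.n_steps > 0:
                rss_opt, _ = exact_staircase_fit(tr.values, fit.n_steps,
                                                 min_dwell=2)
                rss_checked += 1
                if fit.rss <= 1.01 * rss_opt + 1e-9:
                    rss_ok += 1
        per_condition[n_true] = 100.0 * n_exact / n_traces
    return {
        "recovery_pct_by_steps": per_condition,
        "recovery_pct": float(np.mean(list(per_condition.values()))),
        "rss_within_1pct_of_oracle_pct": 100.0 * rss_ok / rss_checked,
        "n_traces_per_condition": n_traces,
        "n_oracle_checked": rss_checked,
    }


# --------------------------------------------------------------- criterion 2

def stoichiometry_recovery_experiment(seed: int = 0, n_traces: int = 1000,
                                      m: float = 0.75) -> dict:
    """Copy-number recovery from pure populations through the dark fraction.

    Step histograms are drawn from the zero-truncated binomial observation
    model for pure monomer/dimer/trimer populations at maturation ``m`` and
    refit by the ML mixture. Also fits the *expected* dimer histogram, whose
    predicted two-step probability must reproduce the analytic value
    C(2,2) m^2 / (1-(1-m)^2) = 0.6 at m = 0.75.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    weights = {}
    for n_true in (1, 2, 3):
        pmf = visible_step_pmf(n_true, m)
        counts = rng.multinomial(n_traces, pmf)
        hist = {j + 1: int(c) for j, c in enumerate(counts) if c > 0}
        est = infer_stoichiometry(hist, m=m, n_max=4, seed=seed)
        weights[n_true] = est.weights[n_true]

    # analytic cross-check on the noise-free expected dimer histogram
    exact_pmf = visible_step_pmf(2, m)
    exact_hist = {1: int(round(1000 * exact_pmf[0])),
                  2: int(round(1000 * exact_pmf[1]))}
    est2 = infer_stoichiometry(exact_hist, m=m, n_max=4, seed=seed)
    return {
        "weight_on_true_n": weights,
        "dimer_two_step_prob_analytic": float(exact_pmf[1]),
        "dimer_two_step_prob_fitted": est2.predicted[2],
        "n_traces": n_traces,
        "maturation": m,
    }


# --------------------------------------------------------------- criterion 3

def _two_color_config(f: float, m_partner: float = 1.0,
                      n_frames: int = 10) -> SimulationConfig:
    """~100 bait complexes per 5000 um^2 area; the partner is pulled down
    independently as well, so the bait channel is the sparser one."""
    return SimulationConfig(
        n_frames=n_frames,
        bleach_prob_per_frame=0.0,  # negligible bleaching in a 10-frame window
        surface_density=0.02,
        partner_only_density=0.03,
        co_complex_fraction=f,
        channels=(ChannelModel("A", {1: 1.0}, 1.0),
                  ChannelModel("B", {1: 1.0}, m_partner)),
    )


def _measure_coloc(cfg: SimulationConfig, seed: int, n_fields: int):
    fields_a, fields_b = [], []
    for rng in _spawn_rngs(seed, n_fields):
        stacks, _ = simulate_field(cfg, rng=rng)
        fields_a.append(detect_spots(stacks["A"]))
        fields_b.append(detect_spots(stacks["B"]))
    return colocalize(fields_a, fields_b, radius_px=2.0,
                      field_area_px2=float(cfg.field_height_px * cfg.field_width_px))


def colocalization_recovery_experiment(seed: int = 0,
                                       fractions=(0.1, 0.25, 0.5, 0.75),
                                       n_fields: int = 20) -> dict:
    """Measured colocalization percentage vs the true co-complex fraction.

    Besides the raw percentage, reports the chance-corrected estimate of f:
    an unmatched bait molecule still overlaps a partner spot by chance with
    probability c (the Poisson null), so E[measured] ~ 100 f + c (100 - 100 f)
    and the corrected percentage inverts that relation.
    """
    out = {}
    for i, f in enumerate(fractions):
        res = _measure_coloc(_two_color_config(f), seed + 1000 * i, n_fields)
        c = res.expected_chance_percent
        corrected = 100.0 * (res.mean_percent - c) / (100.0 - c)
        out[f] = {"measured_pct": res.mean_percent,
                  "corrected_pct": corrected,
                  "sem_pct": res.sem_percent,
                  "expected_pct": 100.0 * f,
                  "chance_pct": c}
    return {"by_fraction": out, "n_fields": n_fields}


def colocalization_attenuation_experiment(seed: int = 0, f: float = 0.5,
                                          m_partner: float = 0.6,
                                          n_fields: int = 20) -> dict:
    """Dark partner chromophores attenuate the raw percentage to ~100*f*m;
    dividing by the maturation probability restores the true fraction."""
    res = _measure_coloc(_two_color_config(f, m_partner=m_partner),
                         seed, n_fields)
    corr = co_complex_fraction_correction(res.mean_percent / 100.0, m_partner)
    return {
        "true_fraction": f,
        "partner_maturation": m_partner,
        "raw_pct": res.mean_percent,
        "raw_sem_pct": res.sem_percent,
        "expected_attenuated_pct": 100.0 * f * m_partner,
        "corrected_fraction": corr.corrected,
        "corrected_sem": res.sem_percent / (100.0 * m_partner),
        "n_fields": n_fields,
    }


def chance_colocalization_experiment(seed: int = 0, lam_b: float = 0.004,
                                     lam_a: float = 0.002, side_px: int = 200,
                                     radius_px: float = 2.0,
                                     n_fields: int = 20) -> dict:
    """Independent Poisson point fields against the analytic chance level."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])

    def field(lam, channel):
        n = rng.poisson(lam * side_px * side_px)
        return [Spot(float(x), float(y), 1.0, 1.0, channel=channel)
                for x, y in zip(rng.uniform(0, side_px, n),
                                rng.uniform(0, side_px, n))]

    fa = [field(lam_a, "A") for _ in range(n_fields)]
    fb = [field(lam_b, "B") for _ in range(n_fields)]
    res = colocalize(fa, fb, radius_px=radius_px)
    return {
        "measured_pct": res.mean_percent,
        "sem_pct": res.sem_percent,
        "expected_pct": expected_chance_colocalization(lam_b, radius_px),
        "n_fields": n_fields,
    }


# --------------------------------------------------------------- criterion 4

def counting_linearity_experiment(seed: int = 0,
                                  expected_counts=(50, 125, 250, 375, 500),
                                  fields_per_density: int = 3) -> dict:
    """Measured spots per area vs true visible molecules: slope of the
    linear fit over the paper-relevant density range."""
    xs, ys = [], []
    rngs = iter(_spawn_rngs(seed, len(expected_counts) * fields_per_density))
    for count in expected_counts:
        cfg = SimulationConfig(
            n_frames=10,
            bleach_prob_per_frame=0.0,
            surface_density=count / SimulationConfig().area_um2,
            channels=(ChannelModel("A", {1: 1.0}, 1.0),))
        for _ in range(fields_per_density):
            stacks, truth = simulate_field(cfg, rng=next(rngs))
            xs.append(len(truth.visible("A")))
            ys.append(len(detect_spots(stacks["A"])))
    slope, intercept = np.polyfit(xs, ys, 1)
    return {"slope": float(slope), "intercept": float(intercept),
            "n_fields": len(xs),
            "max_expected_count": max(expected_counts)}


def specificity_experiment(seed: int = 0, n_pairs: int = 100,
                           density_ratio: float = 10.0) -> dict:
    """Specific vs control-antibody pull-down: fraction of replicate field
    pairs whose enrichment ratio clears the (default 5x) specificity bar when
    the true specific density is 10x the nonspecific one."""
    nonspecific = 0.002
    sample_cfg = SimulationConfig(
        n_frames=10, surface_density=density_ratio * nonspecific,
        nonspecific_density=nonspecific)
    control_cfg = SimulationConfig(
        n_frames=10, surface_density=0.0, nonspecific_density=nonspecific)
    rngs = _spawn_rngs(seed, 2 * n_pairs)
    n_pass = 0
    for i in range(n_pairs):
        s_stacks, _ = simulate_field(sample_cfg, rng=rngs[2 * i])
        c_stacks, _ = simulate_field(control_cfg, rng=rngs[2 * i + 1])
        q_s = quantify_fields([detect_spots(s_stacks["A"])],
                              field_area_um2=sample_cfg.area_um2)
        q_c = quantify_fields([detect_spots(c_stacks["A"])],
                              field_area_um2=control_cfg.area_um2)
        if compare_to_control(q_s, q_c).passes_specificity:
            n_pass += 1
    return {"pass_rate_pct": 100.0 * n_pass / n_pairs, "n_pairs": n_pairs}


# --------------------------------------------------------------- criterion 5

def demo_monomer_experiment(seed: int = 0) -> dict:
    """The packaged bait:partner 1:1 demo: step distribution should be
    predominantly one-step and the stoichiometry call 'monomer'."""
    from .demo import bait_partner_1to1
    report = run_pipeline(bait_partner_1to1(seed=seed))
    dist = report["step_distribution"]
    total = sum(dist["counts"].values())
    return {
        "one_step_fraction_pct": 100.0 * dist["counts"].get("1", 0) / total,
        "call": report["stoichiometry"]["call"],
        "n_accepted_traces": total,
        "coloc_pct": report["colocalization"]["mean_percent"],
    }


def demo_dimer_subpopulation_experiment(seed: int = 0) -> dict:
    """The 20%-dimer demo: mixed one-/two-step distribution, call
    'monomer + dimer'."""
    from .demo import dimer_subpopulation
    report = run_pipeline(dimer_subpopulation(seed=seed))
    dist = report["step_distribution"]
    total = sum(dist["counts"].values())
    return {
        "one_step_fraction_pct": 100.0 * dist["counts"].get("1", 0) / total,
        "two_step_fraction_pct": 100.0 * dist["counts"].get("2", 0) / total,
        "call": report["stoichiometry"]["call"],
        "n_accepted_traces": total,
    }


def demo_scaffold_loss_experiment(seed: int = 0, n_fields: int = 20) -> dict:
    """Halving the true co-complex fraction (0.4 -> 0.2) between two
    conditions must register as a significant drop (|z| > 3)."""
    from .demo import scaffold_loss_pair
    ctrl_cfg, loss_cfg = scaffold_loss_pair(seed=seed, n_fields=n_fields)
    res_ctrl = _measure_coloc(ctrl_cfg.simulation, ctrl_cfg.seed, n_fields)
    res_loss = _measure_coloc(loss_cfg.simulation, loss_cfg.seed, n_fields)
    comp = compare_conditions(res_ctrl, res_loss)
    return {
        "control_pct": res_ctrl.mean_percent,
        "loss_pct": res_loss.mean_percent,
        "difference_pct": comp.difference,
        "ratio": comp.ratio,
        "z_score": comp.z_score,
        "n_fields": n_fields,
    }
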