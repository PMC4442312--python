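"""Packaged demonstration configurations.

Three ready-made synthetic experiments mirroring the canonical SiMPull
readouts:

* ``bait_partner_1to1`` — a monomeric bait label with a monomeric partner in
  every complex; the bait step distribution is predominantly one-step and
  the stoichiometry call is "monomer".
* ``dimer_subpopulation`` — 20% of complexes carry two labeled copies,
  yielding the mixed one-/two-step pattern read as a 1:1-or-1:2 ratio.
* ``scaffold_loss_pair`` — two two-color conditions whose true co-complex
  fraction is halved (0.4 -> 0.2), the readout for losing a scaffold that
  holds the pair together.
"""

from __future__ import annotations

from .pipeline import ColocParams, RunConfig
from .simulator import ChannelModel, SimulationConfig

__all__ = ["bait_partner_1to1", "dimer_subpopulation", "scaffold_loss_pair",
           "DEMO_NAMES", "demo_config"]


def bait_partner_1to1(seed: int = 0, n_fields: int = 4) -> RunConfig:
    sim = SimulationConfig(
        n_frames=300,
        bleach_prob_per_frame=0.012,
        surface_density=0.016,          # ~80 bait complexes / 5000 um^2
        partner_only_density=0.032,
        co_complex_fraction=1.0,
        channels=(ChannelModel("A", {1: 1.0}, maturation_prob=0.75),
                  ChannelModel("B", {1: 1.0}, maturation_prob=0.75)),
    )
    return RunConfig(simulation=sim, n_fields=n_fields, seed=seed,
                     label="bait-partner-1to1")


def dimer_subpopulation(seed: int = 0, n_fields: int = 4) -> RunConfig:
    sim = SimulationConfig(
        n_frames=300,
        bleach_prob_per_frame=0.012,
        surface_density=0.016,
        channels=(ChannelModel("A", {1: 0.8, 2: 0.2}, maturation_prob=0.75),),
    )
    return RunConfig(simulation=sim, n_fields=n_fields, seed=seed,
                     label="dimer-subpopulation")


def scaffold_loss_pair(seed: int = 0, n_fields: int = 20
                       ) -> tuple[RunConfig, RunConfig]:
    """(control, knock-down-like) configs differing only in the true
    co-complex fraction (0.4 vs 0.2)."""

    def make(f: float, label: str, seed_offset: int) -> RunConfig:
        sim = SimulationConfig(
            n_frames=12,
            surface_density=0.02,       # ~100 bait complexes / field
            partner_only_density=0.04,
            co_complex_fraction=f,
            channels=(ChannelModel("A", {1: 1.0}, maturation_prob=0.75),
                      ChannelModel("B", {1: 1.0}, maturation_prob=0.75)),
        )
        return RunConfig(simulation=sim, n_fields=n_fields,
                         seed=seed + seed_offset, label=label,
                         colocalization=ColocParams(radius_px=2.0))

    return (make(0.4, "scaffold-control", 0),
            make(0.2, "scaffold-loss", 1))


DEMO_NAMES = ("bait_partner_1to1", "dimer_subpopulation")


def demo_config(name: str, seed: int = 0) -> RunConfig:
    try:
        return {"bait_partner_1to1": bait_partner_1to1,
                "dimer_subpopulation": dimer_subpopulation}[name](seed=seed)
    except KeyError:
        raise KeyError(f"unknown demo '{name}'; available: {DEMO_NAMES}") from None
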