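import numpy as np
import pandas as pd
import pytest

from simpull.simulator import GroundTruth, ImageStack, SimulationConfig, _render_channel


def make_truth(entries) -> pd.DataFrame:
    """Hand-built ground-truth table for rendering controlled fields.

    entries: iterable of dicts with x_px, y_px, n_fluorescent, bleach_frames
    (list of ints) and optional channel/n_copies.
    """
    rows = []
    for i, e in enumerate(entries):
        bleach = e.get("bleach_frames", [])
        rows.append({
            "molecule_id": i,
            "channel": e.get("channel", "A"),
            "x_px": e["x_px"], "y_px": e["y_px"],
            "n_copies": e.get("n_copies", max(len(bleach), 1)),
            "n_fluorescent": e.get("n_fluorescent", len(bleach)),
            "bleach_frames": ";".join(str(int(b)) for b in bleach),
            "is_nonspecific": False, "is_co_complex": False,
        })
    return pd.DataFrame(rows, columns=GroundTruth.COLUMNS)


def render_stack(config: SimulationConfig, truth: pd.DataFrame,
                 seed: int = 0, channel: str = "A") -> ImageStack:
    """Render a stack from an explicit truth table (controlled positions)."""
    frames = _render_channel(config, channel, truth,
                             np.random.default_rng(seed))
    return ImageStack(frames=frames, channel=channel,
                      pixel_size_nm=config.pixel_size_nm)


@pytest.fixture
def small_field_config() -> SimulationConfig:
    """A 96x96 px field (~207 um^2): fast to render, same photophysics."""
    return SimulationConfig(field_height_px=96, field_width_px=96,
                            n_frames=40, background_level=50.0,
                            read_noise_sd=2.0)
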