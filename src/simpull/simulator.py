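"""Synthetic TIRF-field generator for single-molecule pull-down (SiMPull) assays.

Emulates surface-immobilized protein complexes imaged by prism-type TIRF:
complexes land on the passivated surface as a spatial Poisson process, each
labeled subunit matures into a fluorescent chromophore with some probability,
each matured fluorophore emits a fixed per-frame intensity spread by a 2-D
Gaussian point-spread function until it photobleaches (geometric, i.e.
memoryless, survival per frame), and the camera records Poisson shot noise
plus additive Gaussian read noise.

Every simulated field carries a :class:`GroundTruth` table so that detection,
step counting, stoichiometry and colocalization can all be validated by
parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import stats
from scipy.special import erf

from .photobleaching import IntensityTrace

__all__ = [
    "ChannelModel",
    "SimulationConfig",
    "ImageStack",
    "GroundTruth",
    "simulate_field",
    "simulate_trace",
    "field_shape_for_area",
]

#: Conversion between the paper's imaging-area unit and pixels.
DEFAULT_IMAGING_AREA_UM2 = 5000.0


def field_shape_for_area(area_um2: float = DEFAULT_IMAGING_AREA_UM2,
                         pixel_size_nm: float = 150.0) -> tuple[int, int]:
    """Near-square (height, width) in pixels covering ``area_um2``.

    At the default 150 nm/px, 5000 um^2 comes out as 471 x 472 px
    (5002 um^2), so one simulated field of view is one imaging area.
    """
    px_area_um2 = (pixel_size_nm / 1000.0) ** 2
    n_px = area_um2 / px_area_um2
    h = int(math.floor(math.sqrt(n_px)))
    w = int(round(n_px / h))
    return h, w


@dataclass(frozen=True)
class ChannelModel:
    """Photophysical model of one labeled subunit / camera channel.

    Parameters
    ----------
    label
        Channel name ("A" = bait-associated label, "B" = partner).
    copy_number_dist
        Discrete distribution over subunit copies per complex,
        ``{n: probability}`` with n >= 1; must sum to 1.
    maturation_prob
        Probability that an expressed fluorescent-protein tag folds into an
        active chromophore. Non-matured tags are dark and cause undercounting.
    unit_intensity
        Photons per frame emitted by one active fluorophore.
    """

    label: str = "A"
    copy_number_dist: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    maturation_prob: float = 0.75
    unit_intensity: float = 300.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maturation_prob <= 1.0:
            raise ValueError("maturation_prob must be in [0, 1]")
        if self.unit_intensity < 0:
            raise ValueError("unit_intensity must be >= 0")
        dist = dict(self.copy_number_dist)
        if not dist or any(n < 1 or int(n) != n for n in dist):
            raise ValueError("copy_number_dist requires integer copies >= 1")
        if any(p < 0 for p in dist.values()):
            raise ValueError("copy_number_dist probabilities must be >= 0")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError("copy_number_dist must sum to 1")
        object.__setattr__(self, "copy_number_dist", dist)

    def draw_copies(self, rng: np.random.Generator, size: int) -> np.ndarray:
        ns = np.array(sorted(self.copy_number_dist), dtype=int)
        ps = np.array([self.copy_number_dist[int(n)] for n in ns])
        return rng.choice(ns, size=size, p=ps / ps.sum())


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic SiMPull field of view.

    Geometry defaults give one field = one 5000 um^2 imaging area at
    150 nm/px (so the 2-px colocalization criterion is ~300 nm, a
    diffraction-limited spot). Densities are per um^2 of surface.

    ``surface_density`` is the density of bait-captured complexes; every such
    complex carries the channel-A label and, with probability
    ``co_complex_fraction``, also the channel-B partner at the same surface
    position. ``partner_only_density`` adds complexes carrying only the
    partner label (prey pulled down independently of the co-complex, which is
    why the bait channel can be the lower-density one on the slide).
    ``nonspecific_density`` adds monomeric single-channel background binders
    per channel (the anti-HA control regime).
    """

    field_height_px: int = 471
    field_width_px: int = 472
    pixel_size_nm: float = 150.0
    n_frames: int = 400
    psf_sigma_px: float = 1.0
    surface_density: float = 0.02
    partner_only_density: float = 0.0
    co_complex_fraction: float = 0.0
    channels: tuple[ChannelModel, ...] = (ChannelModel("A"),)
    bleach_prob_per_frame: float = 0.01
    background_level: float = 50.0
    read_noise_sd: float = 2.0
    channel_offset_px: tuple[float, float] = (0.0, 0.0)
    nonspecific_density: float = 0.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_height_px <= 0 or self.field_width_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("pixel_size_nm", "psf_sigma_px", "surface_density",
                     "partner_only_density", "nonspecific_density",
                     "background_level", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("co_complex_fraction", "bleach_prob_per_frame"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.channels) not in (1, 2):
            raise ValueError("one or two channels supported")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")

    @property
    def area_um2(self) -> float:
        return self.field_height_px * self.field_width_px * (self.pixel_size_nm / 1000.0) ** 2

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.channels)

    def channel(self, label: str) -> ChannelModel:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(label)

    def expected_molecules(self) -> float:
        """Expected total complexes (all sources, all channels)."""
        per_um2 = (self.surface_density + self.partner_only_density
                   + self.nonspecific_density * len(self.channels))
        return per_um2 * self.area_um2


@dataclass
class ImageStack:
    """A time series of 2-D intensity frames for one channel of one field."""

    frames: np.ndarray  # (n_frames, height, width), photons, >= 0
    channel: str
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (frame, row, column)")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("negative photon counts")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def area_um2(self) -> float:
        h, w = self.shape
        return h * w * (self.pixel_size_nm / 1000.0) ** 2

    def save_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(
            str(path), self.frames.astype(np.float32),
            metadata={"channel": self.channel, "pixel_size_nm": self.pixel_size_nm},
        )

    @classmethod
    def from_tiff(cls, path: str | Path, channel: str | None = None,
                  pixel_size_nm: float | None = None) -> "ImageStack":
        with tifffile.TiffFile(str(path)) as tf:
            frames = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if frames.ndim == 2:
            frames = frames[None]
        return cls(
            frames=frames,
            channel=channel or str(meta.get("channel", "A")),
            pixel_size_nm=pixel_size_nm or float(meta.get("pixel_size_nm", 150.0)),
        )


@dataclass
class GroundTruth:
    """Per-molecule truth records for one simulated field.

    ``molecules`` has one row per (molecule, channel) entry:
    molecule_id, channel, x_px, y_px (true surface position, before any
    channel offset), n_copies, n_fluorescent, bleach_frames
    (semicolon-joined first dark frame of each matured fluorophore),
    is_nonspecific, is_co_complex.
    """

    molecules: pd.DataFrame
    n_frames: int

    COLUMNS = ["molecule_id", "channel", "x_px", "y_px", "n_copies",
               "n_fluorescent", "bleach_frames", "is_nonspecific", "is_co_complex"]

    def channel_entries(self, channel: str) -> pd.DataFrame:
        return self.molecules[self.molecules["channel"] == channel]

    def visible(self, channel: str) -> pd.DataFrame:
        """Entries with at least one matured fluorophore (detectable spots)."""
        df = self.channel_entries(channel)
        return df[df["n_fluorescent"] >= 1]

    def bleach_frame_lists(self, channel: str) -> list[np.ndarray]:
        out = []
        for s in self.visible(channel)["bleach_frames"]:
            out.append(np.array([int(x) for x in str(s).split(";") if x], dtype=int))
        return out

    def fraction_unbleached(self, channel: str) -> float:
        """Fraction of matured fluorophores still emitting at movie end."""
        total = alive = 0
        for frames in self.bleach_frame_lists(channel):
            total += frames.size
            alive += int((frames >= self.n_frames).sum())
        return alive / total if total else 0.0

    def to_csv(self, path: str | Path) -> None:
        self.molecules.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, n_frames: int) -> "GroundTruth":
        return cls(pd.read_csv(path), n_frames=n_frames)


def _pixel_integrated_psf(x: float, y: float, sigma: float,
                          x0: int, x1: int, y0: int, y1: int) -> np.ndarray:
    """Fraction of a unit 2-D Gaussian at (x, y) landing in each pixel of
    the window [y0, y1) x [x0, x1). Pixel (r, c) spans [c-0.5, c+0.5) etc.,
    so integer coordinates are pixel centers."""
    s = sigma * math.sqrt(2.0)
    ex = np.arange(x0, x1 + 1) - 0.5
    ey = np.arange(y0, y1 + 1) - 0.5
    fx = 0.5 * np.diff(erf((ex - x) / s))
    fy = 0.5 * np.diff(erf((ey - y) / s))
    return np.outer(fy, fx)


def _draw_bleach_frames(rng: np.random.Generator, n: int, p: float,
                        n_frames: int) -> np.ndarray:
    """First dark frame of each fluorophore; geometric survival per frame.

    A fluorophore with bleach frame b emits during frames 0..b-1.  p == 0
    means photostable: bleach frame beyond the movie."""
    if n == 0:
        return np.zeros(0, dtype=int)
    if p <= 0:
        return np.full(n, 10 * n_frames + 1, dtype=int)
    return rng.geometric(p, size=n).astype(int)


def _sample_molecules(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    area = config.area_um2
    h, w = config.field_height_px, config.field_width_px
    labels = config.channel_labels
    two_channel = len(labels) == 2

    rows: list[dict] = []
    mol_id = 0

    def add_entry(mid: int, channel: ChannelModel, x: float, y: float,
                  n_copies: int, nonspecific: bool, co_complex: bool) -> None:
        n_fluor = int(rng.binomial(n_copies, channel.maturation_prob))
        bleach = _draw_bleach_frames(rng, n_fluor, config.bleach_prob_per_frame,
                                     config.n_frames)
        rows.append({
            "molecule_id": mid, "channel": channel.label,
            "x_px": x, "y_px": y, "n_copies": n_copies,
            "n_fluorescent": n_fluor,
            "bleach_frames": ";".join(str(int(b)) for b in np.sort(bleach)),
            "is_nonspecific": nonspecific, "is_co_complex": co_complex,
        })

    ch_a = config.channels[0]
    ch_b = config.channels[1] if two_channel else None

    # bait-captured complexes (always carry the channel-A label)
    n_bait = rng.poisson(config.surface_density * area)
    xs = rng.uniform(0, w, n_bait)
    ys = rng.uniform(0, h, n_bait)
    copies_a = ch_a.draw_copies(rng, n_bait) if n_bait else np.zeros(0, int)
    has_b = (rng.random(n_bait) < config.co_complex_fraction) if two_channel \
        else np.zeros(n_bait, bool)
    copies_b = ch_b.draw_copies(rng, n_bait) if (two_channel and n_bait) else None
    for i in range(n_bait):
        co = bool(has_b[i])
        add_entry(mol_id, ch_a, xs[i], ys[i], int(copies_a[i]), False, co)
        if co:
            add_entry(mol_id, ch_b, xs[i], ys[i], int(copies_b[i]), False, True)
        mol_id += 1

    # partner-only complexes (prey bound to the bait independently)
    if two_channel and config.partner_only_density > 0:
        n_p = rng.poisson(config.partner_only_density * area)
        xs = rng.uniform(0, w, n_p)
        ys = rng.uniform(0, h, n_p)
        copies = ch_b.draw_copies(rng, n_p) if n_p else np.zeros(0, int)
        for i in range(n_p):
            add_entry(mol_id, ch_b, xs[i], ys[i], int(copies[i]), False, False)
            mol_id += 1

    # nonspecific monomeric binders, channel-independent
    if config.nonspecific_density > 0:
        for ch in config.channels:
            n_ns = rng.poisson(config.nonspecific_density * area)
            xs = rng.uniform(0, w, n_ns)
            ys = rng.uniform(0, h, n_ns)
            for i in range(n_ns):
                add_entry(mol_id, ch, xs[i], ys[i], 1, True, False)
                mol_id += 1

    return pd.DataFrame(rows, columns=GroundTruth.COLUMNS)


_FRAME_BLOCK = 64  # frames rendered/noised per block, to bound memory


_NOISE_TABLE_BITS = 20  # inverse-CDF resolution: probabilities to ~1e-6


@lru_cache(maxsize=32)
def _background_noise_table(lam: float, read_sd: float) -> np.ndarray:
    """Inverse CDF of clip(Poisson(lam) + N(0, read_sd), 0) on a 2^20 grid.

    Pure Poisson when read_sd == 0 (exact, discrete); otherwise the
    Poisson-Gaussian convolution evaluated numerically."""
    size = 1 << _NOISE_TABLE_BITS
    u = (np.arange(size) + 0.5) / size
    kmax = int(stats.poisson.isf(1e-12, lam)) + 2 if lam > 0 else 1
    ks = np.arange(kmax)
    pmf = stats.poisson.pmf(ks, lam) if lam > 0 else np.array([1.0])
    if read_sd <= 0:
        cdf = np.cumsum(pmf)
        table = np.searchsorted(cdf, u).astype(np.float32)
    else:
        sd_tot = np.sqrt(lam + read_sd ** 2)
        xs = np.linspace(-8 * read_sd, lam + kmax + 8 * read_sd, 1 << 14)
        cdf = pmf @ stats.norm.cdf((xs[None, :] - ks[:, None]) / read_sd)
        table = np.interp(u, cdf, xs).astype(np.float32)
    return np.clip(table, 0.0, None)


def _background_noise(rng: np.random.Generator, lam: float, read_sd: float,
                      shape: tuple[int, ...]) -> np.ndarray:
    """Camera noise for signal-free pixels via inverse-CDF table lookup.

    Orders of magnitude faster than drawing Poisson and Gaussian variates
    per pixel; distribution exact to the table's ~1e-6 probability
    resolution."""
    if lam <= 0 and read_sd <= 0:
        return np.zeros(shape, dtype=np.float32)
    idx = rng.integers(0, 1 << _NOISE_TABLE_BITS, size=shape, dtype=np.uint32)
    return _background_noise_table(float(lam), float(read_sd))[idx]


def _render_channel(config: SimulationConfig, channel: str,
                    truth: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Render one channel's noisy stack from the truth table."""
    h, w = config.field_height_px, config.field_width_px
    n_frames = config.n_frames
    sigma = config.psf_sigma_px
    half = max(3, int(math.ceil(6.0 * sigma)))  # stamp half-width
    dy, dx = config.channel_offset_px[1], config.channel_offset_px[0]
    apply_offset = (len(config.channels) == 2
                    and channel == config.channels[1].label)

    entries = truth[(truth["channel"] == channel) & (truth["n_fluorescent"] >= 1)]
    ch_model = next(c for c in config.channels if c.label == channel)

    # per-molecule stamps and per-frame active-fluorophore counts
    stamps: list[tuple[slice, slice, np.ndarray, np.ndarray]] = []
    for _, row in entries.iterrows():
        x = float(row["x_px"]) + (dx if apply_offset else 0.0)
        y = float(row["y_px"]) + (dy if apply_offset else 0.0)
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        stamp = _pixel_integrated_psf(x, y, sigma, x0, x1, y0, y1)
        bleach = np.array([int(v) for v in str(row["bleach_frames"]).split(";") if v])
        # active[f] = number of fluorophores still emitting in frame f
        active = (np.arange(n_frames)[:, None] < bleach[None, :]).sum(axis=1)
        stamps.append((slice(y0, y1), slice(x0, x1),
                       stamp * ch_model.unit_intensity, active.astype(np.float32)))

    out = np.empty((n_frames, h, w), dtype=np.float32)
    bg = config.background_level
    for f0 in range(0, n_frames, _FRAME_BLOCK):
        f1 = min(n_frames, f0 + _FRAME_BLOCK)
        block = np.zeros((f1 - f0, h, w), dtype=np.float32)
        for ysl, xsl, stamp, active in stamps:
            act = active[f0:f1]
            if act.any():
                block[:, ysl, xsl] += act[:, None, None] * stamp[None, :, :]
        rn = config.read_noise_sd
        if not config.shot_noise:  # deterministic signal + flat background
            noisy = block + np.float32(bg)
            if rn > 0:
                noisy += rn * rng.standard_normal(size=block.shape,
                                                  dtype=np.float32)
            np.clip(noisy, 0.0, None, out=noisy)
        else:
            # tabulated background noise; signal pixels redrawn per-pixel.
            # PSF tail pixels whose signal is buried far below the shot
            # noise (<0.1 noise s.d.) keep the tabulated background draw.
            noisy = _background_noise(rng, bg, rn, block.shape)
            cut = 0.1 * math.sqrt(bg + rn * rn)
            sig = block > cut
            if sig.any():
                vals = rng.poisson(block[sig].astype(np.float64) + bg
                                   ).astype(np.float32)
                if rn > 0:
                    vals += rn * rng.standard_normal(size=vals.shape,
                                                     dtype=np.float32)
                noisy[sig] = np.clip(vals, 0.0, None)
        out[f0:f1] = noisy
    return out


def simulate_field(config: SimulationConfig,
                   rng: np.random.Generator | int | None = None,
                   ) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Simulate one field of view; returns per-channel stacks and the truth.

    Deterministic given the seed: the same ``config.seed`` (or explicit
    ``rng`` seed) yields bit-identical stacks and GroundTruth.
    """
    if config.expected_molecules() > 0.5 * config.field_height_px * config.field_width_px:
        raise ValueError("expected molecule count exceeds half the pixel count: "
                         "unresolvable overlap regime; dilute the sample")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    truth_df = _sample_molecules(config, rng)
    stacks = {
        label: ImageStack(_render_channel(config, label, truth_df, rng),
                          channel=label, pixel_size_nm=config.pixel_size_nm)
        for label in config.channel_labels
    }
    return stacks, GroundTruth(truth_df, n_frames=config.n_frames)


def simulate_trace(n_fluorophores: int,
                   config: SimulationConfig | None = None,
                   rng: np.random.Generator | int | None = None,
                   noise_sd: float = 0.0,
                   channel: str | None = None) -> IntensityTrace:
    """Idealized photobleaching staircase for ``n_fluorophores`` fluorophores.

    Each fluorophore emits ``unit_intensity`` per frame until its geometric
    bleach frame; optional additive Gaussian noise.  The true bleach frames
    are recorded in ``trace.meta["bleach_frames"]``.
    """
    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be >= 0")
    config = config or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    ch = config.channel(channel) if channel else config.channels[0]
    bleach = _draw_bleach_frames(rng, n_fluorophores,
                                 config.bleach_prob_per_frame, config.n_frames)
    frames = np.arange(config.n_frames)
    values = (frames[:, None] < bleach[None, :]).sum(axis=1) * ch.unit_intensity
    values = values.astype(float)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return IntensityTrace(
        values=values, spot=None, aperture_radius_px=0.0,
        annulus_radii_px=(0.0, 0.0),
        meta={"bleach_frames": np.sort(bleach),
              "n_fluorophores": n_fluorophores,
              "unit_intensity": ch.unit_intensity},
    )


def write_field(out_dir: str | Path, stacks: Mapping[str, ImageStack],
                truth: GroundTruth, config: SimulationConfig,
                field_index: int = 0) -> None:
    """Persist one simulated field: one TIFF per channel + truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, stack in stacks.items():
        stack.save_tiff(out / f"field{field_index:03d}_channel{label}.tif")
    truth.to_csv(out / f"field{field_index:03d}_truth.csv")
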