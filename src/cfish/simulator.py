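"""Ground-truthed multi-cycle FISH image simulation.

The simulator renders what a consecutive-hybridization experiment looks
like to the decoder: diffraction-limited spots at fixed cellular positions
that change fluorescence channel from cycle to cycle according to a
codebook.  The phenomena that make decoding non-trivial are modeled
explicitly:

* geometric amplification — each cycle's probes recruit two probes in the
  next cycle, so the expected spot amplitude grows as ``a**(cycle-1)``
  until a crowding saturation cap;
* photobleach residual — a small fraction ``r`` of the previous cycle's
  signal survives bleaching and appears in the previous cycle's channel;
* stage drift — a cumulative per-cycle translation of the field of view;
* non-specific binding — spurious spots that appear in a single cycle only;
* per-cycle dropout — a spot occasionally fails to stain in one cycle.

Noise follows the standard camera abstraction: Poisson shot noise on
signal plus background, Gaussian read noise, and a constant camera offset
added last.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .codebook import Codebook, default_channel_names

__all__ = [
    "SimulationConfig",
    "CycleStack",
    "expected_amplitude",
    "simulate_experiment",
    "simulate_detection_table",
    "save_stack",
    "load_stack",
]


@dataclass
class SimulationConfig:
    """All knobs of the renderer; defaults are the study conditions.

    Units: lengths in pixels unless suffixed ``_nm``; intensities in
    photons.  ``pixel_size_nm`` defaults to 160 so the 2-pixel
    colocalization radius equals 320 nm.  ``amplification`` defaults to 2
    (two landing sites per probe); ``saturation_cap`` bounds the fold
    amplification to model the crowding plateau.  ``bleach_residual`` is
    the fraction of a cycle's amplitude that survives photobleaching
    (default 0.01 — bleaching removes almost everything).  ``dropout_prob``
    (default 0.002) echoes the ~99.8% per-cycle re-staining efficiency.
    """

    n_cycles: int = 16
    n_channels: int = 2
    image_size: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 160.0
    psf_sigma: float = 1.3
    base_intensity: float = 150.0
    amplification: float = 2.0
    saturation_cap: float = 64.0
    brightness_cv: float = 0.25
    background: float = 20.0
    bleach_residual: float = 0.01
    read_noise: float = 3.0
    camera_offset: float = 100.0
    drift_per_cycle: tuple[float, float] = (0.0, 0.0)
    n_cells: int = 3
    cell_radius_px: float = 42.0
    spots_per_cell_per_target: float = 8.0
    nonspecific_rate: float = 0.5
    dropout_prob: float = 0.002
    min_separation_px: float = 4.0
    enforce_min_separation: bool = True
    shot_noise: bool = True
    seed: int = 0
    channel_names: list[str] = field(default_factory=list)

    _REQUIRED = ("n_cycles", "n_channels")

    def __post_init__(self) -> None:
        if not self.channel_names:
            self.channel_names = default_channel_names(self.n_channels)
        self.image_size = tuple(self.image_size)
        self.drift_per_cycle = tuple(self.drift_per_cycle)
        self.validate()

    def validate(self) -> None:
        if self.n_cycles < 1 or self.n_channels < 1:
            raise ValueError("n_cycles and n_channels must be >= 1")
        if not (0.0 <= self.bleach_residual < 1.0):
            raise ValueError("bleach_residual must be in [0, 1)")
        if self.amplification < 1.0:
            raise ValueError("amplification must be >= 1")
        if self.saturation_cap < 1.0:
            raise ValueError("saturation_cap must be >= 1")
        for name in (
            "psf_sigma", "base_intensity", "brightness_cv", "background",
            "read_noise", "nonspecific_rate", "spots_per_cell_per_target",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be a probability")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size"] = list(self.image_size)
        d["drift_per_cycle"] = list(self.drift_per_cycle)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        missing = sorted(k for k in cls._REQUIRED if k not in data)
        if missing:
            raise ValueError(f"missing required config keys: {', '.join(missing)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CycleStack:
    """Image stack indexed ``[cycle, channel, row, col]`` (photon scale)."""

    images: np.ndarray  # (n_cycles, n_channels, H, W)
    pixel_size_nm: float
    channel_names: list[str]
    cell_mask: np.ndarray | None = None  # (H, W) integer labels, 0 = background

    def __post_init__(self) -> None:
        if self.images.ndim != 4:
            raise ValueError("images must be (n_cycles, n_channels, H, W)")
        if self.cell_mask is not None and self.cell_mask.shape != self.images.shape[2:]:
            raise ValueError("cell mask shape must match image shape")

    @property
    def n_cycles(self) -> int:
        return self.images.shape[0]

    @property
    def n_channels(self) -> int:
        return self.images.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[2:]

    def image(self, cycle: int, channel: int) -> np.ndarray:
        """Image for 1-based ``cycle`` and 0-based ``channel``."""
        return self.images[cycle - 1, channel]

    def channel_sum(self, cycle: int) -> np.ndarray:
        """Sum over channels for 1-based ``cycle`` (used for registration)."""
        return self.images[cycle - 1].sum(axis=0)


def expected_amplitude(I0: float, a: float, cap: float, cycle: int) -> float:
    """Expected peak amplitude at 1-based ``cycle``: ``I0 * min(a**(cycle-1), cap)``.

    Growth is geometric while each probe recruits ``a`` probes for the next
    cycle, and plateaus at ``cap``-fold once crowding limits hybridization.
    """
    if cycle < 1:
        raise ValueError("cycle is 1-based")
    return I0 * min(a ** (cycle - 1), cap)


def _add_gaussian(img: np.ndarray, row: float, col: float, amp: float, sigma: float):
    """Accumulate an isotropic 2D Gaussian (peak ``amp``) into ``img``."""
    if amp <= 0:
        return
    H, W = img.shape
    rad = int(np.ceil(4 * sigma)) + 1
    r0, r1 = int(np.floor(row)) - rad, int(np.floor(row)) + rad + 1
    c0, c1 = int(np.floor(col)) - rad, int(np.floor(col)) + rad + 1
    r0, r1 = max(r0, 0), min(r1, H)
    c0, c1 = max(c0, 0), min(c1, W)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    img[r0:r1, c0:c1] += amp * np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))


def _place_cells(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping disk cells as an integer label mask (0 = outside)."""
    H, W = config.image_size
    r = config.cell_radius_px
    total_drift = max(
        abs(config.drift_per_cycle[0]), abs(config.drift_per_cycle[1])
    ) * (config.n_cycles - 1)
    margin = r + 12 + total_drift
    if 2 * margin >= min(H, W):
        raise ValueError("cells do not fit the image; enlarge image or shrink cells")
    centers: list[tuple[float, float]] = []
    for _ in range(10000):
        if len(centers) == config.n_cells:
            break
        cand = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
        if all(np.hypot(cand[0] - y, cand[1] - x) > 2 * r + 4 for y, x in centers):
            centers.append(cand)
    if len(centers) < config.n_cells:
        raise ValueError("could not place non-overlapping cells; reduce n_cells")
    mask = np.zeros((H, W), dtype=np.uint16)
    yy, xx = np.mgrid[0:H, 0:W]
    for label, (cy, cx) in enumerate(centers, start=1):
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = label
    return mask


def _sample_positions_in_cell(
    mask: np.ndarray,
    label: int,
    n: int,
    min_sep: float,
    rng: np.random.Generator,
    existing: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Uniform positions inside one labeled cell, rejecting close pairs.

    Sampling is restricted to the 2-px-eroded interior so a sub-pixel
    position (plus localization error) can never round to a pixel outside
    its cell.
    """
    from scipy.ndimage import binary_erosion

    interior = binary_erosion(mask == label, iterations=2)
    ys, xs = np.nonzero(interior)
    if len(ys) == 0:
        ys, xs = np.nonzero(mask == label)
    out: list[tuple[float, float]] = []
    attempts = 0
    while len(out) < n and attempts < 200 * max(n, 1):
        attempts += 1
        k = rng.integers(len(ys))
        pos = (ys[k] + rng.uniform(-0.5, 0.5), xs[k] + rng.uniform(-0.5, 0.5))
        if min_sep > 0 and any(
            np.hypot(pos[0] - y, pos[1] - x) < min_sep for y, x in existing + out
        ):
            continue
        out.append(pos)
    return out


def simulate_experiment(
    config: SimulationConfig, codebook: Codebook, truth: pd.DataFrame | None = None
) -> tuple[CycleStack, pd.DataFrame]:
    """Render a full experiment and its ground-truth table.

    If ``truth`` is given it must carry ``cell_id``, ``target_id``, ``row``,
    ``col`` for specific spots and positions are used as-is (presence,
    brightness and non-specific spots are still drawn from the config);
    otherwise spot counts per cell per target are Poisson with mean
    ``spots_per_cell_per_target``.

    Ground-truth columns: ``spot_id, cell_id, target_id, row, col,
    color_sequence`` plus per-cycle ``channel_c{c}``, ``amp_c{c}`` and
    ``present_c{c}`` (designated channel, noise-free designated amplitude,
    and whether the spot was stained that cycle).
    """
    if codebook.n_cycles != config.n_cycles or codebook.n_channels != config.n_channels:
        raise ValueError(
            "codebook dimensions do not match the config "
            f"(codebook {codebook.n_channels}x{codebook.n_cycles}, "
            f"config {config.n_channels}x{config.n_cycles})"
        )
    rng = np.random.default_rng(config.seed)
    H, W = config.image_size
    mask = _place_cells(config, rng)

    # --- draw the spot population -------------------------------------
    rows: list[dict] = []
    min_sep = config.min_separation_px if config.enforce_min_separation else 0.0
    if truth is not None:
        for _, t in truth.iterrows():
            rows.append(
                dict(
                    cell_id=int(t["cell_id"]),
                    target_id=str(t["target_id"]),
                    row=float(t["row"]),
                    col=float(t["col"]),
                )
            )
    else:
        for label in range(1, config.n_cells + 1):
            placed: list[tuple[float, float]] = []
            for target in codebook.targets:
                n = rng.poisson(config.spots_per_cell_per_target)
                pos = _sample_positions_in_cell(mask, label, n, min_sep, rng, placed)
                placed.extend(pos)
                rows.extend(
                    dict(cell_id=label, target_id=target, row=y, col=x)
                    for y, x in pos
                )

    records: list[dict] = []
    for r in rows:
        colors = codebook.sequence_of(r["target_id"])
        factor = float(np.exp(rng.normal(0.0, config.brightness_cv)))
        present = rng.random(config.n_cycles) >= config.dropout_prob
        rec = dict(
            spot_id=len(records),
            cell_id=r["cell_id"],
            target_id=r["target_id"],
            row=r["row"],
            col=r["col"],
            color_sequence="-".join(str(c) for c in colors),
        )
        for c in range(1, config.n_cycles + 1):
            amp = (
                expected_amplitude(
                    config.base_intensity,
                    config.amplification,
                    config.saturation_cap,
                    c,
                )
                * factor
                if present[c - 1]
                else 0.0
            )
            rec[f"channel_c{c}"] = colors[c - 1]
            rec[f"amp_c{c}"] = amp
            rec[f"present_c{c}"] = bool(present[c - 1])
        records.append(rec)

    # Non-specific spots: each exists in exactly one cycle, one channel.
    for label in range(1, config.n_cells + 1):
        for c in range(1, config.n_cycles + 1):
            n_ns = rng.poisson(config.nonspecific_rate)
            pos = _sample_positions_in_cell(mask, label, n_ns, min_sep, rng, [])
            for y, x in pos:
                channel = int(rng.integers(config.n_channels))
                factor = float(np.exp(rng.normal(0.0, config.brightness_cv)))
                rec = dict(
                    spot_id=len(records),
                    cell_id=label,
                    target_id="NONSPECIFIC",
                    row=y,
                    col=x,
                    color_sequence="",
                )
                for cc in range(1, config.n_cycles + 1):
                    rec[f"channel_c{cc}"] = channel if cc == c else -1
                    rec[f"amp_c{cc}"] = (
                        config.base_intensity * factor if cc == c else 0.0
                    )
                    rec[f"present_c{cc}"] = cc == c
                records.append(rec)

    truth_df = pd.DataFrame(records)

    # --- render -------------------------------------------------------
    images = np.zeros((config.n_cycles, config.n_channels, H, W), dtype=np.float64)
    dy, dx = config.drift_per_cycle
    for c in range(1, config.n_cycles + 1):
        off = ((c - 1) * dy, (c - 1) * dx)
        for rec in records:
            y, x = rec["row"] + off[0], rec["col"] + off[1]
            if rec[f"present_c{c}"] and rec[f"amp_c{c}"] > 0:
                _add_gaussian(
                    images[c - 1, rec[f"channel_c{c}"]],
                    y, x, rec[f"amp_c{c}"], config.psf_sigma,
                )
            # photobleach residual from the previous cycle's staining
            if c > 1 and config.bleach_residual > 0 and rec[f"present_c{c-1}"]:
                prev_ch = rec[f"channel_c{c-1}"]
                if prev_ch >= 0:
                    _add_gaussian(
                        images[c - 1, prev_ch],
                        y, x,
                        config.bleach_residual * rec[f"amp_c{c-1}"],
                        config.psf_sigma,
                    )
        images[c - 1] += config.background
    if config.shot_noise:
        images = rng.poisson(images).astype(np.float64)
        if config.read_noise > 0:
            images += rng.normal(0.0, config.read_noise, size=images.shape)
    images += config.camera_offset
    np.clip(images, 0.0, None, out=images)

    stack = CycleStack(
        images=images,
        pixel_size_nm=config.pixel_size_nm,
        channel_names=list(config.channel_names),
        cell_mask=mask,
    )
    return stack, truth_df


def simulate_detection_table(
    n_spots: int,
    n_cycles: int,
    detect_prob: float = 0.998,
    nonspecific_fraction: float = 0.0,
    always_cycles: int = 1,
    jitter_sigma: float = 0.15,
    spacing: float = 8.0,
    n_channels: int = 2,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Point-process simulation of per-cycle detections (no images).

    ``n_spots`` spots are laid out on a jittered grid (``spacing`` px) and
    observed over ``n_cycles`` cycles.  A fraction ``nonspecific_fraction``
    of them are single-cycle non-specific spots, present only in cycle 1;
    the rest are real spots, detected with certainty in the first
    ``always_cycles`` cycles and independently with probability
    ``detect_prob`` in each later cycle.  Detected positions get Gaussian
    localization jitter of ``jitter_sigma`` px.

    Returns ``(detections, truth)``: detections in the standard decoder
    input format (already aligned — no drift at this level), truth with one
    row per spot (``spot_id, row, col, kind`` plus per-cycle presence).
    This is the tool for survival and reappearance arithmetic, where what
    matters is per-cycle presence and the colocalization radius, not pixels.
    """
    if not (0.0 <= detect_prob <= 1.0 and 0.0 <= nonspecific_fraction <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_spots)))
    idx = np.arange(n_spots)
    base_rows = (idx // side + 1) * spacing
    base_cols = (idx % side + 1) * spacing
    n_ns = int(round(n_spots * nonspecific_fraction))
    is_ns = np.zeros(n_spots, dtype=bool)
    is_ns[rng.choice(n_spots, size=n_ns, replace=False)] = True

    present = np.zeros((n_spots, n_cycles), dtype=bool)
    present[:, 0] = True
    for c in range(1, n_cycles):
        if c < always_cycles:
            present[:, c] = ~is_ns
        else:
            present[:, c] = ~is_ns & (rng.random(n_spots) < detect_prob)

    channel_names = default_channel_names(n_channels)
    spot_channel = rng.integers(n_channels, size=n_spots)
    det_rows = []
    for c in range(n_cycles):
        for s in np.nonzero(present[:, c])[0]:
            y = base_rows[s] + rng.normal(0.0, jitter_sigma)
            x = base_cols[s] + rng.normal(0.0, jitter_sigma)
            row = dict(
                cycle=c + 1, row=y, col=x, aligned_row=y, aligned_col=x,
                peak_snr=20.0, edge_flag=False,
            )
            for ch, name in enumerate(channel_names):
                row[f"I_{name}"] = 100.0 if ch == spot_channel[s] else 2.0
            det_rows.append(row)
    detections = pd.DataFrame(det_rows)
    detections.insert(0, "det_id", np.arange(len(detections)))

    truth = pd.DataFrame(
        dict(
            spot_id=idx,
            row=base_rows,
            col=base_cols,
            kind=np.where(is_ns, "nonspecific", "specific"),
        )
    )
    for c in range(n_cycles):
        truth[f"present_c{c+1}"] = present[:, c]
    return detections, truth


def save_stack(
    stack: CycleStack,
    out_dir,
    truth: pd.DataFrame | None = None,
    config: SimulationConfig | None = None,
) -> list[str]:
    """Write TIFFs (16-bit), cell mask, truth table and config echo.

    Files: ``cycle{c:02d}_{channel}.tif``, ``cellmask.tif``, ``truth.csv``,
    ``config.yaml``.  Pixel values are rounded to integers; the camera
    offset is already in the data and noted in the config echo.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for c in range(1, stack.n_cycles + 1):
        for ch, name in enumerate(stack.channel_names):
            fname = f"cycle{c:02d}_{name}.tif"
            data = np.clip(np.round(stack.image(c, ch)), 0, 65535).astype(np.uint16)
            tifffile.imwrite(out / fname, data)
            written.append(fname)
    if stack.cell_mask is not None:
        tifffile.imwrite(out / "cellmask.tif", stack.cell_mask.astype(np.uint16))
        written.append("cellmask.tif")
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
        written.append("truth.csv")
    meta = {"pixel_size_nm": stack.pixel_size_nm, "channel_names": stack.channel_names}
    if config is not None:
        meta = config.to_dict()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    written.append("config.yaml")
    return written


def load_stack(in_dir) -> CycleStack:
    """Read a stack written by :func:`save_stack`."""
    src = Path(in_dir)
    with open(src / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    channel_names = list(meta["channel_names"])
    pixel_size = float(meta["pixel_size_nm"])
    files = sorted(src.glob("cycle*_*.tif"))
    if not files:
        raise FileNotFoundError(f"no cycle TIFFs found in {src}")
    cycles = sorted({int(f.name[5:7]) for f in files})
    if cycles != list(range(1, len(cycles) + 1)):
        raise ValueError("cycle numbering must be contiguous from 1")
    sample = tifffile.imread(files[0])
    images = np.zeros(
        (len(cycles), len(channel_names), *sample.shape), dtype=np.float64
    )
    for c in cycles:
        for ch, name in enumerate(channel_names):
            path = src / f"cycle{c:02d}_{name}.tif"
            if not path.exists():
                raise FileNotFoundError(f"missing image {path.name}")
            images[c - 1, ch] = tifffile.imread(path).astype(np.float64)
    mask_path = src / "cellmask.tif"
    mask = tifffile.imread(mask_path) if mask_path.exists() else None
    return CycleStack(
        images=images,
        pixel_size_nm=pixel_size,
        channel_names=channel_names,
        cell_mask=mask,
    )
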