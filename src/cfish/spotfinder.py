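"""Spot detection, intensity measurement and cycle registration.

Detection is a Laplacian-of-Gaussian blob finder at the PSF scale with
sub-pixel refinement by a 2D Gaussian least-squares fit (falling back to an
intensity-weighted centroid if the fit fails).  Intensities are measured
per channel by aperture photometry: disk sum minus local annulus median.
Cycles are registered to the first cycle by phase cross-correlation of the
channel-summed images, with 0.1-px sub-pixel upsampling.

Coordinates are 0-based ``(row, col)`` with pixel centers at integers;
sub-pixel positions are real-valued.  All distances are in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .simulator import CycleStack

__all__ = [
    "CycleOffsets",
    "detect_spots",
    "measure_intensities",
    "register_cycles",
    "detect_stack",
]

APERTURE_RADIUS = 3.0
ANNULUS_INNER = 6.0
ANNULUS_OUTER = 9.0
MIN_SEPARATION = 2.0  # px between kept detections
MERGE_RADIUS = 1.0    # px for cross-channel merging within a cycle


@dataclass
class CycleOffsets:
    """Per-cycle translation of the field of view relative to cycle 1.

    ``offsets[c-1]`` is the (dy, dx) displacement of cycle ``c``'s content:
    a spot at ``p`` in the cycle-1 frame appears at ``p + offsets[c-1]`` in
    cycle ``c``'s local frame.  ``low_confidence`` flags cycles where the
    estimate degenerated (e.g. flat images).
    """

    offsets: np.ndarray  # (n_cycles, 2)
    low_confidence: np.ndarray  # (n_cycles,) bool

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.low_confidence = np.asarray(self.low_confidence, dtype=bool)
        if not np.allclose(self.offsets[0], 0.0):
            raise ValueError("cycle-1 offset must be (0, 0)")

    def align(self, cycle: int, position: np.ndarray) -> np.ndarray:
        """Map a cycle-local position into the cycle-1 frame."""
        return np.asarray(position, dtype=float) - self.offsets[cycle - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                cycle=np.arange(1, len(self.offsets) + 1),
                dy=self.offsets[:, 0],
                dx=self.offsets[:, 1],
                low_confidence=self.low_confidence,
            )
        )


def _robust_sigma(values: np.ndarray) -> float:
    """Noise scale from the median absolute deviation (Gaussian-consistent)."""
    med = np.median(values)
    return 1.4826 * np.median(np.abs(values - med))


def _gauss2d(coords, amp, row0, col0, sigma, offset):
    rr, cc = coords
    return (
        amp * np.exp(-((rr - row0) ** 2 + (cc - col0) ** 2) / (2.0 * sigma**2))
        + offset
    ).ravel()


def _refine_subpixel(
    image: np.ndarray, peak: tuple[int, int], psf_sigma: float, half: int = 3
) -> tuple[float, float, float]:
    """Sub-pixel position and amplitude from a Gaussian fit in a window.

    Returns (row, col, amplitude).  Falls back to an intensity-weighted
    centroid of the background-subtracted window when the fit fails.
    """
    H, W = image.shape
    r, c = peak
    r0, r1 = max(r - half, 0), min(r + half + 1, H)
    c0, c1 = max(c - half, 0), min(c + half + 1, W)
    window = image[r0:r1, c0:c1].astype(float)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    offset0 = float(window.min())
    amp0 = float(image[r, c] - offset0)

    def _parabolic() -> tuple[float, float, float]:
        """Per-axis 3-point parabola through the peak (at most 0.5 px)."""
        sr, sc = float(r), float(c)
        if 0 < r < H - 1:
            denom = image[r - 1, c] - 2 * image[r, c] + image[r + 1, c]
            if denom < 0:
                sr += 0.5 * (image[r - 1, c] - image[r + 1, c]) / denom
        if 0 < c < W - 1:
            denom = image[r, c - 1] - 2 * image[r, c] + image[r, c + 1]
            if denom < 0:
                sc += 0.5 * (image[r, c - 1] - image[r, c + 1]) / denom
        return sr, sc, amp0

    try:
        # a real center lies within +-1 px of the discrete maximum; a fit
        # drifting further is being pulled by a neighboring spot
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (rr, cc),
            window.ravel(),
            p0=(amp0, float(r), float(c), psf_sigma, offset0),
            bounds=(
                (0.0, r - 1.5, c - 1.5, 0.3 * psf_sigma, -np.inf),
                (np.inf, r + 1.5, c + 1.5, 3.0 * psf_sigma, np.inf),
            ),
            maxfev=200,
        )
        if np.hypot(popt[1] - r, popt[2] - c) > 1.2:
            return _parabolic()
        return float(popt[1]), float(popt[2]), float(popt[0])
    except (RuntimeError, ValueError):
        return _parabolic()


def detect_spots(
    image: np.ndarray, psf_sigma: float, min_snr: float = 5.0
) -> pd.DataFrame:
    """Detect diffraction-limited spots in a single image.

    Local maxima of the scale-normalized LoG response above
    ``min_snr x`` the robust background rms are kept, refined to sub-pixel
    positions, and de-duplicated so no two detections lie within 2 px
    (the brighter one wins).

    Returns a DataFrame with columns ``row, col, peak_snr``.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image is empty")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    response = -(psf_sigma**2) * ndimage.gaussian_laplace(image, psf_sigma)
    # the discrete LoG kernel leaks a small DC term, so a flat background
    # gives a constant non-zero response; remove it, and floor the noise
    # estimate so noise-free images keep a meaningful threshold
    response -= np.median(response)
    span = float(np.abs(response).max())
    noise = max(_robust_sigma(response), 1e-6 * span, 1e-12)
    footprint = ndimage.maximum_filter(response, size=3)
    peaks = (response == footprint) & (response > min_snr * noise)
    # exclude a 1-px border: maxima there are unreliable
    peaks[0, :] = peaks[-1, :] = False
    peaks[:, 0] = peaks[:, -1] = False
    rows, cols = np.nonzero(peaks)

    bg_med = float(np.median(image))
    img_noise = max(_robust_sigma(image), 1e-6 * max(abs(image).max(), 1.0), 1e-12)

    cands = []
    for r, c in zip(rows, cols):
        sr, sc, amp = _refine_subpixel(image, (r, c), psf_sigma)
        if not (0 <= sr < image.shape[0] and 0 <= sc < image.shape[1]):
            sr, sc = float(r), float(c)
        snr = (float(image[r, c]) - bg_med) / img_noise
        cands.append((sr, sc, snr, amp))
    # keep the brighter of any pair closer than MIN_SEPARATION
    cands.sort(key=lambda t: -t[3])
    kept: list[tuple[float, float, float, float]] = []
    for cand in cands:
        if all(
            np.hypot(cand[0] - k[0], cand[1] - k[1]) >= MIN_SEPARATION for k in kept
        ):
            kept.append(cand)
    return pd.DataFrame(
        [dict(row=r, col=c, peak_snr=s) for r, c, s, _ in kept],
        columns=["row", "col", "peak_snr"],
    )


def measure_intensities(
    stack: CycleStack, cycle: int, position: tuple[float, float]
) -> tuple[np.ndarray, bool]:
    """Aperture photometry at ``position`` in every channel of ``cycle``.

    Sum over a radius-3 px disk minus (disk area x annulus median), the
    annulus spanning 6-9 px.  Values can be negative in empty channels.
    Positions closer than the aperture radius to the border are flagged and
    return NaNs; a partially clipped annulus is tolerated (median over the
    available pixels).

    Returns ``(intensity_vector, edge_flag)``.
    """
    H, W = stack.shape
    row, col = position
    if not (0 <= row < H and 0 <= col < W):
        raise ValueError(f"position {position} outside image bounds")
    if (
        row < APERTURE_RADIUS
        or col < APERTURE_RADIUS
        or row > H - 1 - APERTURE_RADIUS
        or col > W - 1 - APERTURE_RADIUS
    ):
        return np.full(stack.n_channels, np.nan), True

    rad = int(np.ceil(ANNULUS_OUTER)) + 1
    r0, r1 = int(np.floor(row)) - rad, int(np.floor(row)) + rad + 1
    c0, c1 = int(np.floor(col)) - rad, int(np.floor(col)) + rad + 1
    r0, r1 = max(r0, 0), min(r1, H)
    c0, c1 = max(c0, 0), min(c1, W)
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    dist = np.hypot(rr, cc)
    disk = dist <= APERTURE_RADIUS
    annulus = (dist >= ANNULUS_INNER) & (dist <= ANNULUS_OUTER)
    out = np.empty(stack.n_channels)
    for ch in range(stack.n_channels):
        patch = stack.image(cycle, ch)[r0:r1, c0:c1]
        bg = float(np.median(patch[annulus])) if annulus.any() else 0.0
        out[ch] = float(patch[disk].sum()) - bg * int(disk.sum())
    return out, False


def register_cycles(stack: CycleStack, reference_cycle: int = 1) -> CycleOffsets:
    """Estimate per-cycle translation relative to the reference cycle.

    Phase cross-correlation of the channel-summed images with 0.1-px
    upsampling.  Flat (degenerate) images yield a zero offset flagged
    low-confidence.
    """
    ref = stack.channel_sum(reference_cycle)
    n = stack.n_cycles
    offsets = np.zeros((n, 2))
    lowconf = np.zeros(n, dtype=bool)
    ref_flat = ref.std() == 0
    for c in range(1, n + 1):
        if c == reference_cycle:
            continue
        mov = stack.channel_sum(c)
        if ref_flat or mov.std() == 0:
            lowconf[c - 1] = True
            continue
        shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=10)
        # pcc returns the shift that registers `mov` onto `ref`,
        # i.e. minus the displacement of cycle-c content.
        offsets[c - 1] = -shift
    if reference_cycle != 1:
        offsets = offsets - offsets[0]
    return CycleOffsets(offsets=offsets, low_confidence=lowconf)


def detect_stack(
    stack: CycleStack,
    psf_sigma: float,
    min_snr: float = 5.0,
    offsets: CycleOffsets | None = None,
) -> tuple[pd.DataFrame, CycleOffsets]:
    """Run registration, per-cycle per-channel detection and photometry.

    Detections found in different channels of the same cycle within 1 px
    are merged into a single record (the brighter position wins) so each
    record carries the full per-channel intensity vector — decoding
    compares all channels at one location regardless of which channel
    triggered detection.

    Returns ``(detections, offsets)``; detections columns: ``det_id, cycle,
    row, col, aligned_row, aligned_col, peak_snr, edge_flag`` and one
    ``I_{channel}`` column per channel name.
    """
    if offsets is None:
        offsets = register_cycles(stack)
    rows = []
    for cycle in range(1, stack.n_cycles + 1):
        per_channel = []
        for ch in range(stack.n_channels):
            det = detect_spots(stack.image(cycle, ch), psf_sigma, min_snr)
            for _, d in det.iterrows():
                per_channel.append((d["row"], d["col"], d["peak_snr"]))
        # merge across channels: brighter detection absorbs neighbors < 1 px
        per_channel.sort(key=lambda t: -t[2])
        merged: list[tuple[float, float, float]] = []
        for cand in per_channel:
            if all(
                np.hypot(cand[0] - m[0], cand[1] - m[1]) >= MERGE_RADIUS
                for m in merged
            ):
                merged.append(cand)
        for r, c, snr in merged:
            vec, edge = measure_intensities(stack, cycle, (r, c))
            aligned = offsets.align(cycle, np.array([r, c]))
            rec = dict(
                cycle=cycle,
                row=r,
                col=c,
                aligned_row=aligned[0],
                aligned_col=aligned[1],
                peak_snr=snr,
                edge_flag=edge,
            )
            for ch, name in enumerate(stack.channel_names):
                rec[f"I_{name}"] = vec[ch]
            rows.append(rec)
    detections = pd.DataFrame(rows)
    if len(detections):
        detections.insert(0, "det_id", np.arange(len(detections)))
    else:
        detections = pd.DataFrame(
            columns=["det_id", "cycle", "row", "col", "aligned_row",
                     "aligned_col", "peak_snr", "edge_flag"]
            + [f"I_{n}" for n in stack.channel_names]
        )
    return detections, offsets
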