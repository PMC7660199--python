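"""Cross-cycle linking, threshold-free channel calling and barcode decoding.

Detections from all cycles (already registered to the cycle-1 frame) are
linked into tracks by the colocalization rule: detections closer than
2 px (320 nm at 160 nm/px) to a track's anchor belong to the same
molecule.  Tracks are seeded from cycle-1 detections; later-cycle
detections that no track claims are *orphans* (they can never satisfy the
real-signal rule, which requires presence in both of the first two
cycles).

Each linked cycle's channel is called by comparing intensities across all
channels — the argmax wins, with no absolute threshold, so weak spots stay
callable; a call is flagged ambiguous when the winner fails to beat the
runner-up by a configurable ratio.  A track decodes to a target only when
it is present in every cycle, unambiguous throughout, and its color
sequence is in the codebook; everything else is reported as UNASSIGNED
with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .codebook import Codebook

__all__ = [
    "SpotTrack",
    "LinkResult",
    "link_tracks",
    "call_color",
    "decode_track",
    "decode_tracks",
    "copy_number",
    "qc_metrics",
    "tracks_to_frame",
]

MISSING = -1
UNASSIGNED = "UNASSIGNED"
DEFAULT_RADIUS_PX = 2.0      # strict: linked iff distance < 2 px
DEFAULT_AMBIGUITY_RATIO = 1.5


@dataclass
class SpotTrack:
    """One candidate molecule followed across all cycles."""

    track_id: int
    anchor_row: float
    anchor_col: float
    n_cycles: int
    det_ids: list[int] = field(default_factory=list)      # MISSING where unlinked
    intensities: np.ndarray | None = None                 # (n_cycles, n_channels)
    called: list[int] = field(default_factory=list)       # MISSING where uncallable
    ambiguous: list[bool] = field(default_factory=list)
    target_id: str = UNASSIGNED
    reason: str = ""                                      # incomplete|ambiguous|no-codebook-match
    cell_id: int = 0

    @property
    def present(self) -> list[bool]:
        return [d != MISSING for d in self.det_ids]

    @property
    def n_present(self) -> int:
        return sum(self.present)

    @property
    def is_real_signal(self) -> bool:
        """Present in both of the first two cycles (the real-signal rule)."""
        p = self.present
        return p[0] and (self.n_cycles < 2 or p[1])

    @property
    def is_complete(self) -> bool:
        return all(self.present)

    @property
    def is_decoded(self) -> bool:
        return self.target_id != UNASSIGNED


@dataclass
class LinkResult:
    tracks: list[SpotTrack]
    orphans: pd.DataFrame  # later-cycle detections claimed by no track

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


def _intensity_columns(detections: pd.DataFrame) -> list[str]:
    return [c for c in detections.columns if c.startswith("I_")]


def link_tracks(
    detections: pd.DataFrame,
    n_cycles: int,
    radius_px: float = DEFAULT_RADIUS_PX,
) -> LinkResult:
    """Link per-cycle detections into cross-cycle tracks.

    ``detections`` needs columns ``det_id, cycle, aligned_row, aligned_col``
    and optionally ``I_*`` intensity columns (copied into the tracks).
    Tracks are seeded from cycle-1 detections in input order.  For each
    later cycle, candidate (track, detection) pairs within ``radius_px``
    (strict) of the track anchor are assigned greedily in ascending
    distance (ties by track creation order), one-to-one, so no detection is
    shared.  Unclaimed later-cycle detections are returned as orphans.
    """
    icols = _intensity_columns(detections)
    n_channels = len(icols)
    tracks: list[SpotTrack] = []
    cyc1 = detections[detections["cycle"] == 1]
    c1_pos = cyc1[["aligned_row", "aligned_col"]].to_numpy(dtype=float)
    c1_ids = cyc1["det_id"].to_numpy()
    c1_I = cyc1[icols].to_numpy(dtype=float) if n_channels else None
    for k in range(len(cyc1)):
        t = SpotTrack(
            track_id=k,
            anchor_row=float(c1_pos[k, 0]),
            anchor_col=float(c1_pos[k, 1]),
            n_cycles=n_cycles,
            det_ids=[MISSING] * n_cycles,
        )
        t.intensities = np.full((n_cycles, max(n_channels, 1)), np.nan)
        t.det_ids[0] = int(c1_ids[k])
        if n_channels:
            t.intensities[0] = c1_I[k]
        tracks.append(t)

    anchors = np.array([[t.anchor_row, t.anchor_col] for t in tracks]).reshape(-1, 2)
    tree = cKDTree(anchors) if len(tracks) else None
    orphan_ids: list[int] = []
    for cycle in range(2, n_cycles + 1):
        sub = detections[detections["cycle"] == cycle]
        if sub.empty:
            continue
        if tree is None:
            orphan_ids.extend(int(i) for i in sub["det_id"])
            continue
        pos = sub[["aligned_row", "aligned_col"]].to_numpy(dtype=float)
        candidates: list[tuple[float, int, int]] = []  # (distance, track, row-in-sub)
        neighbor_lists = tree.query_ball_point(pos, r=radius_px)
        for k, neigh in enumerate(neighbor_lists):
            for ti in neigh:
                dist = float(
                    np.hypot(pos[k, 0] - anchors[ti, 0], pos[k, 1] - anchors[ti, 1])
                )
                if dist < radius_px:  # strict inequality
                    candidates.append((dist, ti, k))
        candidates.sort(key=lambda t: (t[0], t[1]))
        taken_tracks: set[int] = set()
        taken_dets: set[int] = set()
        sub_det_ids = sub["det_id"].to_numpy()
        sub_I = sub[icols].to_numpy(dtype=float) if n_channels else None
        for dist, ti, k in candidates:
            if ti in taken_tracks or k in taken_dets:
                continue
            taken_tracks.add(ti)
            taken_dets.add(k)
            tracks[ti].det_ids[cycle - 1] = int(sub_det_ids[k])
            if n_channels:
                tracks[ti].intensities[cycle - 1] = sub_I[k]
        orphan_ids.extend(
            int(sub_det_ids[k]) for k in range(len(sub)) if k not in taken_dets
        )
    orphans = detections[detections["det_id"].isin(orphan_ids)].copy()
    return LinkResult(tracks=tracks, orphans=orphans)


def call_color(
    intensity_vector: np.ndarray,
    ambiguity_ratio: float = DEFAULT_AMBIGUITY_RATIO,
) -> tuple[int, str]:
    """Call the stained channel by comparing intensities across channels.

    Returns ``(channel, status)`` where status is ``"ok"``, ``"ambiguous"``
    (argmax still reported) or ``"missing"`` (all values missing; channel
    is ``MISSING``).  The call is ambiguous when the largest intensity
    fails to exceed ``ambiguity_ratio`` times the runner-up; a runner-up at
    or below zero can never cause ambiguity.  No absolute threshold is
    applied, so arbitrarily weak spots remain callable.
    """
    vec = np.asarray(intensity_vector, dtype=float)
    if np.all(np.isnan(vec)):
        return MISSING, "missing"
    best = int(np.nanargmax(vec))
    if vec.size < 2:
        return best, "ok"
    rest = np.delete(vec, best)
    second = np.nanmax(rest)
    if np.isnan(second) or second <= 0:
        return best, "ok"
    if vec[best] < ambiguity_ratio * second:
        return best, "ambiguous"
    return best, "ok"


def decode_track(track: SpotTrack, codebook: Codebook) -> str:
    """Decode one track's called color sequence against the codebook.

    Requires the track to be complete and unambiguous; otherwise the track
    stays UNASSIGNED with ``reason`` set to ``incomplete``, ``ambiguous``
    or ``no-codebook-match``.
    """
    if not track.called:
        raise ValueError("track has no called colors; run decode_tracks first")
    if any(c == MISSING for c in track.called) or not track.is_complete:
        track.target_id, track.reason = UNASSIGNED, "incomplete"
    elif any(track.ambiguous):
        track.target_id, track.reason = UNASSIGNED, "ambiguous"
    else:
        hit = codebook.lookup(tuple(track.called))
        if hit is None:
            track.target_id, track.reason = UNASSIGNED, "no-codebook-match"
        else:
            track.target_id, track.reason = hit, ""
    return track.target_id


def decode_tracks(
    tracks: list[SpotTrack],
    codebook: Codebook,
    ambiguity_ratio: float = DEFAULT_AMBIGUITY_RATIO,
) -> list[SpotTrack]:
    """Call colors for every linked cycle of every track, then decode."""
    lookup = {tuple(s): t for t, s in codebook.entries.items()}
    for track in tracks:
        track.called = []
        track.ambiguous = []
        for c in range(track.n_cycles):
            if track.det_ids[c] == MISSING:
                track.called.append(MISSING)
                track.ambiguous.append(False)
                continue
            ch, status = call_color(track.intensities[c], ambiguity_ratio)
            track.called.append(ch)
            track.ambiguous.append(status == "ambiguous")
        if any(c == MISSING for c in track.called) or not track.is_complete:
            track.target_id, track.reason = UNASSIGNED, "incomplete"
        elif any(track.ambiguous):
            track.target_id, track.reason = UNASSIGNED, "ambiguous"
        else:
            hit = lookup.get(tuple(track.called))
            if hit is None:
                track.target_id, track.reason = UNASSIGNED, "no-codebook-match"
            else:
                track.target_id, track.reason = hit, ""
    return tracks


def assign_cells(tracks: list[SpotTrack], cell_mask: np.ndarray) -> None:
    """Set each track's cell id from the mask label at its anchor."""
    H, W = cell_mask.shape
    for t in tracks:
        r = int(round(t.anchor_row))
        c = int(round(t.anchor_col))
        if 0 <= r < H and 0 <= c < W:
            t.cell_id = int(cell_mask[r, c])
        else:
            t.cell_id = 0


def copy_number(
    tracks: list[SpotTrack], cell_mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-cell per-target copy numbers from complete, decoded tracks.

    Only tracks present in every cycle and decoded to a codebook target are
    counted — the all-cycles counting rule.  Tracks outside every cell
    (mask label 0) are excluded.  Returns a long-format table
    ``cell_id, target_id, count``.
    """
    if cell_mask is not None:
        if cell_mask.ndim != 2:
            raise ValueError("cell mask must be a 2D label image")
        assign_cells(tracks, cell_mask)
    counts: dict[tuple[int, str], int] = {}
    for t in tracks:
        if t.is_decoded and t.is_complete and t.cell_id > 0:
            key = (t.cell_id, t.target_id)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        dict(cell_id=cell, target_id=target, count=n)
        for (cell, target), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["cell_id", "target_id", "count"])


def qc_metrics(tracks: list[SpotTrack], channel_names=None) -> dict:
    """Tracking quality metrics mirroring the method's validation readouts.

    * ``reappearance_1_2`` — fraction of cycle-1 spots found again in
      cycle 2 (spots that vanish are attributed to non-specific binding);
    * ``real_signal_cycle3`` — among real-signal tracks (present in cycles
      1 and 2), the fraction also present in cycle 3;
    * ``real_signal_all_cycles`` — among real-signal tracks, the fraction
      present in every cycle;
    * ``cycles_present_histogram`` — number of tracks by how many cycles
      they appear in;
    * ``per_cycle`` — per-cycle mean called-channel intensity, spread of
      the non-called channels, and their ratio (signal-to-background).
    """
    out: dict = {"n_tracks": len(tracks)}
    if not tracks:
        return out
    n_cycles = tracks[0].n_cycles
    present = np.array([t.present for t in tracks])  # (n_tracks, n_cycles)
    out["reappearance_1_2"] = (
        float(present[:, 1].mean()) if n_cycles >= 2 else 1.0
    )
    real = present[:, 0] & (present[:, 1] if n_cycles >= 2 else True)
    out["n_real_signal"] = int(real.sum())
    if real.any():
        if n_cycles >= 3:
            out["real_signal_cycle3"] = float(present[real, 2].mean())
        out["real_signal_all_cycles"] = float(present[real].all(axis=1).mean())
    hist = np.bincount(present.sum(axis=1), minlength=n_cycles + 1)
    out["cycles_present_histogram"] = {
        int(k): int(v) for k, v in enumerate(hist) if v
    }

    per_cycle = []
    for c in range(n_cycles):
        called_I, other_I = [], []
        for t in tracks:
            if t.det_ids[c] == MISSING or not t.called:
                continue
            ch = t.called[c]
            if ch == MISSING or np.all(np.isnan(t.intensities[c])):
                continue
            called_I.append(t.intensities[c][ch])
            others = np.delete(t.intensities[c], ch)
            other_I.extend(others[~np.isnan(others)])
        entry = {"cycle": c + 1, "n": len(called_I)}
        if called_I:
            entry["mean_called_intensity"] = float(np.mean(called_I))
            spread = float(np.std(other_I)) if other_I else float("nan")
            entry["other_channel_spread"] = spread
            entry["signal_to_background"] = (
                float(np.mean(called_I) / spread) if spread and spread > 0 else float("nan")
            )
        per_cycle.append(entry)
    out["per_cycle"] = per_cycle
    return out


def tracks_to_frame(tracks: list[SpotTrack], channel_names=None) -> pd.DataFrame:
    """Flatten tracks into the tracks.csv layout."""
    rows = []
    for t in tracks:
        seq = "-".join(
            "." if c == MISSING else str(c) for c in (t.called or [MISSING] * t.n_cycles)
        )
        row = dict(
            track_id=t.track_id,
            anchor_row=t.anchor_row,
            anchor_col=t.anchor_col,
            cell_id=t.cell_id,
            n_present=t.n_present,
            is_real_signal=t.is_real_signal,
            is_complete=t.is_complete,
            called_sequence=seq,
            target_id=t.target_id,
            reason=t.reason,
        )
        for c in range(t.n_cycles):
            ch = t.called[c] if t.called else MISSING
            if channel_names is not None and ch != MISSING:
                row[f"call_c{c+1}"] = channel_names[ch]
            else:
                row[f"call_c{c+1}"] = "." if ch == MISSING else str(ch)
        for c in range(t.n_cycles):
            row[f"present_c{c+1}"] = t.det_ids[c] != MISSING
        rows.append(row)
    return pd.DataFrame(rows)


def qc_from_frame(tracks_df: pd.DataFrame) -> dict:
    """Presence-based QC metrics recomputed from a tracks.csv table.

    Covers the reappearance/survival metrics; the intensity-based
    ``per_cycle`` block needs the original intensity vectors and is only
    available from :func:`qc_metrics`.
    """
    out: dict = {"n_tracks": len(tracks_df)}
    if not len(tracks_df):
        return out
    pcols = sorted(
        (c for c in tracks_df.columns if c.startswith("present_c")),
        key=lambda c: int(c.split("present_c")[1]),
    )
    present = tracks_df[pcols].to_numpy(dtype=bool)
    n_cycles = present.shape[1]
    out["reappearance_1_2"] = float(present[:, 1].mean()) if n_cycles >= 2 else 1.0
    real = present[:, 0] & (present[:, 1] if n_cycles >= 2 else True)
    out["n_real_signal"] = int(real.sum())
    if real.any():
        if n_cycles >= 3:
            out["real_signal_cycle3"] = float(present[real, 2].mean())
        out["real_signal_all_cycles"] = float(present[real].all(axis=1).mean())
    hist = np.bincount(present.sum(axis=1), minlength=n_cycles + 1)
    out["cycles_present_histogram"] = {int(k): int(v) for k, v in enumerate(hist) if v}
    return out
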