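"""End-to-end decode pipeline and evaluation against ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .codebook import Codebook
from .decoder import (
    LinkResult,
    SpotTrack,
    copy_number,
    decode_tracks,
    link_tracks,
    qc_metrics,
    tracks_to_frame,
)
from .simulator import CycleStack
from .spotfinder import CycleOffsets, detect_stack

__all__ = ["DecodeRun", "run_decode", "evaluate_tracks"]


class DecodeRun:
    """Bundle of every artifact the decode pipeline produces."""

    def __init__(
        self,
        detections: pd.DataFrame,
        offsets: CycleOffsets,
        link: LinkResult,
        counts: pd.DataFrame,
        qc: dict,
        channel_names: list[str],
    ):
        self.detections = detections
        self.offsets = offsets
        self.link = link
        self.counts = counts
        self.qc = qc
        self.channel_names = channel_names

    @property
    def tracks(self) -> list[SpotTrack]:
        return self.link.tracks

    def tracks_frame(self) -> pd.DataFrame:
        return tracks_to_frame(self.tracks, self.channel_names)


def run_decode(
    stack: CycleStack,
    codebook: Codebook,
    psf_sigma: float = 1.3,
    min_snr: float = 5.0,
    radius_px: float = 2.0,
    ambiguity_ratio: float = 1.5,
) -> DecodeRun:
    """register -> detect -> measure -> link -> call -> decode -> count.

    The codebook must match the stack (cycle count and channel names).
    """
    if codebook.n_cycles != stack.n_cycles:
        raise ValueError(
            f"codebook has {codebook.n_cycles} cycles, stack has {stack.n_cycles}"
        )
    if codebook.channel_names != stack.channel_names:
        raise ValueError(
            "codebook channels "
            f"{codebook.channel_names} do not match stack channels "
            f"{stack.channel_names}"
        )
    detections, offsets = detect_stack(stack, psf_sigma=psf_sigma, min_snr=min_snr)
    link = link_tracks(detections, n_cycles=stack.n_cycles, radius_px=radius_px)
    decode_tracks(link.tracks, codebook, ambiguity_ratio=ambiguity_ratio)
    counts = copy_number(link.tracks, stack.cell_mask)
    qc = qc_metrics(link.tracks, stack.channel_names)
    qc["n_orphan_detections"] = int(len(link.orphans))
    return DecodeRun(detections, offsets, link, counts, qc, stack.channel_names)


def evaluate_tracks(
    tracks: list[SpotTrack],
    truth: pd.DataFrame,
    match_radius: float = 1.0,
) -> dict:
    """Score tracks against a simulator ground-truth table.

    True specific spots (``target_id != "NONSPECIFIC"``) are matched
    one-to-one to track anchors, greedily in ascending distance, within
    ``match_radius`` px in the cycle-1 frame.  Reported:

    * ``track_recall`` — matched true spots / true spots;
    * ``decoded_fraction`` — decoded tracks / true spots (sensitivity);
    * ``decode_error_rate`` — among decoded tracks matched to truth, the
      fraction assigned the wrong target;
    * ``precision`` — decoded tracks matched to a true spot of the decoded
      target / all decoded tracks.
    """
    specific = truth[truth["target_id"] != "NONSPECIFIC"].reset_index(drop=True)
    n_true = len(specific)
    out = {
        "n_true_specific": n_true,
        "n_tracks": len(tracks),
        "n_decoded": sum(t.is_decoded for t in tracks),
    }
    if n_true == 0 or not tracks:
        out.update(track_recall=0.0, decoded_fraction=0.0,
                   decode_error_rate=0.0, precision=0.0)
        return out
    anchors = np.array([[t.anchor_row, t.anchor_col] for t in tracks])
    true_pos = specific[["row", "col"]].to_numpy(dtype=float)
    tree = cKDTree(anchors)
    pairs: list[tuple[float, int, int]] = []
    for i, neigh in enumerate(tree.query_ball_point(true_pos, r=match_radius)):
        for ti in neigh:
            d = float(np.hypot(*(true_pos[i] - anchors[ti])))
            pairs.append((d, i, ti))
    pairs.sort()
    match_true: dict[int, int] = {}
    match_track: dict[int, int] = {}
    for d, i, ti in pairs:
        if i in match_true or ti in match_track:
            continue
        match_true[i] = ti
        match_track[ti] = i

    out["track_recall"] = len(match_true) / n_true
    out["decoded_fraction"] = out["n_decoded"] / n_true

    wrong = 0
    correct = 0
    n_decoded_matched = 0
    for ti, i in match_track.items():
        t = tracks[ti]
        if not t.is_decoded:
            continue
        n_decoded_matched += 1
        if t.target_id == specific.loc[i, "target_id"]:
            correct += 1
        else:
            wrong += 1
    out["decode_error_rate"] = wrong / n_decoded_matched if n_decoded_matched else 0.0
    out["precision"] = correct / out["n_decoded"] if out["n_decoded"] else 0.0
    return out
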