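import numpy as np
import pandas as pd
import pytest

from cfish.codebook import Codebook, generate_codebook
from cfish.decoder import (
    MISSING,
    UNASSIGNED,
    call_color,
    copy_number,
    decode_track,
    decode_tracks,
    link_tracks,
    qc_from_frame,
    qc_metrics,
    tracks_to_frame,
)
from cfish.pipeline import evaluate_tracks, run_decode
from cfish.simulator import simulate_detection_table, simulate_experiment

from conftest import alternating_codebook, clean_config, noisy_config


def det_frame(rows):
    """Detections from (cycle, row, col[, I0, I1]) tuples."""
    recs = []
    for k, r in enumerate(rows):
        cycle, row, col = r[:3]
        I0, I1 = (r[3], r[4]) if len(r) > 3 else (100.0, 5.0)
        recs.append(
            dict(det_id=k, cycle=cycle, row=row, col=col,
                 aligned_row=row, aligned_col=col,
                 I_Quasar570=I0, I_Cy5=I1)
        )
    return pd.DataFrame(recs)


class TestLinkTracks:
    def test_identical_positions_form_one_complete_track(self):
        det = det_frame([(c, 50.0, 50.0) for c in range(1, 5)])
        res = link_tracks(det, n_cycles=4)
        assert len(res.tracks) == 1
        assert res.tracks[0].is_complete
        assert res.tracks[0].is_real_signal
        assert len(res.orphans) == 0

    def test_colocalization_radius_is_strict_two_px(self):
        det = det_frame([(1, 50.0, 50.0), (2, 50.0, 52.5)])
        res = link_tracks(det, n_cycles=2)
        track = res.tracks[0]
        assert track.det_ids[1] == MISSING
        assert not track.is_real_signal
        assert list(res.orphans.det_id) == [1]
        # exactly 2.0 px is also not linked (strict inequality)
        det = det_frame([(1, 50.0, 50.0), (2, 50.0, 52.0)])
        assert link_tracks(det, n_cycles=2).tracks[0].det_ids[1] == MISSING
        det = det_frame([(1, 50.0, 50.0), (2, 50.0, 51.99)])
        assert link_tracks(det, n_cycles=2).tracks[0].det_ids[1] == 1

    def test_nearest_candidate_wins(self):
        det = det_frame([(1, 50.0, 50.0), (2, 50.0, 51.3), (2, 50.0, 50.4)])
        res = link_tracks(det, n_cycles=2)
        assert res.tracks[0].det_ids[1] == 2  # the 0.4 px candidate
        assert list(res.orphans.det_id) == [1]

    def test_one_to_one_assignment_no_sharing(self):
        det = det_frame(
            [(1, 50.0, 50.0), (1, 50.0, 53.0), (2, 50.0, 51.4), (2, 50.0, 51.8)]
        )
        res = link_tracks(det, n_cycles=2)
        claimed = [t.det_ids[1] for t in res.tracks]
        assert sorted(claimed) == [2, 3]
        assert len(set(claimed)) == 2

    def test_later_cycle_detections_never_seed_tracks(self):
        det = det_frame([(2, 80.0, 80.0), (3, 80.0, 80.0)])
        res = link_tracks(det, n_cycles=3)
        assert res.tracks == []
        assert sorted(res.orphans.det_id) == [0, 1]

    def test_linking_correct_on_simulated_tables(self):
        det, truth = simulate_detection_table(
            500, 6, detect_prob=0.99, jitter_sigma=0.15, seed=12
        )
        res = link_tracks(det, n_cycles=6)
        assert len(res.tracks) == 500
        # track presence must reproduce the truth presence table
        present = np.array([t.present for t in res.tracks])
        tcols = truth[[f"present_c{c}" for c in range(1, 7)]].to_numpy()
        assert (present == tcols).mean() >= 0.99


class TestCallColor:
    @pytest.mark.parametrize(
        "vec, channel, status",
        [
            ((100.0, 5.0), 0, "ok"),
            ((100.0, 100.0), 0, "ambiguous"),
            ((12.0, 3.0), 0, "ok"),          # weak spots stay callable
            ((3.0, 12.0), 1, "ok"),
            ((90.0, 70.0), 0, "ambiguous"),  # below the 1.5x ratio
            ((50.0, -10.0), 0, "ok"),        # non-positive runner-up
        ],
    )
    def test_threshold_free_argmax(self, vec, channel, status):
        got_channel, got_status = call_color(np.array(vec))
        assert got_channel == channel
        assert got_status == status

    def test_all_missing(self):
        ch, status = call_color(np.array([np.nan, np.nan]))
        assert ch == MISSING
        assert status == "missing"

    def test_custom_ratio(self):
        assert call_color(np.array([30.0, 20.0]), ambiguity_ratio=1.2)[1] == "ok"


class TestDecode:
    def test_alternating_sequence_decodes_to_gapdh(self, fig_codebook):
        det = det_frame(
            [(c, 40.0, 40.0, 100.0, 5.0) if c % 2 == 1 else (c, 40.0, 40.0, 5.0, 100.0)
             for c in range(1, 17)]
        )
        res = link_tracks(det, n_cycles=16)
        decode_tracks(res.tracks, fig_codebook)
        assert res.tracks[0].target_id == "GAPDH"

    def test_sequence_absent_from_codebook(self):
        cb = Codebook.from_entries({"a": (0, 0), "b": (1, 1)}, 2, 2)
        det = det_frame([(1, 40.0, 40.0, 100.0, 5.0), (2, 40.0, 40.0, 5.0, 100.0)])
        res = link_tracks(det, n_cycles=2)
        decode_tracks(res.tracks, cb)
        assert res.tracks[0].target_id == UNASSIGNED
        assert res.tracks[0].reason == "no-codebook-match"

    def test_missing_cycle_is_incomplete(self, fig_codebook):
        det = det_frame([(c, 40.0, 40.0) for c in range(1, 17) if c != 9])
        res = link_tracks(det, n_cycles=16)
        decode_tracks(res.tracks, fig_codebook)
        assert res.tracks[0].target_id == UNASSIGNED
        assert res.tracks[0].reason == "incomplete"

    def test_ambiguous_slot_blocks_decoding(self):
        cb = Codebook.from_entries({"a": (0, 0)}, 2, 2)
        det = det_frame([(1, 40.0, 40.0, 100.0, 5.0), (2, 40.0, 40.0, 100.0, 90.0)])
        res = link_tracks(det, n_cycles=2)
        decode_tracks(res.tracks, cb)
        assert res.tracks[0].reason == "ambiguous"

    def test_decode_track_single(self, fig_codebook):
        det = det_frame(
            [(c, 40.0, 40.0, 100.0, 5.0) if c % 2 == 1 else (c, 40.0, 40.0, 5.0, 100.0)
             for c in range(1, 17)]
        )
        res = link_tracks(det, n_cycles=16)
        decode_tracks(res.tracks, fig_codebook)
        assert decode_track(res.tracks[0], fig_codebook) == "GAPDH"


class TestCopyNumberAndConservation:
    def test_lossless_counts_equal_truth(self):
        cfg = clean_config(n_cycles=8, seed=21)
        cb = alternating_codebook(8)
        stack, truth = simulate_experiment(cfg, cb)
        run = run_decode(stack, cb, psf_sigma=cfg.psf_sigma)
        specific = truth[truth.target_id != "NONSPECIFIC"]
        expected = (
            specific.groupby(["cell_id", "target_id"]).size().reset_index(name="count")
        )
        got = run.counts.sort_values(["cell_id", "target_id"]).reset_index(drop=True)
        expected = expected.sort_values(["cell_id", "target_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            got, expected, check_dtype=False, check_like=True
        )

    def test_track_outside_cells_excluded(self):
        cb = Codebook.from_entries({"a": (0, 0)}, 2, 2)
        det = det_frame([(1, 5.0, 5.0, 100.0, 5.0), (2, 5.0, 5.0, 100.0, 5.0)])
        res = link_tracks(det, n_cycles=2)
        decode_tracks(res.tracks, cb)
        mask = np.zeros((20, 20), dtype=np.uint16)  # no cell anywhere
        counts = copy_number(res.tracks, mask)
        assert len(counts) == 0

    def test_mask_shape_validated(self):
        cb = Codebook.from_entries({"a": (0, 0)}, 2, 2)
        det = det_frame([(1, 5.0, 5.0), (2, 5.0, 5.0)])
        res = link_tracks(det, n_cycles=2)
        decode_tracks(res.tracks, cb)
        with pytest.raises(ValueError):
            copy_number(res.tracks, np.zeros((4, 4, 2)))

    def test_counting_conservation(self):
        # every detection ends in a track slot or in the orphan table
        det, _ = simulate_detection_table(
            300, 5, detect_prob=0.95, nonspecific_fraction=0.2, seed=5
        )
        res = link_tracks(det, n_cycles=5)
        linked = sum(t.n_present for t in res.tracks)
        assert linked + len(res.orphans) == len(det)
        # and every track is decoded or carries an UNASSIGNED reason
        cb = generate_codebook(2, 5, [f"t{i}" for i in range(32)])
        decode_tracks(res.tracks, cb)
        assert all(t.is_decoded or t.reason for t in res.tracks)


class TestQcMetrics:
    def test_perfect_conditions_reappearance_is_one(self):
        det, _ = simulate_detection_table(400, 3, detect_prob=1.0, seed=2)
        res = link_tracks(det, n_cycles=3)
        qc = qc_metrics(res.tracks)
        assert qc["reappearance_1_2"] == 1.0
        assert qc["real_signal_all_cycles"] == 1.0

    def test_nonspecific_fraction_sets_reappearance(self):
        # 15% single-cycle spurious spots: expected reappearance
        # 0.85 x 0.998, within 3 binomial standard errors
        n = 4000
        det, _ = simulate_detection_table(
            n, 2, detect_prob=0.998, nonspecific_fraction=0.15, seed=17
        )
        res = link_tracks(det, n_cycles=2)
        qc = qc_metrics(res.tracks)
        p = 0.85 * 0.998
        se = np.sqrt(p * (1 - p) / n)
        assert abs(qc["reappearance_1_2"] - p) < 3 * se

    def test_mean_intensity_grows_until_saturation(self):
        cfg = noisy_config(n_cycles=10, saturation_cap=16.0, seed=30)
        cb = alternating_codebook(10)
        stack, _ = simulate_experiment(cfg, cb)
        run = run_decode(stack, cb, psf_sigma=cfg.psf_sigma)
        means = [e["mean_called_intensity"] for e in run.qc["per_cycle"]]
        # doubling through cycle 5 (cap 16 = 2^4), then a plateau
        for c in range(4):
            assert means[c + 1] > 1.5 * means[c]
        assert means[9] < 1.5 * means[5]

    def test_empty_input(self):
        assert qc_metrics([]) == {"n_tracks": 0}

    def test_qc_from_frame_matches_qc_metrics(self):
        det, _ = simulate_detection_table(
            300, 4, detect_prob=0.9, nonspecific_fraction=0.1, seed=8
        )
        res = link_tracks(det, n_cycles=4)
        cb = generate_codebook(2, 4, [f"t{i}" for i in range(16)])
        decode_tracks(res.tracks, cb)
        direct = qc_metrics(res.tracks)
        via_frame = qc_from_frame(tracks_to_frame(res.tracks))
        for key in ("n_tracks", "reappearance_1_2", "n_real_signal",
                    "real_signal_cycle3", "real_signal_all_cycles",
                    "cycles_present_histogram"):
            assert direct[key] == via_frame[key]


class TestNonspecificRejection:
    def test_single_cycle_spots_never_decode(self):
        det, truth = simulate_detection_table(
            400, 4, detect_prob=1.0, nonspecific_fraction=0.25, seed=9
        )
        res = link_tracks(det, n_cycles=4)
        cb = generate_codebook(2, 4, [f"t{i}" for i in range(16)])
        decode_tracks(res.tracks, cb)
        ns_positions = truth.loc[truth.kind == "nonspecific", ["row", "col"]].to_numpy()
        for t in res.tracks:
            if t.is_decoded:
                d = np.hypot(
                    ns_positions[:, 0] - t.anchor_row,
                    ns_positions[:, 1] - t.anchor_col,
                ).min()
                assert d > 1.0  # decoded tracks are never non-specific spots


class TestEvaluateTracks:
    def test_perfect_pipeline_scores_perfectly(self):
        cfg = clean_config(n_cycles=6, seed=13)
        cb = alternating_codebook(6)
        stack, truth = simulate_experiment(cfg, cb)
        run = run_decode(stack, cb, psf_sigma=cfg.psf_sigma)
        ev = evaluate_tracks(run.tracks, truth)
        assert ev["track_recall"] == 1.0
        assert ev["decode_error_rate"] == 0.0
        assert ev["precision"] == 1.0
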