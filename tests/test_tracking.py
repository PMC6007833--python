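"""Frame-to-frame focus linking, split assignment and curation overrides."""

import numpy as np
import pandas as pd
import pytest

from parabtrack import lineage, tracking
from parabtrack.detection import Focus
from parabtrack.tracking import FocusTrack, link_foci, assign_splits, apply_overrides

from conftest import match_true_focus


def _focus(frame, px, cell=1):
    return Focus(cell_id=cell, frame=frame, position_px=px,
                 position_um=px * 0.1, intensity=100.0, validation_count=20)


def _single_cell_tree(cell=1):
    df = pd.DataFrame([{"frame": 0, "time_h": 0.0, "cell_id": cell,
                        "parent_id": None, "length_um": 4.0,
                        "new_pole_end": "left"}])
    return lineage.build_lineage(df)


class TestLinkFoci:
    def test_small_step_links_one_track(self):
        tracks = link_foci([_focus(0, 10), _focus(1, 12)], _single_cell_tree())
        assert len(tracks) == 1 and len(tracks[0].foci) == 2

    def test_large_step_splits_tracks(self):
        tracks = link_foci([_focus(0, 10), _focus(1, 17)], _single_cell_tree())
        assert len(tracks) == 2

    def test_every_focus_in_exactly_one_track(self):
        rng = np.random.default_rng(0)
        foci = [_focus(f, int(p))
                for f in range(20)
                for p in rng.integers(0, 60, rng.integers(1, 4))]
        tracks = link_foci(foci, _single_cell_tree())
        assigned = [id(f) for t in tracks for f in t.foci]
        assert sorted(assigned) == sorted(id(f) for f in foci)

    def test_single_focus_per_frame_infinite_step_single_track(self):
        rng = np.random.default_rng(1)
        foci = [_focus(f, int(rng.integers(0, 60))) for f in range(15)]
        tracks = link_foci(foci, _single_cell_tree(), max_step_px=np.inf)
        assert len(tracks) == 1

    def test_contested_link_resolved_by_distance(self):
        # two tracks at frame 0; single focus at frame 1 near both
        foci = [_focus(0, 10), _focus(0, 14), _focus(1, 13)]
        tracks = link_foci(foci, _single_cell_tree())
        winner = [t for t in tracks if len(t.foci) == 2]
        assert len(winner) == 1
        assert winner[0].foci[0].position_px == 14  # nearest previous focus

    def test_axis_flip_invariance(self):
        # flipping positions and the pole reference leaves links unchanged
        n_px = 41
        L = (n_px - 1) * 0.1
        foci_l = [_focus(0, 10), _focus(0, 30), _focus(1, 12), _focus(1, 28)]
        foci_r = [Focus(cell_id=1, frame=f.frame,
                        position_px=n_px - 1 - f.position_px,
                        position_um=L - f.position_um,
                        intensity=100.0, validation_count=20)
                  for f in foci_l]
        t_l = link_foci(foci_l, _single_cell_tree())
        t_r = link_foci(foci_r, _single_cell_tree())
        sig_l = sorted(tuple(round(f.position_um, 6) for f in t.foci) for t in t_l)
        sig_r = sorted(tuple(round(L - f.position_um, 6) for f in t.foci)
                       for t in t_r)
        assert sig_l == sig_r

    def test_synthetic_movie_link_agreement(self, pipeline_run):
        truth = pipeline_run["truth"]
        tracks = pipeline_run["tables"]["tracks"]
        lookup = match_true_focus(truth.foci)
        good = bad = 0
        for _, g in tracks.groupby("track_id"):
            rows = list(g.sort_values("frame").itertuples())
            for a, b in zip(rows, rows[1:]):
                ta = lookup(a.cell_id, a.frame, a.position_um)
                tb = lookup(b.cell_id, b.frame, b.position_um)
                if ta is None or tb is None:
                    continue
                good += ta == tb
                bad += ta != tb
        assert good / (good + bad) >= 0.95


def _division_tree():
    rows = [
        {"frame": 0, "time_h": 0.0, "cell_id": 1, "parent_id": None,
         "length_um": 5.0, "new_pole_end": "left"},
        {"frame": 1, "time_h": 0.25, "cell_id": 2, "parent_id": 1,
         "length_um": 3.0, "new_pole_end": "right"},
        {"frame": 1, "time_h": 0.25, "cell_id": 3, "parent_id": 1,
         "length_um": 2.0, "new_pole_end": "left"},
    ]
    return lineage.build_lineage(pd.DataFrame(rows))


class TestDivisionRemap:
    def test_track_continues_into_correct_daughter(self):
        # parent (new pole left) focus at 1.0 um -> inside daughter 2
        # (birth length 3.0, adjacent to the parent's new pole); daughter
        # coordinates are re-anchored at the plane: 3.0 - 1.0 = 2.0 um
        tree = _division_tree()
        foci = [
            _focus(0, 10, cell=1),
            Focus(cell_id=2, frame=1, position_px=20, position_um=2.0,
                  intensity=100.0, validation_count=20),
        ]
        tracks = link_foci(foci, tree)
        assert len(tracks) == 1
        assert [f.cell_id for f in tracks[0].foci] == [1, 2]

    def test_focus_beyond_plane_goes_to_other_daughter(self):
        tree = _division_tree()
        foci = [
            Focus(cell_id=1, frame=0, position_px=40, position_um=4.0,
                  intensity=100.0, validation_count=20),
            Focus(cell_id=3, frame=1, position_px=10, position_um=1.0,
                  intensity=100.0, validation_count=20),
        ]
        tracks = link_foci(foci, tree)
        assert len(tracks) == 1


class TestAssignSplits:
    def test_two_nearby_children_assigned(self):
        foci = [_focus(0, 30), _focus(1, 27), _focus(1, 34)]
        tracks = link_foci(foci, _single_cell_tree(), max_step_px=2.0)
        assert len(tracks) == 3
        tracks = assign_splits(tracks, _single_cell_tree())
        parent = next(t for t in tracks if t.foci[0].frame == 0)
        assert parent.child_track_ids is not None
        kids = {tid for tid in parent.child_track_ids}
        assert all(tracks[i - 1].parent_track_id == parent.track_id for i in kids)

    def test_three_candidates_suppressed(self, caplog):
        import logging
        foci = [_focus(0, 30), _focus(1, 26), _focus(1, 33), _focus(1, 38)]
        tracks = link_foci(foci, _single_cell_tree(), max_step_px=2.0)
        with caplog.at_level(logging.WARNING):
            tracks = assign_splits(tracks, _single_cell_tree())
        parent = next(t for t in tracks if t.foci[0].frame == 0)
        assert parent.child_track_ids is None
        assert "split candidates" in caplog.text

    def test_synthetic_split_assignment_accuracy(self, pipeline_run):
        truth = pipeline_run["truth"]
        tracks_df = pipeline_run["tables"]["tracks"]
        lookup = match_true_focus(truth.foci)
        # reconstruct proposals: child track -> (parent track, truth ids)
        first = tracks_df.sort_values("frame").groupby("track_id").first()
        last = tracks_df.sort_values("frame").groupby("track_id").last()
        true_splits = {
            int(s.parent_focus_id): {int(s.child_near_id), int(s.child_far_id)}
            for s in truth.splits.itertuples()
        }
        checked = correct = 0
        for tid, row in first.iterrows():
            pid = row.parent_track_id
            if pd.isna(pid):
                continue
            checked += 1
            child_true = lookup(row.cell_id, row.frame, row.position_um)
            p = last.loc[int(pid)]
            parent_true = lookup(p.cell_id, p.frame, p.position_um)
            if parent_true in true_splits and child_true in true_splits[parent_true]:
                correct += 1
        assert checked >= 2 * len(truth.splits) * 0.8
        assert correct / checked >= 0.9


class TestOverrides:
    def _tracks(self):
        t1 = FocusTrack(1, [_focus(0, 10), _focus(1, 12)])
        t2 = FocusTrack(2, [_focus(2, 14)])
        t3 = FocusTrack(3, [_focus(2, 30)])
        return [t1, t2, t3]

    def test_none_is_identity(self):
        tracks = self._tracks()
        assert apply_overrides(tracks, None) is tracks

    def test_empty_file_is_identity(self, tmp_path):
        f = tmp_path / "ov.txt"
        f.write_text("# nothing to do\n\n")
        tracks = apply_overrides(self._tracks(), f)
        assert [t.track_id for t in tracks] == [1, 2, 3]

    def test_merge_concatenates(self, tmp_path):
        f = tmp_path / "ov.txt"
        f.write_text("merge 2 1\n")
        tracks = apply_overrides(self._tracks(), f)
        t1 = next(t for t in tracks if t.track_id == 1)
        assert [fc.frame for fc in t1.foci] == [0, 1, 2]
        assert all(t.track_id != 2 for t in tracks)

    def test_split_and_unsplit(self, tmp_path):
        f = tmp_path / "ov.txt"
        f.write_text("split 1 2 3\nunsplit 1\n")
        tracks = apply_overrides(self._tracks(), f)
        t1 = next(t for t in tracks if t.track_id == 1)
        assert t1.child_track_ids is None

    def test_duplicate_frame_merge_rejected(self, tmp_path):
        f = tmp_path / "ov.txt"
        f.write_text("merge 3 2\n")  # both tracks have a focus at frame 2
        with pytest.raises(ValueError, match="duplicate"):
            apply_overrides(self._tracks(), f)

    def test_dangling_id_is_hard_error(self, tmp_path):
        f = tmp_path / "ov.txt"
        f.write_text("merge 99 1\n")
        with pytest.raises(ValueError, match="unknown track id"):
            apply_overrides(self._tracks(), f)
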