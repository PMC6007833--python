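"""Temporal linking of ParB foci into tracks, splits and curation overrides.

Foci in consecutive frames are connected when they lie within a maximum
pole-relative pixel displacement of each other (greedy nearest-neighbour,
closest pair first).  Across a cell division, a parent-cell focus is first
remapped into the coordinate frame of the daughter whose segment contains
it — daughters are anchored at their own new pole, the division-plane end —
and may then continue its track inside that daughter.

A focus split (one spot becoming two at origin-region duplication) shows up
as a track that ends while two new tracks begin nearby in the next frame;
such configurations are proposed automatically and can be corrected through
a plain-text override file, which stands in for manual curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .detection import Focus
from .lineage import LineageTree

logger = logging.getLogger(__name__)


@dataclass
class FocusTrack:
    track_id: int
    foci: list[Focus] = field(default_factory=list)
    parent_track_id: int | None = None
    child_track_ids: tuple[int, int] | None = None

    @property
    def start_frame(self) -> int:
        return self.foci[0].frame

    @property
    def end_frame(self) -> int:
        return self.foci[-1].frame

    @property
    def cell_ids(self) -> list[int]:
        seen: list[int] = []
        for f in self.foci:
            if not seen or seen[-1] != f.cell_id:
                seen.append(f.cell_id)
        return seen


def _daughter_remap(
    tree: LineageTree, parent_id: int, pos_um: float
) -> tuple[int, float] | None:
    """Map a parent-cell new-pole-relative position into its daughter.

    The daughter adjacent to the parent's new pole is the one whose
    ``new_pole_end`` label differs from the parent's (its old pole is the
    parent's new pole).  Positions within that daughter's birth length stay
    on the new-pole side of the plane; the rest belong to the other
    daughter.  Both daughters are re-anchored at the plane (their new
    pole).  Returns ``(daughter_id, position_um)`` or None if the tree has
    no daughters for this cell.
    """
    if parent_id not in tree.children:
        return None
    d1, d2 = tree.children[parent_id]
    parent_pole = tree.cells[parent_id].new_pole_end
    if tree.cells[d1].new_pole_end != parent_pole:
        near, far = d1, d2
    else:
        near, far = d2, d1
    l_near = tree.cells[near].birth_length
    if pos_um < l_near:
        return near, l_near - pos_um
    return far, pos_um - l_near


def link_foci(
    foci: list[Focus],
    tree: LineageTree,
    max_step_px: float = 5.0,
    pixel_size: float = 0.1,
) -> list[FocusTrack]:
    """Greedily link validated foci frame-to-frame into tracks.

    Candidate links connect a track's last focus at frame t to a focus at
    frame t+1 in the same cell (or, across a division, in the daughter the
    parent's position remaps into) with pole-relative displacement of at
    most ``max_step_px`` pixels.  Closest pairs win; ties prefer the lower
    position.  Unlinked foci seed new tracks.
    """
    by_frame: dict[int, list[Focus]] = {}
    for f in foci:
        by_frame.setdefault(f.frame, []).append(f)
    tracks: list[FocusTrack] = []
    open_tracks: list[FocusTrack] = []
    for frame in sorted(by_frame):
        current = by_frame[frame]
        # candidate (distance, tie, track, focus) across all open tracks
        cands = []
        for tr in open_tracks:
            last = tr.foci[-1]
            if last.frame != frame - 1:
                continue
            for fc in current:
                if fc.cell_id == last.cell_id:
                    pred_um = last.position_um
                elif (remap := _daughter_remap(tree, last.cell_id, last.position_um)) \
                        and remap[0] == fc.cell_id:
                    pred_um = remap[1]
                else:
                    continue
                d_px = abs(fc.position_um - pred_um) / pixel_size
                if d_px <= max_step_px:
                    cands.append((d_px, fc.position_um, tr, fc))
        cands.sort(key=lambda c: (c[0], c[1]))
        used_tracks, used_foci = set(), set()
        for d_px, _, tr, fc in cands:
            if id(tr) in used_tracks or id(fc) in used_foci:
                continue
            tr.foci.append(fc)
            used_tracks.add(id(tr))
            used_foci.add(id(fc))
        leftover = [fc for fc in current if id(fc) not in used_foci]
        if len({id(c[3]) for c in cands}) > len(used_foci):
            logger.debug("frame %d: %d contested links resolved by distance",
                         frame, len(cands) - len(used_foci))
        for fc in leftover:
            nt = FocusTrack(track_id=len(tracks) + 1, foci=[fc])
            tracks.append(nt)
            open_tracks.append(nt)
        open_tracks = [t for t in open_tracks if t.end_frame == frame]
    return tracks


def assign_splits(
    tracks: list[FocusTrack],
    tree: LineageTree,
    split_radius_px: float = 10.0,
    pixel_size: float = 0.1,
) -> list[FocusTrack]:
    """Propose parent/child links for focus splits.

    A track ending at frame t whose end position has exactly two tracks
    starting at frame t+1 within ``split_radius_px`` (same cell, or the
    daughter the end position remaps into) becomes their parent.  More
    than two candidates suppresses the proposal and logs a warning for
    manual override.
    """
    starts: dict[int, list[FocusTrack]] = {}
    for tr in tracks:
        starts.setdefault(tr.start_frame, []).append(tr)
    for tr in tracks:
        if tr.child_track_ids is not None:
            continue
        last = tr.foci[-1]
        nxt = starts.get(last.frame + 1, [])
        cands = []
        for other in nxt:
            first = other.foci[0]
            if first.cell_id == last.cell_id:
                pred_um = last.position_um
            elif (remap := _daughter_remap(tree, last.cell_id, last.position_um)) \
                    and remap[0] == first.cell_id:
                pred_um = remap[1]
            else:
                continue
            if abs(first.position_um - pred_um) / pixel_size <= split_radius_px:
                cands.append(other)
        if len(cands) == 2:
            a, b = sorted(cands, key=lambda t: t.track_id)
            tr.child_track_ids = (a.track_id, b.track_id)
            a.parent_track_id = tr.track_id
            b.parent_track_id = tr.track_id
        elif len(cands) > 2:
            logger.warning("track %d: %d split candidates, needs manual override",
                           tr.track_id, len(cands))
    return tracks


# ---------------------------------------------------------------------------
# Manual-curation overrides
# ---------------------------------------------------------------------------

def apply_overrides(
    tracks: list[FocusTrack], override_file: str | Path | None
) -> list[FocusTrack]:
    """Apply plain-text curation commands, in file order.

    Supported commands (one per line, ``#`` comments allowed)::

        merge <src_track> <dst_track>     # append src's foci onto dst
        split <parent> <child_a> <child_b>
        unsplit <parent>                  # remove a split assignment

    Dangling track ids are a hard error; a merge that would give a track
    two foci in one frame is rejected.
    """
    if override_file is None:
        return tracks
    text = Path(override_file).read_text()
    by_id = {t.track_id: t for t in tracks}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        cmd, args = parts[0], [int(a) for a in parts[1:]]
        for a in args:
            if a not in by_id:
                raise ValueError(f"line {lineno}: unknown track id {a}")
        if cmd == "merge":
            src, dst = (by_id[a] for a in args)
            frames = {f.frame for f in dst.foci}
            if frames & {f.frame for f in src.foci}:
                raise ValueError(
                    f"line {lineno}: merge would duplicate a frame in track {dst.track_id}"
                )
            dst.foci = sorted(dst.foci + src.foci, key=lambda f: f.frame)
            tracks = [t for t in tracks if t.track_id != src.track_id]
            by_id.pop(src.track_id)
        elif cmd == "split":
            parent, a, b = (by_id[x] for x in args)
            parent.child_track_ids = (a.track_id, b.track_id)
            a.parent_track_id = parent.track_id
            b.parent_track_id = parent.track_id
        elif cmd == "unsplit":
            parent = by_id[args[0]]
            if parent.child_track_ids:
                for cid in parent.child_track_ids:
                    if cid in by_id:
                        by_id[cid].parent_track_id = None
            parent.child_track_ids = None
        else:
            raise ValueError(f"line {lineno}: unknown command {cmd!r}")
    _check_invariants(tracks)
    return tracks


def _check_invariants(tracks: list[FocusTrack]) -> None:
    for t in tracks:
        frames = [f.frame for f in t.foci]
        if len(frames) != len(set(frames)):
            raise ValueError(f"track {t.track_id}: more than one focus in a frame")
        if t.child_track_ids is not None and len(t.child_track_ids) != 2:
            raise ValueError(f"track {t.track_id}: splits need exactly 2 children")


def tracks_to_table(tracks: list[FocusTrack]) -> pd.DataFrame:
    """Long-format track table: track_id, cell_id, frame, position_um, parent_track_id."""
    rows = [
        {"track_id": t.track_id, "cell_id": f.cell_id, "frame": f.frame,
         "position_um": f.position_um, "parent_track_id": t.parent_track_id}
        for t in tracks for f in t.foci
    ]
    return pd.DataFrame(
        rows, columns=["track_id", "cell_id", "frame", "position_um", "parent_track_id"]
    )
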