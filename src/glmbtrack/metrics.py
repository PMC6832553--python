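"""OSPA and OSPA(2) multi-object miss-distances.

OSPA compares two finite point sets with a cutoff ``c`` and order ``p``,
splitting the error into localization and cardinality parts.  OSPA(2)
compares two sets of *tracks* by applying the OSPA construction to a base
distance that averages the per-frame cutoff distance over a sliding time
window, charging ``c`` on frames where exactly one of the two tracks exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["OSPAParams", "OSPAResult", "ospa", "ospa2", "division_parent_accuracy"]


@dataclass
class OSPAParams:
    """Cutoff ``c`` (position units), order ``p`` >= 1, and window length
    ``w`` in frames (used by OSPA(2) only)."""

    c: float = 100.0
    p: float = 1.0
    w: int = 10

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("cutoff c must be positive")
        if self.p < 1:
            raise ValueError("order p must be >= 1")
        if self.w < 1:
            raise ValueError("window w must be >= 1")


@dataclass
class OSPAResult:
    total: float
    localization: float
    cardinality: float


def _empty_result() -> OSPAResult:
    return OSPAResult(0.0, 0.0, 0.0)


def ospa(X: np.ndarray, Y: np.ndarray, params: OSPAParams) -> OSPAResult:
    """Optimal subpattern assignment distance between two point sets.

    With m = |X| <= n = |Y|, the total is
    ((min_assignment sum min(d, c)^p + c^p (n - m)) / n)^(1/p); the
    localization and cardinality components split the two summands under the
    same normalization.  Two empty sets give 0 by convention.
    """
    X = np.atleast_2d(np.asarray(X, float)) if np.size(X) else np.zeros((0, 2))
    Y = np.atleast_2d(np.asarray(Y, float)) if np.size(Y) else np.zeros((0, 2))
    m, n = X.shape[0], Y.shape[0]
    if m == 0 and n == 0:
        return _empty_result()
    if m > n:
        X, Y = Y, X
        m, n = n, m
    c, p = params.c, params.p
    if m == 0:
        return OSPAResult(c, 0.0, c)
    D = np.linalg.norm(X[:, None, :] - Y[None, :, :], axis=2)
    Dc = np.minimum(D, c) ** p
    ri, ci = linear_sum_assignment(Dc)
    loc_sum = Dc[ri, ci].sum()
    card_sum = c**p * (n - m)
    total = ((loc_sum + card_sum) / n) ** (1.0 / p)
    return OSPAResult(
        total=float(total),
        localization=float((loc_sum / n) ** (1.0 / p)),
        cardinality=float((card_sum / n) ** (1.0 / p)),
    )


TrackSet = Mapping[object, Mapping[int, np.ndarray]]


def _track_base_distance(
    ta: Mapping[int, np.ndarray],
    tb: Mapping[int, np.ndarray],
    frames: Sequence[int],
    c: float,
) -> float:
    """Window-averaged cutoff distance between two tracks.

    Frames where both tracks are absent contribute nothing; the average is
    over frames where at least one exists (0 if neither ever exists).
    """
    num = 0.0
    cnt = 0
    for k in frames:
        a = ta.get(k)
        b = tb.get(k)
        if a is None and b is None:
            continue
        cnt += 1
        if a is None or b is None:
            num += c
        else:
            num += min(float(np.linalg.norm(np.asarray(a) - np.asarray(b))), c)
    return num / cnt if cnt else 0.0


def ospa2(
    tracks_x: TrackSet,
    tracks_y: TrackSet,
    params: OSPAParams,
    frames: Optional[Sequence[int]] = None,
) -> List[OSPAResult]:
    """Per-frame OSPA(2) between two track sets.

    Each track is a mapping frame -> position (gaps allowed).  At frame k the
    base distance between two tracks averages the existence-aware cutoff
    distance over the window of the last ``w`` frames ending at k; the OSPA
    formula is then applied over the two track sets, counting only tracks
    that exist somewhere inside the window.
    """
    if frames is None:
        all_frames = set()
        for ts in (tracks_x, tracks_y):
            for t in ts.values():
                all_frames.update(t.keys())
        frames = sorted(all_frames)
    c, p, w = params.c, params.p, params.w
    out: List[OSPAResult] = []
    xs = list(tracks_x.values())
    ys = list(tracks_y.values())
    for k in frames:
        win = [q for q in range(k - w + 1, k + 1)]
        ax = [t for t in xs if any(q in t for q in win)]
        ay = [t for t in ys if any(q in t for q in win)]
        m, n = len(ax), len(ay)
        if m == 0 and n == 0:
            out.append(_empty_result())
            continue
        if m > n:
            ax, ay = ay, ax
            m, n = n, m
        if m == 0:
            out.append(OSPAResult(c, 0.0, c))
            continue
        D = np.array(
            [[_track_base_distance(ta, tb, win, c) ** p for tb in ay] for ta in ax]
        )
        ri, ci = linear_sum_assignment(D)
        loc_sum = D[ri, ci].sum()
        card_sum = c**p * (n - m)
        out.append(
            OSPAResult(
                total=float(((loc_sum + card_sum) / n) ** (1.0 / p)),
                localization=float((loc_sum / n) ** (1.0 / p)),
                cardinality=float((card_sum / n) ** (1.0 / p)),
            )
        )
    return out


def _match_tracks(
    truth_tracks: TrackSet,
    est_tracks: TrackSet,
    max_dist: float,
) -> Dict[object, object]:
    """One-to-one match of estimated to true tracks by mean overlap distance.

    Pairs must share at least one frame and have mean position distance below
    ``max_dist``; the assignment minimizes total distance (Hungarian over the
    padded cost matrix).  Returns {est_id: truth_id}.
    """
    tids = list(truth_tracks)
    eids = list(est_tracks)
    if not tids or not eids:
        return {}
    big = 10.0 * max_dist
    C = np.full((len(eids), len(tids)), big)
    for i, e in enumerate(eids):
        te = est_tracks[e]
        for j, t in enumerate(tids):
            tt = truth_tracks[t]
            common = set(te) & set(tt)
            if not common:
                continue
            d = np.mean(
                [np.linalg.norm(np.asarray(te[k]) - np.asarray(tt[k])) for k in common]
            )
            if d < max_dist:
                C[i, j] = d
    ri, ci = linear_sum_assignment(C)
    return {eids[i]: tids[j] for i, j in zip(ri, ci) if C[i, j] < max_dist}


def division_parent_accuracy(
    truth,
    trajectories,
    max_dist: float = 30.0,
    birth_slack: int = 3,
):
    """Fraction of true divisions recovered with the correct decoded parent.

    ``truth`` is a scenario :class:`~glmbtrack.scenarios.GroundTruth` with
    lineage; ``trajectories`` are estimator outputs whose spawn labels encode
    ancestry.  Division events are scored locally (in the spirit of the Cell
    Tracking Challenge lineage measures): a true division (parent p,
    daughter d born at frame b) counts as correct when some spawn-labelled
    track starts within ``birth_slack`` frames of b, follows the true
    daughter over its first few frames (mean distance < ``max_dist``), and
    its decoded parent track lies within ``max_dist`` of the true parent
    just before the division.  Scoring locally means later identity drift of
    either track does not disqualify a correctly detected division.
    Returns (n_correct, n_divisions).
    """
    truth_tracks = {t.track_id: t for t in truth.tracks}
    by_label = {t.label: t for t in trajectories}

    def traj_pos(traj, frame):
        i = frame - traj.birth_frame
        if 0 <= i < len(traj.components):
            return traj.components[i].mean[:2]
        return None

    def truth_pos(tt, frame):
        s = tt.state_at(frame)
        return None if s is None else s[:2]

    correct = 0
    divisions = truth.divisions()
    for parent_id, daughter_id, b in divisions:
        td = truth_tracks[daughter_id]
        tp = truth_tracks[parent_id]
        ok = False
        for traj in trajectories:
            if traj.parent is None or not (b <= traj.birth_frame <= b + birth_slack):
                continue
            # daughter correspondence over its first few frames
            ds = []
            for k in range(traj.birth_frame, min(traj.birth_frame + 5, traj.last_frame + 1)):
                a, bb = traj_pos(traj, k), truth_pos(td, k)
                if a is not None and bb is not None:
                    ds.append(np.linalg.norm(a - bb))
            if not ds or np.mean(ds) >= max_dist:
                continue
            ptraj = by_label.get(traj.parent)
            if ptraj is None:
                continue
            # parent correspondence just before the division
            ps = []
            for k in range(b - 3, b):
                a, bb = traj_pos(ptraj, k), truth_pos(tp, k)
                if a is not None and bb is not None:
                    ps.append(np.linalg.norm(a - bb))
            if ps and np.mean(ps) < max_dist:
                ok = True
                break
        correct += ok
    return correct, len(divisions)
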