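"""Multi-scan estimator: MAP extraction, trajectory-tuple bookkeeping,
short-track pruning, and per-trajectory forward filtering with RTS/URTS
backward smoothing.

The estimator consumes only trajectory tuples (label, birth state,
association history) accumulated during forward GLMB filtering; because a
whole trajectory is estimated at once, its output is fragmentation-free by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .filter import GLMBDensity, GLMBHypothesis, ModelSet, Scan
from .models import GaussianComponent, Label
from .smoothing import GaussianTrack, kf_predict, kf_update, rts_smooth, urts_smooth

__all__ = [
    "TrajectoryTuple",
    "SmoothedTrajectory",
    "map_estimate",
    "update_trajectory_tuples",
    "prune_short",
    "smooth_trajectories",
    "fragmentation_count",
]


@dataclass(eq=False)
class TrajectoryTuple:
    """(label, birth frame + state, association history) record.

    ``history`` has one entry per frame from birth to last-seen; entry 0
    means miss-detection, entry j > 0 indexes measurement j (1-based) of
    that frame's scan.
    """

    label: Label
    birth_frame: int
    birth_state: GaussianComponent
    history: Tuple[int, ...]

    @property
    def last_frame(self) -> int:
        return self.birth_frame + len(self.history) - 1

    @property
    def lifetime(self) -> int:
        return len(self.history)


@dataclass(eq=False)
class SmoothedTrajectory:
    """Smoothed per-frame Gaussian sequence for one label, with decoded
    parent (None for founding births)."""

    label: Label
    parent: Optional[Label]
    birth_frame: int
    components: List[GaussianComponent]

    @property
    def last_frame(self) -> int:
        return self.birth_frame + len(self.components) - 1

    def positions(self) -> np.ndarray:
        return np.array([c.mean[:2] for c in self.components])


def map_estimate(
    glmb: GLMBDensity,
) -> Tuple[int, GLMBHypothesis, Dict[Label, np.ndarray]]:
    """MAP multi-object estimate.

    The cardinality distribution rho(n) sums hypothesis weights by label-set
    size; N-hat maximizes rho (ties to the smaller cardinality) and the
    returned hypothesis is the heaviest one with exactly N-hat labels (ties
    by insertion order).
    """
    if not glmb.hypotheses:
        raise ValueError("cannot estimate from an empty density")
    rho = glmb.cardinality_distribution()
    n_hat = int(np.argmax(rho))  # argmax returns the first (smallest) maximizer
    best = None
    for h in glmb.hypotheses:
        if h.cardinality != n_hat:
            continue
        if best is None or h.log_weight > best.log_weight:
            best = h
    assert best is not None
    states = {t.label: t.comp.mean.copy() for t in best.tracks}
    return n_hat, best, states


def tuples_from_hypothesis(hyp: GLMBHypothesis) -> List[TrajectoryTuple]:
    return [
        TrajectoryTuple(t.label, t.birth_frame, t.birth_state, tuple(t.history))
        for t in hyp.tracks
    ]


def update_trajectory_tuples(
    accumulated: Iterable[TrajectoryTuple],
    current: Iterable[TrajectoryTuple],
) -> List[TrajectoryTuple]:
    """Merge the current frame's MAP tuples into the accumulated set.

    A label present in both gets its tuple replaced (full-history rewrite);
    new labels are appended; labels absent from the current estimate are
    retained unchanged (a track keeps its last stored history).
    """
    acc: Dict[Label, TrajectoryTuple] = {}
    for t in accumulated:
        if t.label in acc:
            raise ValueError(f"duplicate label {t.label} in accumulated tuples")
        acc[t.label] = t
    seen = set()
    for t in current:
        if t.label in seen:
            raise ValueError(f"duplicate label {t.label} in current tuples")
        seen.add(t.label)
        acc[t.label] = t
    return list(acc.values())


def prune_short(
    trajectories: Iterable[TrajectoryTuple], tau_t: int
) -> List[TrajectoryTuple]:
    """Remove trajectories whose lifetime (history length) is < tau_t frames."""
    if tau_t < 0:
        raise ValueError("pruning threshold must be nonnegative")
    return [t for t in trajectories if t.lifetime >= tau_t]


def forward_filter_tuple(
    tup: TrajectoryTuple, scans: Sequence[Scan], models: ModelSet
) -> GaussianTrack:
    """Forward pass of one trajectory: seeded from the birth state, updated
    with the associated measurement when the history says detect, predicted
    only on miss frames."""
    scan_by_frame = {s.frame: s for s in scans}
    comps: List[GaussianComponent] = []
    detected: List[bool] = []
    comp = tup.birth_state.copy()
    for step, j in enumerate(tup.history):
        frame = tup.birth_frame + step
        if step > 0:
            comp = kf_predict(comp, models.motion, models.ut)
        if j > 0:
            scan = scan_by_frame.get(frame)
            if scan is None or j > scan.n_meas:
                raise ValueError(
                    f"track {tup.label}: history points at measurement {j} "
                    f"of frame {frame}, which does not exist"
                )
            comp, _ = kf_update(comp, scan.Z[j - 1], models.obs, models.ut)
            detected.append(True)
        else:
            detected.append(False)
        comps.append(comp)
    return GaussianTrack(tup.birth_frame, comps, detected)


def smooth_trajectories(
    trajectories: Iterable[TrajectoryTuple],
    scans: Sequence[Scan],
    models: ModelSet,
) -> List[SmoothedTrajectory]:
    """Forward filter then backward smooth every trajectory tuple.

    Linear motion uses the RTS recursion, nonlinear motion the unscented
    variant.  Output count equals input count and each label appears exactly
    once, so the result is fragmentation-free by construction.
    """
    out: List[SmoothedTrajectory] = []
    for tup in trajectories:
        filtered = forward_filter_tuple(tup, scans, models)
        if models.motion.is_linear:
            smoothed = rts_smooth(filtered, models.motion)
        else:
            smoothed = urts_smooth(filtered, models.motion, models.ut)
        out.append(
            SmoothedTrajectory(
                label=tup.label,
                parent=tup.label.parent,
                birth_frame=tup.birth_frame,
                components=list(smoothed.components),
            )
        )
    labels = [t.label for t in out]
    assert len(set(labels)) == len(labels)
    return out


def fragmentation_count(trajectories: Iterable[SmoothedTrajectory]) -> int:
    """Number of extra maximal contiguous segments per label, summed.

    Each SmoothedTrajectory is one contiguous frame range per label, so this
    is identically 0 on estimator output; exposed so runs can assert it.
    """
    by_label: Dict[Label, set] = {}
    for t in trajectories:
        by_label.setdefault(t.label, set()).update(
            range(t.birth_frame, t.last_frame + 1)
        )
    frag = 0
    for frames in by_label.values():
        ordered = sorted(frames)
        segments = 1 + sum(
            1 for a, b in zip(ordered, ordered[1:]) if b > a + 1
        )
        frag += segments - 1
    return frag
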