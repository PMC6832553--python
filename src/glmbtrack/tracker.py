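"""End-to-end tracker: forward GLMB filtering over a scan sequence, then the
multi-scan estimator (pruning + per-trajectory smoothing)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .estimator import (
    SmoothedTrajectory,
    TrajectoryTuple,
    map_estimate,
    prune_short,
    smooth_trajectories,
    tuples_from_hypothesis,
    update_trajectory_tuples,
)
from .filter import (
    FilterSettings,
    ModelSet,
    Scan,
    empty_density,
    hybrid_joint_predict_update,
    joint_predict_update,
    spawning_joint_predict_update,
)
from .models import BirthModel, Label

__all__ = ["TrackerResult", "FrameLog", "run_tracker"]


@dataclass
class FrameLog:
    frame: int
    n_meas: int
    n_hyp_pre: int
    n_hyp_post: int
    map_cardinality: int
    effective_n_hyp: float


@dataclass
class TrackerResult:
    """Filter-only per-frame estimates plus the smoothed trajectory set."""

    mode: str
    filter_estimates: List[Dict[Label, np.ndarray]]  # per frame: label -> state mean
    map_cardinalities: List[int]
    trajectories: List[SmoothedTrajectory]
    pruned_count: int
    logs: List[FrameLog] = field(default_factory=list)

    def filter_positions(self, k: int) -> np.ndarray:
        est = self.filter_estimates[k]
        if not est:
            return np.zeros((0, 2))
        return np.array([m[:2] for m in est.values()])

    def smoothed_positions(self, frame: int) -> np.ndarray:
        pts = [
            t.components[frame - t.birth_frame].mean[:2]
            for t in self.trajectories
            if t.birth_frame <= frame <= t.last_frame
        ]
        return np.array(pts) if pts else np.zeros((0, 2))


def run_tracker(
    scans: Sequence[Scan],
    models: ModelSet,
    settings: Optional[FilterSettings] = None,
    rng: Optional[np.random.Generator] = None,
    mode: str = "standard",
    tau_t: int = 3,
    smooth: bool = True,
    lag: Optional[int] = None,
) -> TrackerResult:
    """Run forward GLMB filtering and the multi-scan estimator.

    ``mode`` is one of "standard", "hybrid" (point detections + raw image)
    or "spawning" (cell division).  ``tau_t`` prunes trajectories shorter
    than that many frames before smoothing; ``lag=None`` smooths the whole
    sequence (fixed-lag operation re-runs the estimator over a trailing
    window and is provided for completeness).
    """
    settings = settings or FilterSettings()
    rng = rng if rng is not None else np.random.default_rng()
    if mode not in ("standard", "hybrid", "spawning"):
        raise ValueError(f"unknown mode {mode!r}")
    update = {
        "standard": joint_predict_update,
        "hybrid": hybrid_joint_predict_update,
        "spawning": spawning_joint_predict_update,
    }[mode]

    birth = models.birth
    adaptive = isinstance(birth, BirthModel) and birth.adaptive
    prior = empty_density(frame=scans[0].frame - 1)
    accumulated: List[TrajectoryTuple] = []
    filter_estimates: List[Dict[Label, np.ndarray]] = []
    cardinalities: List[int] = []
    logs: List[FrameLog] = []
    prev_scan: Optional[Scan] = None
    prev_mass: Optional[np.ndarray] = None

    for i, scan in enumerate(scans):
        if adaptive:
            init_phase = i < birth.n_init_frames
            if i == 0:
                # bootstrap births from the first scan itself
                bcs = birth.adaptive_components(scan.Z, np.zeros(scan.n_meas), True)
            else:
                bcs = birth.adaptive_components(prev_scan.Z, prev_mass, init_phase)
        else:
            bcs = None
        post = update(prior, scan, models, settings, rng, birth_components=bcs)
        n_hat, hyp, states = map_estimate(post)
        accumulated = update_trajectory_tuples(accumulated, tuples_from_hypothesis(hyp))
        filter_estimates.append(states)
        cardinalities.append(n_hat)
        logs.append(
            FrameLog(
                frame=scan.frame,
                n_meas=scan.n_meas,
                n_hyp_pre=post.n_hyp_pre_truncation,
                n_hyp_post=len(post.hypotheses),
                map_cardinality=n_hat,
                effective_n_hyp=post.effective_n_hypotheses(),
            )
        )
        prev_scan, prev_mass = scan, post.assoc_mass
        prior = post

    kept = prune_short(accumulated, tau_t)
    pruned = len(accumulated) - len(kept)
    if lag is not None:
        last = scans[-1].frame
        kept = [t for t in kept if t.last_frame >= last - lag]
    if smooth:
        trajectories = smooth_trajectories(kept, scans, models)
    else:
        trajectories = []
    return TrackerResult(
        mode=mode,
        filter_estimates=filter_estimates,
        map_cardinalities=cardinalities,
        trajectories=trajectories,
        pruned_count=pruned,
        logs=logs,
    )
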