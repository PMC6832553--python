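"""Synthetic ground truth and observations.

Four scenario families exercise every tracking mode without any external
data: a linear constant-velocity scenario with position detections, a
constant-turn scenario with bearing-range detections over a half-disc, a
point-spread-function image scenario for hybrid track-before-detect, and a
dividing-cell sequence with spawn lineage.

Printed state vectors and diagonal covariances in the radar literature often
interleave position and velocity ([px, vx, py, vy]); the helpers here accept
that order and convert to the package's canonical [px, py, vx, vy(, w)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .filter import ModelSet, Scan
from .models import (
    BirthComponent,
    BirthModel,
    ClutterModel,
    DetectionModel,
    MotionModel,
    ObservationModel,
    PolarSupport,
    RectSupport,
    SpawnModel,
    make_bearing_range_model,
    make_ct_model,
    make_cv_model,
    make_image_psf_model,
    make_linear_position_model,
)

__all__ = [
    "ScenarioConfig",
    "TruthTrack",
    "GroundTruth",
    "default_config",
    "build_models",
    "generate_scenario",
    "generate_linear_scenario",
    "generate_ct_scenario",
    "generate_tbd_scenario",
    "generate_cell_scenario",
    "render_point_spread_image",
    "threshold_detections",
    "interleaved_to_canonical",
    "snr_to_intensity",
]


def interleaved_to_canonical(v: Sequence[float]) -> np.ndarray:
    """Reorder [px, vx, py, vy(, w)] -> [px, py, vx, vy(, w)]."""
    v = np.asarray(v, float).ravel()
    if v.size == 4:
        return v[[0, 2, 1, 3]]
    if v.size == 5:
        return v[[0, 2, 1, 3, 4]]
    raise ValueError("expected a 4- or 5-vector")


def snr_to_intensity(snr_db: float, sigma_h: float, sigma_y: float) -> float:
    """Blob intensity I from SNR(dB) = 20 log10(peak / sigma_y) with
    peak = I / (2 pi sigma_h)."""
    peak = sigma_y * 10.0 ** (snr_db / 20.0)
    return peak * 2.0 * math.pi * sigma_h


@dataclass
class TruthTrack:
    track_id: int
    parent_id: int  # 0 = founding track
    birth: int  # first frame (1-based)
    states: np.ndarray  # (lifetime, state_dim)

    @property
    def death(self) -> int:
        return self.birth + self.states.shape[0] - 1

    def state_at(self, k: int) -> Optional[np.ndarray]:
        if self.birth <= k <= self.death:
            return self.states[k - self.birth]
        return None


@dataclass
class GroundTruth:
    tracks: List[TruthTrack]
    K: int

    def alive(self, k: int) -> List[TruthTrack]:
        return [t for t in self.tracks if t.birth <= k <= t.death]

    def cardinality(self, k: int) -> int:
        return len(self.alive(k))

    def positions_at(self, k: int) -> np.ndarray:
        pts = [t.state_at(k)[:2] for t in self.alive(k)]
        return np.array(pts) if pts else np.zeros((0, 2))

    def track_dict(self) -> Dict[int, Dict[int, np.ndarray]]:
        return {
            t.track_id: {
                t.birth + i: t.states[i, :2] for i in range(t.states.shape[0])
            }
            for t in self.tracks
        }

    def divisions(self) -> List[Tuple[int, int, int]]:
        """(parent_id, daughter_id, daughter birth frame) for every division."""
        return [(t.parent_id, t.track_id, t.birth) for t in self.tracks if t.parent_id]


@dataclass
class ScenarioConfig:
    """Scenario parameters; :func:`default_config` fills the per-kind
    defaults used throughout the experiments."""

    kind: str  # linear | ct | tbd | cell
    K: int = 100
    dt: float = 1.0
    sigma_v: float = 5.0
    sigma_w: float = 0.0
    sigma_eps: float = 15.0
    sigma_theta: float = 0.0
    sigma_r: float = 0.0
    p_d: float = 0.95
    p_s: float = 0.99
    clutter_rate: float = 66.0
    birth_r: float = 0.03
    birth_sites: List[np.ndarray] = field(default_factory=list)
    birth_cov_diag: Optional[np.ndarray] = None
    region: Tuple[float, float, float, float] = (-1000.0, 1000.0, -1000.0, 1000.0)
    half_disc_radius: float = 0.0
    # schedule: (birth frame, site index, lifetime in frames)
    schedule: List[Tuple[int, int, int]] = field(default_factory=list)
    init_speed_std: float = 8.0
    # image / TBD
    image_size: Tuple[int, int] = (100, 100)
    sigma_h: float = 4.0
    sigma_y: float = 1.0
    snr_db_range: Tuple[float, float] = (7.0, 10.0)
    filter_snr_db: float = 10.0
    detect_threshold_frac: float = 0.4
    min_blob_area: int = 5
    # cell / spawning
    n_init_cells: int = 4
    p_spawn: float = 0.035
    spawn_cov_diag_interleaved: Tuple[float, ...] = (400.0, 5.0, 400.0, 5.0, np.pi / 90)
    max_cells: int = 20
    init_min_separation: float = 100.0  # sparse-culture placement (pixels)
    # true cell kinematics: much gentler than the tracker's deliberately
    # loose motion model (the filter noise absorbs model mismatch)
    truth_sigma_v: float = 0.5
    truth_sigma_w: float = np.pi / 90


def default_config(kind: str, **overrides) -> ScenarioConfig:
    if kind == "linear":
        cfg = ScenarioConfig(
            kind="linear",
            K=100,
            sigma_v=5.0,
            sigma_eps=15.0,
            p_d=0.95,
            p_s=0.99,
            clutter_rate=66.0,
            birth_r=0.03,
            birth_sites=[
                interleaved_to_canonical([0.1, 0.0, 0.1, 0.0]),
                interleaved_to_canonical([400.0, 0.0, -600.0, 0.0]),
                interleaved_to_canonical([-800.0, 0.0, -200.0, 0.0]),
                interleaved_to_canonical([-200.0, 0.0, 800.0, 0.0]),
            ],
            birth_cov_diag=np.array([10.0, 10.0, 10.0, 10.0]),
            region=(-1000.0, 1000.0, -1000.0, 1000.0),
            schedule=[
                (1, 0, 70), (1, 1, 60), (1, 2, 90), (1, 3, 50),
                (10, 0, 60), (15, 1, 70), (20, 2, 55), (25, 3, 45),
                (35, 0, 60), (45, 1, 50), (55, 2, 40), (65, 3, 35),
            ],
            init_speed_std=8.0,
        )
    elif kind == "ct":
        cfg = ScenarioConfig(
            kind="ct",
            K=100,
            sigma_v=5.0,
            sigma_w=np.pi / 180.0,
            sigma_theta=np.pi / 90.0,
            sigma_r=5.0,
            p_d=0.95,
            p_s=0.99,
            clutter_rate=66.0,
            birth_r=0.02,
            birth_sites=[
                interleaved_to_canonical([-1500.0, 0.0, 250.0, 0.0, np.pi / 180]),
                interleaved_to_canonical([-250.0, 0.0, 1000.0, 0.0, np.pi / 180]),
                interleaved_to_canonical([250.0, 0.0, 750.0, 0.0, np.pi / 180]),
                interleaved_to_canonical([1000.0, 0.0, 1500.0, 0.0, np.pi / 180]),
            ],
            birth_cov_diag=np.array([50.0, 50.0, 50.0, 50.0, np.pi / 30]),
            half_disc_radius=2000.0,
            schedule=[
                (1, 0, 80), (1, 1, 65), (10, 2, 70), (15, 3, 60),
                (25, 0, 55), (35, 1, 50), (45, 2, 45), (55, 3, 40),
            ],
            init_speed_std=8.0,
        )
    elif kind == "tbd":
        cfg = ScenarioConfig(
            kind="tbd",
            K=100,
            sigma_v=1.0,
            sigma_eps=4.0,
            p_d=0.9,
            p_s=0.98,
            clutter_rate=10.0,
            birth_r=0.03,
            birth_sites=[
                interleaved_to_canonical([5.0, 0.0, 25.0, 0.0]),
                interleaved_to_canonical([5.0, 0.0, 90.0, 0.0]),
                interleaved_to_canonical([80.0, 0.0, 90.0, 0.0]),
                interleaved_to_canonical([5.0, 0.0, 5.0, 0.0]),
                interleaved_to_canonical([90.0, 0.0, 30.0, 0.0]),
            ],
            birth_cov_diag=interleaved_to_canonical([3.0, 2.0, 3.0, 2.0]),
            region=(0.5, 100.5, 0.5, 100.5),
            image_size=(100, 100),
            sigma_h=4.0,
            sigma_y=1.0,
            schedule=[(1, 0, 80), (1, 1, 70), (10, 2, 75), (20, 3, 65), (30, 4, 60)],
            init_speed_std=0.6,
        )
    elif kind == "cell":
        cfg = ScenarioConfig(
            kind="cell",
            K=90,
            sigma_v=5.0,
            sigma_w=np.pi / 90.0,
            sigma_eps=2.0,
            p_d=0.88,
            p_s=0.999,
            clutter_rate=0.05,
            region=(0.0, 400.0, 0.0, 400.0),
            n_init_cells=4,
            p_spawn=0.035,
            init_speed_std=1.0,
        )
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Filter-side model construction
# ---------------------------------------------------------------------------


def build_models(cfg: ScenarioConfig) -> ModelSet:
    """Filter-side model set consistent with a scenario configuration."""
    if cfg.kind in ("linear", "tbd"):
        motion = make_cv_model(cfg.dt, cfg.sigma_v)
    else:
        motion = make_ct_model(cfg.dt, cfg.sigma_w, cfg.sigma_v)
    state_dim = motion.dim

    if cfg.kind == "ct":
        obs = make_bearing_range_model(cfg.sigma_theta, cfg.sigma_r)
        support = PolarSupport(r_max=cfg.half_disc_radius)
    else:
        obs = make_linear_position_model(cfg.sigma_eps, state_dim=state_dim)
        x0, x1, y0, y1 = cfg.region
        support = RectSupport([x0, y0], [x1, y1])
    clutter = ClutterModel(rate=cfg.clutter_rate, support=support)
    detection = DetectionModel(p_d=cfg.p_d, p_s=cfg.p_s)

    spawn = None
    image_obs = None
    if cfg.kind == "cell":
        qt = np.diag(interleaved_to_canonical(cfg.spawn_cov_diag_interleaved))
        spawn = SpawnModel(p_t=cfg.p_spawn, Q_t=qt, max_offspring=1)

        def pos_to_state(z):
            s = np.zeros(state_dim)
            s[:2] = z
            return s

        birth = BirthModel(
            adaptive=True,
            r_init=0.99,
            r_cap=1e-7,
            r0=1.0,
            birth_cov=np.diag([10.0, 10.0, 25.0, 25.0, (np.pi / 30) ** 2]),
            pos_to_state=pos_to_state,
        )
    else:
        comps = [
            BirthComponent(
                r=cfg.birth_r,
                mean=site,
                cov=np.diag(np.asarray(cfg.birth_cov_diag, float)),
                index=i + 1,
            )
            for i, site in enumerate(cfg.birth_sites)
        ]
        birth = BirthModel(components=comps)

    if cfg.kind == "tbd":
        w, h = cfg.image_size
        image_obs = make_image_psf_model(
            intensity=snr_to_intensity(cfg.filter_snr_db, cfg.sigma_h, cfg.sigma_y),
            sigma_h=cfg.sigma_h,
            sigma_y=cfg.sigma_y,
            width=w,
            height=h,
        )
    return ModelSet(
        motion=motion,
        obs=obs,
        birth=birth,
        clutter=clutter,
        detection=detection,
        spawn=spawn,
        image_obs=image_obs,
    )


# ---------------------------------------------------------------------------
# Truth propagation helpers
# ---------------------------------------------------------------------------


def _propagate_truth(
    x0: np.ndarray, lifetime: int, motion: MotionModel, rng: np.random.Generator
) -> np.ndarray:
    states = np.empty((lifetime, x0.size))
    states[0] = x0
    noiseless = np.all(motion.Q == 0.0)
    L = None if noiseless else np.linalg.cholesky(motion.Q + 1e-12 * np.eye(motion.dim))
    for i in range(1, lifetime):
        states[i] = motion.propagate(states[i - 1])
        if L is not None:
            states[i] += L @ rng.standard_normal(motion.dim)
    return states


def _scripted_truth(
    cfg: ScenarioConfig, motion: MotionModel, rng: np.random.Generator
) -> GroundTruth:
    tracks = []
    for tid, (birth, site, lifetime) in enumerate(cfg.schedule, start=1):
        if birth > cfg.K:
            continue
        x0 = np.array(cfg.birth_sites[site], float).copy()
        x0[2:4] += rng.normal(0.0, cfg.init_speed_std, size=2)
        life = min(lifetime, cfg.K - birth + 1)
        states = _propagate_truth(x0, life, motion, rng)
        tracks.append(TruthTrack(track_id=tid, parent_id=0, birth=birth, states=states))
    return GroundTruth(tracks=tracks, K=cfg.K)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_linear_scenario(
    cfg: Optional[ScenarioConfig] = None, seed: int = 0
) -> Tuple[GroundTruth, List[Scan]]:
    """Constant-velocity truth with position detections and uniform clutter."""
    cfg = cfg or default_config("linear")
    rng = np.random.default_rng(seed)
    models = build_models(cfg)
    truth = _scripted_truth(cfg, models.motion, rng)
    scans = _point_scans(truth, cfg, models, rng)
    return truth, scans


def generate_ct_scenario(
    cfg: Optional[ScenarioConfig] = None, seed: int = 0
) -> Tuple[GroundTruth, List[Scan]]:
    """Constant-turn truth with bearing-range detections over a half-disc."""
    cfg = cfg or default_config("ct")
    rng = np.random.default_rng(seed)
    models = build_models(cfg)
    truth = _scripted_truth(cfg, models.motion, rng)
    scans = _point_scans(truth, cfg, models, rng)
    return truth, scans


def _point_scans(
    truth: GroundTruth, cfg: ScenarioConfig, models: ModelSet, rng: np.random.Generator
) -> List[Scan]:
    obs = models.obs
    Lr = np.linalg.cholesky(obs.R)
    scans = []
    for k in range(1, cfg.K + 1):
        zs = []
        for t in truth.alive(k):
            if rng.random() < cfg.p_d:
                z = obs.h(t.state_at(k)) + Lr @ rng.standard_normal(obs.meas_dim)
                zs.append(z)
        clut = models.clutter.sample(rng)
        Zt = np.array(zs).reshape(len(zs), obs.meas_dim) if zs else np.zeros((0, obs.meas_dim))
        Z = np.vstack([Zt, np.asarray(clut, float).reshape(-1, obs.meas_dim)])
        if Z.shape[0]:
            Z = Z[rng.permutation(Z.shape[0])]
        scans.append(
            Scan(
                frame=k,
                Z=Z,
                meta={
                    "n_clutter": int(len(clut)),
                    "n_true_detections": len(zs),
                    "n_alive": truth.cardinality(k),
                },
            )
        )
    return scans


def render_point_spread_image(
    states: np.ndarray,
    obs: ObservationModel,
    rng: Optional[np.random.Generator] = None,
    intensities: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Image of Gaussian blobs plus pixel noise.

    Pixel (a, b) are 1-based centre coordinates with a = column and b = row;
    pixel i takes value sum_x I/(2 pi sigma_h) exp(-||(a,b)-p||^2 /
    (2 sigma_h^2)) + N(0, sigma_y^2).  ``intensities`` overrides the model
    intensity per object (used to vary SNR across objects)."""
    w, h = obs.width, obs.height
    a = np.arange(1, w + 1, dtype=float)
    b = np.arange(1, h + 1, dtype=float)
    A, B = np.meshgrid(a, b)
    img = np.zeros((h, w))
    states = np.atleast_2d(np.asarray(states, float)) if np.size(states) else np.zeros((0, 2))
    for i, s in enumerate(states):
        inten = obs.intensity if intensities is None else intensities[i]
        peak = inten / (2.0 * math.pi * obs.sigma_h)
        d2 = (A - s[0]) ** 2 + (B - s[1]) ** 2
        img += peak * np.exp(-d2 / (2.0 * obs.sigma_h**2))
    if rng is not None and obs.sigma_y > 0:
        img += rng.normal(0.0, obs.sigma_y, size=img.shape)
    return img


def threshold_detections(
    image: np.ndarray, tau: float, min_area: int = 1
) -> np.ndarray:
    """Hard-threshold point extraction: connected components of
    super-threshold pixels (8-connectivity) reduced to intensity-weighted
    centroids; components smaller than ``min_area`` pixels are discarded."""
    mask = image > tau
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    pts = []
    for comp in range(1, n + 1):
        idx = np.nonzero(labels == comp)
        if idx[0].size < min_area:
            continue
        wts = image[idx]
        wts = np.maximum(wts, 1e-12)
        # rows are b (y), columns are a (x); pixel centres are 1-based
        py = float(np.average(idx[0] + 1.0, weights=wts))
        px = float(np.average(idx[1] + 1.0, weights=wts))
        pts.append([px, py])
    return np.array(pts) if pts else np.zeros((0, 2))


def generate_tbd_scenario(
    cfg: Optional[ScenarioConfig] = None, seed: int = 0
) -> Tuple[GroundTruth, List[Scan]]:
    """Constant-velocity truth on a pixel grid observed through PSF images;
    point detections are extracted by hard thresholding and polluted with
    uniform Poisson clutter."""
    cfg = cfg or default_config("tbd")
    rng = np.random.default_rng(seed)
    models = build_models(cfg)
    truth = _scripted_truth(cfg, models.motion, rng)
    lo, hi = cfg.snr_db_range
    snrs = {
        t.track_id: rng.uniform(lo, hi) for t in truth.tracks
    }
    obs_img = models.image_obs
    tau = cfg.detect_threshold_frac * obs_img.peak_amplitude
    scans = []
    for k in range(1, cfg.K + 1):
        alive = truth.alive(k)
        states = np.array([t.state_at(k)[:2] for t in alive]) if alive else np.zeros((0, 2))
        inten = [snr_to_intensity(snrs[t.track_id], cfg.sigma_h, cfg.sigma_y) for t in alive]
        img = render_point_spread_image(states, obs_img, rng, intensities=inten)
        dets = threshold_detections(img, tau, min_area=cfg.min_blob_area)
        clut = models.clutter.sample(rng)
        Z = np.vstack([dets.reshape(-1, 2), np.asarray(clut, float).reshape(-1, 2)])
        if Z.shape[0]:
            Z = Z[rng.permutation(Z.shape[0])]
        scans.append(
            Scan(
                frame=k,
                Z=Z,
                image=img,
                meta={
                    "n_clutter": int(len(clut)),
                    "n_extracted": int(len(dets)),
                    "n_alive": len(alive),
                },
            )
        )
    return truth, scans


def generate_cell_scenario(
    cfg: Optional[ScenarioConfig] = None, seed: int = 0
) -> Tuple[GroundTruth, List[Scan]]:
    """Dividing-cell sequence: constant-turn motion, per-frame survival and
    division (daughter state ~ N(parent state, Q_T), spawn lineage recorded),
    position detections with clutter.  A cap on the live population guards
    against explosion."""
    import warnings

    cfg = cfg or default_config("cell")
    rng = np.random.default_rng(seed)
    models = build_models(cfg)
    motion = make_ct_model(cfg.dt, cfg.truth_sigma_w, cfg.truth_sigma_v)
    qt = np.diag(interleaved_to_canonical(cfg.spawn_cov_diag_interleaved))
    Lq = np.linalg.cholesky(qt + 1e-12 * np.eye(qt.shape[0]))
    Lm = np.linalg.cholesky(motion.Q + 1e-12 * np.eye(motion.dim))
    x0_, x1_, y0_, y1_ = cfg.region
    margin = 0.25

    # live cell records: [track_id, parent_id, birth, list-of-states]
    next_id = 1
    live = []
    placed = []
    lo = np.array([x0_ + margin * (x1_ - x0_), y0_ + margin * (y1_ - y0_)])
    hi = np.array([x1_ - margin * (x1_ - x0_), y1_ - margin * (y1_ - y0_)])
    for _ in range(cfg.n_init_cells):
        # rejection-sample a sparse (well separated) initial culture
        for _attempt in range(200):
            pos = rng.uniform(lo, hi)
            if all(np.linalg.norm(pos - q) >= cfg.init_min_separation for q in placed):
                break
        placed.append(pos)
        x = np.concatenate(
            [pos, rng.normal(0.0, cfg.init_speed_std, 2), [rng.normal(0.0, cfg.sigma_w)]]
        )
        live.append([next_id, 0, 1, [x]])
        next_id += 1
    done: List[TruthTrack] = []
    warned = False
    for k in range(2, cfg.K + 1):
        new_live = []
        births = []
        for rec in live:
            tid, pid, birth, states = rec
            if rng.random() >= cfg.p_s:  # death
                done.append(TruthTrack(tid, pid, birth, np.array(states)))
                continue
            x = motion.propagate(states[-1]) + Lm @ rng.standard_normal(motion.dim)
            states.append(x)
            new_live.append(rec)
            if rng.random() < cfg.p_spawn:
                if len(new_live) + len(births) + sum(1 for r in live if r is not rec) >= cfg.max_cells:
                    if not warned:
                        warnings.warn("cell population cap reached; further divisions suppressed")
                        warned = True
                    continue
                parent_prev = np.asarray(states[-2], float)
                daughter = parent_prev + Lq @ rng.standard_normal(qt.shape[0])
                births.append([next_id, tid, k, [daughter]])
                next_id += 1
        live = new_live + births
        if len(live) > cfg.max_cells:
            live = live[: cfg.max_cells]
    for rec in live:
        tid, pid, birth, states = rec
        done.append(TruthTrack(tid, pid, birth, np.array(states)))
    done.sort(key=lambda t: t.track_id)
    truth = GroundTruth(tracks=done, K=cfg.K)
    scans = _point_scans(truth, cfg, models, rng)
    return truth, scans


def generate_scenario(
    kind: str, cfg: Optional[ScenarioConfig] = None, seed: int = 0
) -> Tuple[GroundTruth, List[Scan]]:
    gen = {
        "linear": generate_linear_scenario,
        "ct": generate_ct_scenario,
        "tbd": generate_tbd_scenario,
        "cell": generate_cell_scenario,
    }
    if kind not in gen:
        raise ValueError(f"unknown scenario kind {kind!r}")
    return gen[kind](cfg, seed)
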