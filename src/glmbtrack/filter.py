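"""Generalized labeled multi-Bernoulli (GLMB) forward filtering.

The multi-object posterior is a weighted mixture over hypotheses, each a set
of labelled tracks with full label-to-measurement association histories and
per-label Gaussian densities.  The joint prediction-update enumerates, per
parent hypothesis, survival/death decisions for existing labels,
birth/no-birth decisions for birth candidates, spawn/no-spawn decisions for
offspring candidates (cell division), and a positive 1-1 association map to
the scan's measurements; high-weight children are selected with a
systematic-scan Gibbs sampler and the result is normalized and truncated.

All weights are carried in the log domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from ._gibbs import _gibbs_sweeps
from .models import (
    BirthComponent,
    ClutterModel,
    DetectionModel,
    GaussianComponent,
    Label,
    MotionModel,
    ObservationModel,
    SpawnModel,
    wrap_angle,
)
from .smoothing import UnscentedParams, kf_predict, kf_update, unscented_transform

__all__ = [
    "Scan",
    "ModelSet",
    "FilterSettings",
    "Track",
    "GLMBHypothesis",
    "GLMBDensity",
    "empty_density",
    "association_weight",
    "tbd_likelihood_ratio",
    "gibbs_sample_assignments",
    "joint_predict_update",
    "hybrid_joint_predict_update",
    "spawning_joint_predict_update",
    "normalize_truncate",
]

_LOG2PI = math.log(2.0 * math.pi)
_NEG_INF = -np.inf


@dataclass
class Scan:
    """One frame's observation: a point-measurement set and optionally an image.

    ``meta`` carries generator-side bookkeeping (e.g. sampled clutter and
    true-detection counts) for evaluation; the filter never reads it.
    """

    frame: int
    Z: np.ndarray
    image: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.size == 0:
            self.Z = self.Z.reshape(0, self.Z.shape[1] if self.Z.ndim == 2 and self.Z.shape[1] else 2)

    @property
    def n_meas(self) -> int:
        return self.Z.shape[0]


@dataclass
class ModelSet:
    """Bundle of the model ingredients one filtering mode needs."""

    motion: MotionModel
    obs: ObservationModel
    birth: "object"
    clutter: ClutterModel
    detection: DetectionModel
    spawn: Optional[SpawnModel] = None
    image_obs: Optional[ObservationModel] = None  # PSF model for hybrid mode
    ut: UnscentedParams = field(default_factory=UnscentedParams)


@dataclass
class FilterSettings:
    """Truncation and sampling knobs.

    ``gibbs_sweeps`` is the total sweep budget per update, shared across
    parent hypotheses in proportion to their weights; ``None`` resolves to
    max(1000, 10 * n_variables * (n_meas + 2)).
    """

    h_max: int = 20000
    gibbs_sweeps: Optional[int] = None
    prune_log_weight: float = -300.0

    def resolve_sweeps(self, n_vars: int, n_meas: int) -> int:
        if self.gibbs_sweeps is not None:
            return int(self.gibbs_sweeps)
        return max(1000, 10 * n_vars * (n_meas + 2))


# ---------------------------------------------------------------------------
# Hypotheses
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Track:
    """One labelled track inside a hypothesis: birth information, full
    association history (one entry per frame since birth; 0 = miss) and the
    current filtered Gaussian density."""

    label: Label
    birth_frame: int
    birth_state: GaussianComponent
    history: Tuple[int, ...]
    comp: GaussianComponent

    @property
    def key(self) -> tuple:
        return (self.label, self.history)


@dataclass(eq=False)
class GLMBHypothesis:
    """Weighted hypothesis (I, xi): a set of labelled tracks with distinct labels."""

    log_weight: float
    tracks: Tuple[Track, ...]

    def __post_init__(self):
        self.tracks = tuple(sorted(self.tracks, key=lambda t: t.label.sort_key))
        labels = [t.label for t in self.tracks]
        if len(set(labels)) != len(labels):
            raise ValueError("distinct-label invariant violated within a hypothesis")

    @property
    def labels(self) -> frozenset:
        return frozenset(t.label for t in self.tracks)

    @property
    def key(self) -> tuple:
        return tuple(t.key for t in self.tracks)

    @property
    def weight(self) -> float:
        return math.exp(self.log_weight)

    @property
    def cardinality(self) -> int:
        return len(self.tracks)

    def association_map(self) -> Dict[Label, int]:
        """Current-frame association map theta (only meaningful post-update)."""
        return {t.label: t.history[-1] for t in self.tracks}


@dataclass
class GLMBDensity:
    """Normalized weighted set of GLMB hypotheses at one frame."""

    hypotheses: List[GLMBHypothesis]
    frame: int
    assoc_mass: Optional[np.ndarray] = None  # per-measurement association mass
    n_hyp_pre_truncation: int = 0

    def log_weights(self) -> np.ndarray:
        return np.array([h.log_weight for h in self.hypotheses])

    def normalize(self) -> "GLMBDensity":
        lw = self.log_weights()
        tot = logsumexp(lw)
        for h in self.hypotheses:
            h.log_weight -= tot
        return self

    def cardinality_distribution(self) -> np.ndarray:
        if not self.hypotheses:
            return np.array([1.0])
        nmax = max(h.cardinality for h in self.hypotheses)
        rho = np.zeros(nmax + 1)
        for h in self.hypotheses:
            rho[h.cardinality] += math.exp(h.log_weight)
        return rho

    def effective_n_hypotheses(self) -> float:
        w = np.exp(self.log_weights())
        return float(1.0 / np.sum(w**2)) if w.size else 0.0


def empty_density(frame: int = 0) -> GLMBDensity:
    """The vacuous prior: a single empty hypothesis of weight 1."""
    return GLMBDensity([GLMBHypothesis(0.0, ())], frame)


# ---------------------------------------------------------------------------
# Association weights
# ---------------------------------------------------------------------------


def _meas_logliks(
    pred: GaussianComponent, Z: np.ndarray, obs: ObservationModel, ut: UnscentedParams
) -> np.ndarray:
    """Predictive log-likelihood of every measurement under one component,
    vectorized over the scan."""
    if Z.shape[0] == 0:
        return np.zeros(0)
    if obs.kind == "linear":
        H, R = obs.H, obs.R
        S = H @ pred.cov @ H.T + R
        zhat = H @ pred.mean
        resid = Z - zhat
    elif obs.kind == "bearing-range":
        pts, wm, wc = unscented_transform(pred.mean, pred.cov, None, ut)
        Zs = np.array([obs.h(p) for p in pts])
        zhat = np.empty(2)
        zhat[0] = math.atan2(wm @ np.sin(Zs[:, 0]), wm @ np.cos(Zs[:, 0]))
        zhat[1] = wm @ Zs[:, 1]
        dz = Zs - zhat
        dz[:, 0] = wrap_angle(dz[:, 0])
        S = (wc[:, None] * dz).T @ dz + obs.R
        resid = Z - zhat
        resid[:, 0] = wrap_angle(resid[:, 0])
    else:
        raise ValueError("point measurements need a linear or bearing-range model")
    S = 0.5 * (S + S.T)
    L = np.linalg.cholesky(S)
    alpha = np.linalg.solve(L, resid.T)
    maha = np.sum(alpha**2, axis=0)
    return -0.5 * maha - np.log(np.diag(L)).sum() - 0.5 * resid.shape[1] * _LOG2PI


def association_weight(
    pred: GaussianComponent,
    j: int,
    Z: np.ndarray,
    det: DetectionModel,
    clut: ClutterModel,
    obs: ObservationModel,
    ut: Optional[UnscentedParams] = None,
) -> float:
    """Single-label association factor psi: qD for a miss (j = 0), else
    pD * ghat(z_j) / kappa(z_j) with ghat the Gaussian predictive likelihood."""
    Z = np.atleast_2d(np.asarray(Z, float))
    if not 0 <= j <= Z.shape[0]:
        raise ValueError("measurement index out of range")
    if j == 0:
        return det.q_d
    ll = _meas_logliks(pred, Z[j - 1 : j], obs, ut or UnscentedParams())[0]
    kappa = clut.intensity(Z[j - 1])
    if kappa <= 0.0:
        kappa = math.exp(clut.log_intensity_floor())
    return det.p_d * math.exp(ll) / kappa


def tbd_likelihood_ratio(
    image: np.ndarray, comp: GaussianComponent, obs: ObservationModel
) -> float:
    """Track-before-detect likelihood ratio sigma_T for one component.

    Product over the truncated template T(x) of N(y_i; h_i(x), sigma_y) /
    N(y_i; 0, sigma_y), evaluated in the log domain at the component mean.
    Pixels are 1-based with (a, b) = (column, row) centres; out-of-image
    template pixels clip to the image bounds.
    """
    return math.exp(log_tbd_ratio(image, comp.mean, obs))


def log_tbd_ratio(image: np.ndarray, mean: np.ndarray, obs: ObservationModel) -> float:
    if obs.kind != "image-psf":
        raise ValueError("tbd_likelihood_ratio needs an image-psf observation model")
    px, py = float(mean[0]), float(mean[1])
    r = obs.template_radius
    h, w = image.shape
    a_lo = max(1, int(math.floor(px - r)))
    a_hi = min(w, int(math.ceil(px + r)))
    b_lo = max(1, int(math.floor(py - r)))
    b_hi = min(h, int(math.ceil(py + r)))
    if a_lo > a_hi or b_lo > b_hi:
        return 0.0
    a = np.arange(a_lo, a_hi + 1, dtype=float)
    b = np.arange(b_lo, b_hi + 1, dtype=float)
    A, B = np.meshgrid(a, b)
    hv = obs.template_value(px, py, A, B)
    y = image[b_lo - 1 : b_hi, a_lo - 1 : a_hi]
    # log N(y; h, s) - log N(y; 0, s) = (2 y h - h^2) / (2 s^2)
    return float(np.sum(2.0 * y * hv - hv**2) / (2.0 * obs.sigma_y**2))


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------


def gibbs_sample_assignments(
    log_costs: np.ndarray,
    n_iter: int,
    init: np.ndarray,
    rng: np.random.Generator,
    return_counts: bool = False,
):
    """Unique assignments visited by a systematic-scan Gibbs chain.

    ``log_costs`` has one row per decision variable and columns
    [die/absent, miss, z_1, ..., z_m]; measurement columns are exclusive
    across variables.  ``init`` gives the starting option per variable and is
    always included in the output.  Returns an integer array of shape
    (n_unique, n_vars) of option indices.
    """
    log_costs = np.asarray(log_costs, dtype=float)
    init = np.asarray(init, dtype=np.int32)
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    n_vars, n_opts = log_costs.shape
    n_meas = n_opts - 2
    used = init[init >= 2]
    if used.size != np.unique(used).size:
        raise ValueError("infeasible init: a measurement is assigned twice")
    if n_vars == 0:
        return init.reshape(1, 0)
    seed = int(rng.integers(0, 2**31 - 1))
    visited = _gibbs_sweeps(log_costs, n_meas, int(n_iter), init, seed)
    allrows = np.vstack([init.reshape(1, -1), visited])
    # dedupe preserving first-visit order (cheaper than np.unique for the
    # small row counts the per-parent chains produce)
    seen: Dict[bytes, int] = {}
    keep = []
    counts = []
    for i, row in enumerate(allrows):
        k = row.tobytes()
        if k not in seen:
            seen[k] = len(keep)
            keep.append(i)
            counts.append(0 if i == 0 else 1)  # the injected init is not a visit
        elif i > 0:
            counts[seen[k]] += 1
    unique = allrows[keep]
    if return_counts:
        return unique, np.asarray(counts)
    return unique


# ---------------------------------------------------------------------------
# Joint prediction-update
# ---------------------------------------------------------------------------


class _Candidate:
    """Per-variable precomputation: option costs plus posterior construction."""

    __slots__ = ("row", "make_child", "is_track")

    def __init__(self, row, make_child, is_track):
        self.row = row
        self.make_child = make_child
        self.is_track = is_track


def _log_kappas(Z: np.ndarray, clut: ClutterModel) -> np.ndarray:
    floor = clut.log_intensity_floor()
    out = np.empty(Z.shape[0])
    for j, z in enumerate(Z):
        k = clut.intensity(z)
        out[j] = math.log(k) if k > 0 else floor
    return out


def _survival_candidate(
    track: Track,
    scan: Scan,
    models: ModelSet,
    log_kappa: np.ndarray,
    log_sigma_t: Optional[float],
) -> _Candidate:
    det = models.detection
    pred = kf_predict(track.comp, models.motion, models.ut)
    lls = _meas_logliks(pred, scan.Z, models.obs, models.ut)
    row = np.empty(2 + scan.n_meas)
    row[0] = math.log(det.q_s) if det.q_s > 0 else _NEG_INF
    log_ps = math.log(det.p_s) if det.p_s > 0 else _NEG_INF
    row[1] = log_ps + (math.log(det.q_d) if det.q_d > 0 else _NEG_INF)
    if log_sigma_t is not None:
        row[1] += log_sigma_t
    log_pd = math.log(det.p_d) if det.p_d > 0 else _NEG_INF
    row[2:] = log_ps + log_pd + lls - log_kappa

    cache: Dict[int, Track] = {}

    def make_child(j: int) -> Optional[Track]:
        if j < 0:
            return None
        if j not in cache:
            comp = pred if j == 0 else kf_update(pred, scan.Z[j - 1], models.obs, models.ut)[0]
            cache[j] = Track(
                label=track.label,
                birth_frame=track.birth_frame,
                birth_state=track.birth_state,
                history=track.history + (j,),
                comp=comp,
            )
        return cache[j]

    return _Candidate(row, make_child, True)


def _birth_candidate(
    bc: BirthComponent,
    scan: Scan,
    models: ModelSet,
    log_kappa: np.ndarray,
    log_sigma_t_fn,
) -> _Candidate:
    det = models.detection
    pred = GaussianComponent(bc.mean, bc.cov)
    lls = _meas_logliks(pred, scan.Z, models.obs, models.ut)
    row = np.empty(2 + scan.n_meas)
    row[0] = math.log1p(-bc.r) if bc.r < 1.0 else _NEG_INF
    log_r = math.log(bc.r) if bc.r > 0 else _NEG_INF
    row[1] = log_r + (math.log(det.q_d) if det.q_d > 0 else _NEG_INF)
    if log_sigma_t_fn is not None:
        row[1] += log_sigma_t_fn(pred)
    log_pd = math.log(det.p_d) if det.p_d > 0 else _NEG_INF
    row[2:] = log_r + log_pd + lls - log_kappa

    label = Label(time=scan.frame, index=bc.index)
    cache: Dict[int, Track] = {}

    def make_child(j: int) -> Optional[Track]:
        if j < 0:
            return None
        if j not in cache:
            comp = pred if j == 0 else kf_update(pred, scan.Z[j - 1], models.obs, models.ut)[0]
            cache[j] = Track(
                label=label,
                birth_frame=scan.frame,
                birth_state=pred,
                history=(j,),
                comp=comp,
            )
        return cache[j]

    return _Candidate(row, make_child, False)


def _collect_children(
    prior: GLMBDensity,
    scan: Scan,
    models: ModelSet,
    settings: FilterSettings,
    rng: np.random.Generator,
    birth_components: Sequence[BirthComponent],
    log_sigma_t_fn,
    spawn: bool = False,
) -> GLMBDensity:
    if scan.frame != prior.frame + 1:
        raise ValueError(f"scan frame {scan.frame} must follow prior frame {prior.frame}")
    Z = scan.Z
    n_z = scan.n_meas
    log_kappa = _log_kappas(Z, models.clutter)

    # Per-track candidate cache shared across parent hypotheses.
    surv_cache: Dict[int, _Candidate] = {}
    spawn_cache: Dict[Tuple[int, int], "_SpawnPair"] = {}

    def surv_for(t: Track) -> _Candidate:
        key = id(t)
        if key not in surv_cache:
            lst = log_sigma_t_fn(kf_predict(t.comp, models.motion, models.ut)) if log_sigma_t_fn else None
            surv_cache[key] = _survival_candidate(t, scan, models, log_kappa, lst)
        return surv_cache[key]

    birth_cands = [
        _birth_candidate(bc, scan, models, log_kappa, log_sigma_t_fn)
        for bc in birth_components
    ]

    # Weight-ordered parents; sweep budget shared proportionally.
    parents = sorted(prior.hypotheses, key=lambda h: -h.log_weight)
    wts = np.exp(np.array([h.log_weight for h in parents]))
    wts = wts / wts.sum() if wts.sum() > 0 else np.full(len(parents), 1.0 / len(parents))
    max_vars = max((h.cardinality for h in parents), default=0)
    if spawn and models.spawn is not None:
        max_vars += max_vars * models.spawn.max_offspring
    max_vars += len(birth_cands)
    total_sweeps = settings.resolve_sweeps(max(1, max_vars), n_z)

    merged: Dict[tuple, float] = {}
    merged_tracks: Dict[tuple, Tuple[Track, ...]] = {}

    for h, w in zip(parents, wts):
        cands: List[_Candidate] = [surv_for(t) for t in h.tracks]
        if spawn and models.spawn is not None:
            for ti, t in enumerate(h.tracks):
                for i in range(1, models.spawn.max_offspring + 1):
                    key = (id(t), i)
                    if key not in spawn_cache:
                        spawn_cache[key] = _SpawnPair(t, i, scan, models, log_kappa)
                    cands.append(spawn_cache[key].candidate)
        cands.extend(birth_cands)
        n_vars = len(cands)
        if n_vars == 0:
            child_key = ()
            lw = h.log_weight
            _merge_child(merged, merged_tracks, child_key, (), lw)
            continue
        rows = np.vstack([c.row for c in cands])
        init = np.array([1 if c.is_track else 0 for c in cands], dtype=np.int32)
        sweeps = max(1, int(math.ceil(total_sweeps * w)))
        assignments = gibbs_sample_assignments(rows, sweeps, init, rng)
        n_track_vars = len(h.tracks)
        for assign in assignments:
            decisions = assign.astype(int) - 1  # -1 die/absent, 0 miss, j meas
            lw = h.log_weight
            tracks: List[Track] = []
            ok = True
            if spawn and models.spawn is not None:
                lw_extra, extra_tracks, handled = _spawn_assemble(
                    h, decisions, n_track_vars, models, spawn_cache, scan
                )
                if lw_extra is None:
                    ok = False
                else:
                    lw += lw_extra
                    tracks.extend(extra_tracks)
                for vi, c in enumerate(cands):
                    if vi in handled:
                        continue
                    d = int(decisions[vi])
                    cost = rows[vi, assign[vi]]
                    if not np.isfinite(cost):
                        ok = False
                        break
                    lw += cost
                    child = c.make_child(d)
                    if child is not None:
                        tracks.append(child)
            else:
                for vi, c in enumerate(cands):
                    d = int(decisions[vi])
                    cost = rows[vi, assign[vi]]
                    if not np.isfinite(cost):
                        ok = False
                        break
                    lw += cost
                    child = c.make_child(d)
                    if child is not None:
                        tracks.append(child)
            if not ok:
                continue
            tracks_t = tuple(sorted(tracks, key=lambda t: t.label.sort_key))
            child_key = tuple(t.key for t in tracks_t)
            _merge_child(merged, merged_tracks, child_key, tracks_t, lw)

    if not merged:
        raise RuntimeError("joint predict-update produced no feasible hypothesis")
    children = [
        GLMBHypothesis(lw, merged_tracks[k]) for k, lw in merged.items()
    ]
    post = GLMBDensity(children, scan.frame, n_hyp_pre_truncation=len(children))
    post = normalize_truncate(post, settings.h_max)
    post.assoc_mass = _association_mass(post, n_z)
    post.n_hyp_pre_truncation = len(children)
    return post


def _merge_child(merged, merged_tracks, key, tracks, lw):
    if key in merged:
        merged[key] = np.logaddexp(merged[key], lw)
    else:
        merged[key] = lw
        merged_tracks[key] = tracks


def _association_mass(post: GLMBDensity, n_z: int) -> np.ndarray:
    mass = np.zeros(n_z)
    for h in post.hypotheses:
        w = math.exp(h.log_weight)
        for t in h.tracks:
            j = t.history[-1]
            if j > 0:
                mass[j - 1] += w
    return np.clip(mass, 0.0, 1.0)


def joint_predict_update(
    prior: GLMBDensity,
    scan: Scan,
    models: ModelSet,
    settings: Optional[FilterSettings] = None,
    rng: Optional[np.random.Generator] = None,
    birth_components: Optional[Sequence[BirthComponent]] = None,
) -> GLMBDensity:
    """Standard-observation GLMB joint prediction-update.

    Each child hypothesis extends a parent by survival/death decisions,
    birth decisions, and a positive 1-1 association map; per-label densities
    are Kalman (linear) or unscented (bearing-range) updated and hypothesis
    weights follow the product of survival, birth, detection and
    clutter-ratio factors.
    """
    settings = settings or FilterSettings()
    rng = rng if rng is not None else np.random.default_rng()
    if birth_components is None:
        birth_components = getattr(models.birth, "static_components", lambda: [])()
    return _collect_children(prior, scan, models, settings, rng, birth_components, None)


def hybrid_joint_predict_update(
    prior: GLMBDensity,
    scan: Scan,
    models: ModelSet,
    settings: Optional[FilterSettings] = None,
    rng: Optional[np.random.Generator] = None,
    birth_components: Optional[Sequence[BirthComponent]] = None,
) -> GLMBDensity:
    """Hybrid track-before-detect update: identical to the standard update
    except every miss-detection factor is scaled by the image likelihood
    ratio sigma_T of the predicted component."""
    if scan.image is None:
        raise ValueError("hybrid update needs a scan with an image; use joint_predict_update")
    if models.image_obs is None:
        raise ValueError("hybrid update needs models.image_obs (image-psf model)")
    settings = settings or FilterSettings()
    rng = rng if rng is not None else np.random.default_rng()
    if birth_components is None:
        birth_components = getattr(models.birth, "static_components", lambda: [])()

    def log_sigma_t_fn(pred: GaussianComponent) -> float:
        return log_tbd_ratio(scan.image, pred.mean, models.image_obs)

    return _collect_children(
        prior, scan, models, settings, rng, birth_components, log_sigma_t_fn
    )


# ---------------------------------------------------------------------------
# Spawning
# ---------------------------------------------------------------------------


class _SpawnPair:
    """Joint parent-daughter prediction for one spawn candidate.

    The daughter is spawned from the parent's posterior at the previous
    frame (mean f_T(x), covariance mapped + Q_T) while the parent moves
    through the motion model; the joint Gaussian over [parent+; daughter]
    is formed by an unscented pass so parent-daughter correlation is kept
    for the exact update, after which each label keeps its marginal
    (moment matching back to standard GLMB form).
    """

    def __init__(self, parent: Track, index: int, scan: Scan, models: ModelSet, log_kappa):
        self.parent = parent
        sp = models.spawn
        det = models.detection
        nx = parent.comp.dim
        self.nx = nx
        noise = np.zeros((2 * nx, 2 * nx))
        noise[:nx, :nx] = models.motion.Q
        noise[nx:, nx:] = sp.Q_t
        pts, wm, wc = unscented_transform(parent.comp.mean, parent.comp.cov, noise, models.ut)
        prop = np.empty((pts.shape[0], 2 * nx))
        for i, p in enumerate(pts):
            x = p[:nx]
            prop[i, :nx] = models.motion.propagate(x) + p[nx : 2 * nx]
            prop[i, nx:] = sp.offspring_map(x) + p[2 * nx :]
        m = wm @ prop
        d = prop - m
        P = (wc[:, None] * d).T @ d
        self.joint_mean = m
        self.joint_cov = 0.5 * (P + P.T)
        self.label = Label(time=scan.frame, index=index, parent=parent.label)
        self.daughter_pred = GaussianComponent(m[nx:], self.joint_cov[nx:, nx:])
        lls = _meas_logliks(self.daughter_pred, scan.Z, models.obs, models.ut)
        row = np.empty(2 + scan.n_meas)
        row[0] = math.log(sp.q_t) if sp.q_t > 0 else _NEG_INF
        log_pt = math.log(sp.p_t) if sp.p_t > 0 else _NEG_INF
        row[1] = log_pt + (math.log(det.q_d) if det.q_d > 0 else _NEG_INF)
        log_pd = math.log(det.p_d) if det.p_d > 0 else _NEG_INF
        row[2:] = log_pt + log_pd + lls - log_kappa
        self.candidate = _Candidate(row, None, False)
        self._models = models
        self._scan = scan
        self._log_kappa = log_kappa
        self._exact_cache: Dict[Tuple[int, int], Tuple[Optional[Track], Optional[Track], float]] = {}

    def exact(self, jp: int, jd: int) -> Tuple[Optional[Track], Optional[Track], float]:
        """Joint update for parent decision jp and daughter decision jd
        (decisions: -1 absent, 0 miss, j measurement).  Returns the
        marginalized parent/daughter child tracks and the extra log-weight
        (likelihood and clutter-ratio terms; decision priors excluded)."""
        key = (jp, jd)
        if key in self._exact_cache:
            return self._exact_cache[key]
        models, scan, nx = self._models, self._scan, self.nx
        obs = models.obs
        m = self.joint_mean.copy()
        P = self.joint_cov.copy()
        extra = 0.0

        def joint_update(block: int, j: int):
            nonlocal m, P, extra
            H = np.zeros((obs.H.shape[0], 2 * nx))
            H[:, block * nx : (block + 1) * nx] = obs.H
            S = H @ P @ H.T + obs.R
            S = 0.5 * (S + S.T)
            resid = scan.Z[j - 1] - H @ m
            L = np.linalg.cholesky(S)
            alpha = np.linalg.solve(L, resid)
            extra += float(
                -0.5 * alpha @ alpha - np.log(np.diag(L)).sum() - 0.5 * resid.size * _LOG2PI
            )
            extra -= self._log_kappa[j - 1]
            K = np.linalg.solve(S, H @ P).T
            m = m + K @ resid
            P = P - K @ S @ K.T
            P = 0.5 * (P + P.T)

        if obs.kind != "linear" and (jp > 0 or jd > 0):
            # Nonlinear point observations: fall back to independent marginal
            # updates (no cross-correlation carried through the update).
            parent_child = None
            if jp >= 0:
                pc = GaussianComponent(m[:nx], P[:nx, :nx])
                if jp > 0:
                    pc, ll = kf_update(pc, scan.Z[jp - 1], obs, models.ut)
                    extra += ll - self._log_kappa[jp - 1]
                parent_child = self._mk_parent(pc, jp)
            daughter_child = None
            if jd >= 0:
                dc = GaussianComponent(m[nx:], P[nx:, nx:])
                if jd > 0:
                    dc, ll = kf_update(dc, scan.Z[jd - 1], obs, models.ut)
                    extra += ll - self._log_kappa[jd - 1]
                daughter_child = self._mk_daughter(dc, jd)
            out = (parent_child, daughter_child, extra)
            self._exact_cache[key] = out
            return out

        if jp > 0:
            joint_update(0, jp)
        if jd > 0:
            joint_update(1, jd)
        parent_child = (
            self._mk_parent(GaussianComponent(m[:nx], P[:nx, :nx]), jp) if jp >= 0 else None
        )
        daughter_child = (
            self._mk_daughter(GaussianComponent(m[nx:], P[nx:, nx:]), jd) if jd >= 0 else None
        )
        out = (parent_child, daughter_child, extra)
        self._exact_cache[key] = out
        return out

    def _mk_parent(self, comp: GaussianComponent, jp: int) -> Track:
        t = self.parent
        return Track(t.label, t.birth_frame, t.birth_state, t.history + (jp,), comp)

    def _mk_daughter(self, comp: GaussianComponent, jd: int) -> Track:
        return Track(self.label, self._scan.frame, self.daughter_pred, (jd,), comp)


def _spawn_assemble(
    h: GLMBHypothesis,
    decisions: np.ndarray,
    n_track_vars: int,
    models: ModelSet,
    spawn_cache: Dict[Tuple[int, int], _SpawnPair],
    scan: Scan,
):
    """Resolve the parent+spawn variables of one assignment jointly.

    Returns (extra log-weight, list of child tracks, set of handled variable
    indices) or (None, None, handled) when the assignment hits a -inf cost.
    """
    det = models.detection
    sp = models.spawn
    handled = set()
    tracks: List[Track] = []
    lw = 0.0
    n_off = sp.max_offspring
    for ti, t in enumerate(h.tracks):
        jp = int(decisions[ti])
        handled.add(ti)
        # decision priors for the parent
        if jp < 0:
            if det.q_s <= 0:
                return None, None, handled
            lw += math.log(det.q_s)
        else:
            if det.p_s <= 0:
                return None, None, handled
            lw += math.log(det.p_s)
            if jp == 0:
                if det.q_d <= 0:
                    return None, None, handled
                lw += math.log(det.q_d)
            else:
                if det.p_d <= 0:
                    return None, None, handled
                lw += math.log(det.p_d)
        for i in range(1, n_off + 1):
            vi = n_track_vars + ti * n_off + (i - 1)
            handled.add(vi)
            jd = int(decisions[vi])
            pair = spawn_cache[(id(t), i)]
            if jd < 0:
                if sp.q_t <= 0:
                    return None, None, handled
                lw += math.log(sp.q_t)
                jd_eff = None
            else:
                if sp.p_t <= 0:
                    return None, None, handled
                lw += math.log(sp.p_t)
                lw += math.log(det.q_d if jd == 0 else det.p_d)
                jd_eff = jd
            if i == 1:
                pc, dc, extra = pair.exact(jp, -1 if jd_eff is None else jd_eff)
                lw += extra
                if pc is not None:
                    tracks.append(pc)
                if dc is not None:
                    tracks.append(dc)
            else:
                # additional offspring candidates are treated marginally
                if jd_eff is not None:
                    _, dc, extra = pair.exact(-1, jd_eff)
                    lw += extra
                    tracks.append(dc)
    return lw, tracks, handled


def spawning_joint_predict_update(
    prior: GLMBDensity,
    scan: Scan,
    models: ModelSet,
    settings: Optional[FilterSettings] = None,
    rng: Optional[np.random.Generator] = None,
    birth_components: Optional[Sequence[BirthComponent]] = None,
) -> GLMBDensity:
    """GLMB joint prediction-update with per-parent spawning (cell division).

    Child hypotheses additionally carry per-parent spawn decisions with
    labels (parent, k+1, i); daughter densities are spawned from the parent
    posterior and jointly updated with the parent before marginalizing each
    label back to a single Gaussian, keeping the density in standard GLMB
    form.
    """
    if models.spawn is None:
        raise ValueError("spawning update needs models.spawn")
    settings = settings or FilterSettings()
    rng = rng if rng is not None else np.random.default_rng()
    if birth_components is None:
        birth_components = getattr(models.birth, "static_components", lambda: [])()
    return _collect_children(
        prior, scan, models, settings, rng, birth_components, None, spawn=True
    )


# ---------------------------------------------------------------------------
# Truncation
# ---------------------------------------------------------------------------


def normalize_truncate(glmb: GLMBDensity, h_max: int) -> GLMBDensity:
    """Merge duplicate (I, xi) hypotheses, keep the ``h_max`` heaviest
    (ties by insertion order), renormalize to unit total weight."""
    if h_max < 1:
        raise ValueError("h_max must be at least 1")
    if not glmb.hypotheses:
        raise ValueError("cannot truncate an empty density")
    merged: Dict[tuple, GLMBHypothesis] = {}
    for h in glmb.hypotheses:
        k = h.key
        if k in merged:
            merged[k].log_weight = np.logaddexp(merged[k].log_weight, h.log_weight)
        else:
            merged[k] = GLMBHypothesis(h.log_weight, h.tracks)
    hyps = list(merged.values())
    order = sorted(range(len(hyps)), key=lambda i: (-hyps[i].log_weight, i))
    kept = [hyps[i] for i in order[:h_max]]
    out = GLMBDensity(kept, glmb.frame, n_hyp_pre_truncation=len(hyps))
    return out.normalize()
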