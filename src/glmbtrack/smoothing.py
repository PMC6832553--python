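"""Single-object Gaussian filtering and backward smoothing.

Kalman and unscented predict/update steps, the Rauch-Tung-Striebel (RTS)
backward recursion for linear dynamics and its unscented variant (URTS) for
the constant-turn model.  These are the numerical primitives driven per
estimated trajectory by the multi-scan estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .models import GaussianComponent, MotionModel, ObservationModel, wrap_angle

__all__ = [
    "UnscentedParams",
    "GaussianTrack",
    "unscented_transform",
    "kf_predict",
    "kf_update",
    "rts_smooth",
    "urts_smooth",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class UnscentedParams:
    """Sigma-point spread/weighting parameters.

    Defaults (alpha=1, beta=2, kappa=3-n) keep the weights well conditioned
    for state dimensions up to ~7; kappa=None resolves to 3-n at call time.
    """

    alpha: float = 1.0
    beta: float = 2.0
    kappa: Optional[float] = None

    def resolve_kappa(self, n: int) -> float:
        return 3.0 - n if self.kappa is None else self.kappa

    def weights(self, n: int) -> Tuple[float, np.ndarray, np.ndarray]:
        kappa = self.resolve_kappa(n)
        lam = self.alpha**2 * (n + kappa) - n
        wm = np.full(2 * n + 1, 1.0 / (2.0 * (n + lam)))
        wc = wm.copy()
        wm[0] = lam / (n + lam)
        wc[0] = lam / (n + lam) + (1.0 - self.alpha**2 + self.beta)
        return lam, wm, wc


@dataclass
class GaussianTrack:
    """Time-indexed sequence of Gaussian components for one object."""

    start_frame: int
    components: List[GaussianComponent]
    detected: List[bool] = field(default_factory=list)

    def __post_init__(self):
        if not self.components:
            raise ValueError("a track needs at least one component")
        if not self.detected:
            self.detected = [True] * len(self.components)
        if len(self.detected) != len(self.components):
            raise ValueError("detected flags must align with components")

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.components) - 1

    def __len__(self) -> int:
        return len(self.components)


def _safe_cholesky(M: np.ndarray) -> np.ndarray:
    jitter = 0.0
    scale = max(1.0, float(np.trace(M)) / M.shape[0])
    for _ in range(6):
        try:
            return np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))
        except np.linalg.LinAlgError:
            jitter = 1e-12 * scale if jitter == 0.0 else jitter * 100.0
    raise np.linalg.LinAlgError("Cholesky factorization failed even with jitter")


def unscented_transform(
    mean: np.ndarray,
    cov: np.ndarray,
    noise_cov: Optional[np.ndarray] = None,
    params: Optional[UnscentedParams] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Augmented sigma-point set for (mean, blockdiag(cov, noise_cov)).

    Returns ``(points, wm, wc)`` with ``points`` of shape (2n+1, nx+nq);
    the weighted empirical mean/covariance of the points reproduce the
    augmented mean and covariance exactly.
    """
    params = params or UnscentedParams()
    mean = np.asarray(mean, float).ravel()
    cov = np.asarray(cov, float)
    nx = mean.size
    if noise_cov is None:
        noise_cov = np.zeros((0, 0))
    nq = noise_cov.shape[0]
    n = nx + nq
    mu = np.concatenate([mean, np.zeros(nq)])
    P = np.zeros((n, n))
    P[:nx, :nx] = cov
    if nq:
        P[nx:, nx:] = noise_cov
    lam, wm, wc = params.weights(n)
    L = _safe_cholesky((n + lam) * P)
    pts = np.empty((2 * n + 1, n))
    pts[0] = mu
    for i in range(n):
        pts[1 + i] = mu + L[:, i]
        pts[1 + n + i] = mu - L[:, i]
    return pts, wm, wc


def kf_predict(
    comp: GaussianComponent,
    motion: MotionModel,
    params: Optional[UnscentedParams] = None,
) -> GaussianComponent:
    """One-step prediction: exact for linear motion, unscented for constant-turn."""
    if motion.is_linear:
        F = motion.F
        m = F @ comp.mean
        P = F @ comp.cov @ F.T + motion.Q
        return GaussianComponent.unchecked(m, 0.5 * (P + P.T))
    nx = comp.dim
    pts, wm, wc = unscented_transform(comp.mean, comp.cov, motion.Q, params)
    prop = np.array([motion.f(p[:nx]) + p[nx:] for p in pts])
    m = wm @ prop
    d = prop - m
    P = (wc[:, None] * d).T @ d
    return GaussianComponent.unchecked(m, 0.5 * (P + P.T))


def _loglik_gauss(resid: np.ndarray, S: np.ndarray) -> float:
    L = _safe_cholesky(S)
    alpha = np.linalg.solve(L, resid)
    return float(
        -0.5 * (alpha @ alpha) - np.log(np.diag(L)).sum() - 0.5 * resid.size * _LOG2PI
    )


def kf_update(
    comp: GaussianComponent,
    z: np.ndarray,
    obs: ObservationModel,
    params: Optional[UnscentedParams] = None,
) -> Tuple[GaussianComponent, float]:
    """Measurement update returning the posterior and the predictive
    log-likelihood of ``z``.

    Linear models use the Joseph-form Kalman update; bearing-range models use
    an unscented update with the bearing innovation wrapped to (-pi, pi].
    """
    z = np.asarray(z, float).ravel()
    if obs.kind == "linear":
        H, R = obs.H, obs.R
        S = H @ comp.cov @ H.T + R
        S = 0.5 * (S + S.T)
        resid = z - H @ comp.mean
        K = np.linalg.solve(S, H @ comp.cov).T
        m = comp.mean + K @ resid
        IKH = np.eye(comp.dim) - K @ H
        P = IKH @ comp.cov @ IKH.T + K @ R @ K.T
        return GaussianComponent.unchecked(m, 0.5 * (P + P.T)), _loglik_gauss(resid, S)
    if obs.kind == "bearing-range":
        pts, wm, wc = unscented_transform(comp.mean, comp.cov, None, params)
        Zs = np.array([obs.h(p) for p in pts])
        # circular mean for the bearing channel keeps the average well defined
        zbar = np.empty(2)
        zbar[0] = math.atan2(wm @ np.sin(Zs[:, 0]), wm @ np.cos(Zs[:, 0]))
        zbar[1] = wm @ Zs[:, 1]
        dz = Zs - zbar
        dz[:, 0] = wrap_angle(dz[:, 0])
        S = (wc[:, None] * dz).T @ dz + obs.R
        S = 0.5 * (S + S.T)
        dx = pts - comp.mean
        C = (wc[:, None] * dx).T @ dz
        K = np.linalg.solve(S, C.T).T
        resid = z - zbar
        resid[0] = wrap_angle(resid[0])
        m = comp.mean + K @ resid
        P = comp.cov - K @ S @ K.T
        return GaussianComponent.unchecked(m, 0.5 * (P + P.T)), _loglik_gauss(resid, S)
    raise ValueError(f"unsupported observation kind {obs.kind!r} for point update")


def _regularized_inverse_solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve X A = B (i.e. X = B A^{-1}) with a regularized fallback."""
    try:
        return np.linalg.solve(A.T, B.T).T
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular predicted covariance; using regularized inverse")
        Areg = A + 1e-9 * max(1.0, float(np.trace(A)) / A.shape[0]) * np.eye(A.shape[0])
        return np.linalg.solve(Areg.T, B.T).T


def rts_smooth(track: GaussianTrack, motion: MotionModel) -> GaussianTrack:
    """Rauch-Tung-Striebel backward recursion for linear dynamics.

    The final frame is initialized to the filtered value; each earlier frame
    applies the smoother gain D = P_k F^T (P_bar_{k+1})^{-1}.
    """
    if not motion.is_linear:
        raise ValueError("rts_smooth requires a linear motion model")
    F, Q = motion.F, motion.Q
    n = len(track)
    sm: List[Optional[GaussianComponent]] = [None] * n
    sm[-1] = track.components[-1].copy()
    for k in range(n - 2, -1, -1):
        xk, Pk = track.components[k].mean, track.components[k].cov
        xpred = F @ xk
        Ppred = F @ Pk @ F.T + Q
        D = _regularized_inverse_solve(Ppred, Pk @ F.T)
        xs = xk + D @ (sm[k + 1].mean - xpred)
        Ps = Pk + D @ (sm[k + 1].cov - Ppred) @ D.T
        sm[k] = GaussianComponent.unchecked(xs, 0.5 * (Ps + Ps.T))
    return GaussianTrack(track.start_frame, sm, list(track.detected))


def urts_smooth(
    track: GaussianTrack,
    motion: MotionModel,
    params: Optional[UnscentedParams] = None,
) -> GaussianTrack:
    """Unscented RTS backward recursion for nonlinear dynamics.

    Sigma points are drawn over the augmented (state, process-noise) space;
    the smoother gain is the state/prediction cross-covariance times the
    inverse predicted covariance.  Exact sigma-point propagation of linear
    maps makes this coincide with :func:`rts_smooth` on linear dynamics.
    """
    if motion.is_linear:
        fn = lambda x: motion.F @ x  # noqa: E731 - allow linear motion through the UT path
    else:
        fn = motion.f
    Q = motion.Q
    n = len(track)
    sm: List[Optional[GaussianComponent]] = [None] * n
    sm[-1] = track.components[-1].copy()
    nx = track.components[0].dim
    for k in range(n - 2, -1, -1):
        xk, Pk = track.components[k].mean, track.components[k].cov
        pts, wm, wc = unscented_transform(xk, Pk, Q, params)
        prop = np.array([fn(p[:nx]) + p[nx:] for p in pts])
        xpred = wm @ prop
        dprop = prop - xpred
        Ppred = (wc[:, None] * dprop).T @ dprop
        dx = pts[:, :nx] - xk
        C = (wc[:, None] * dx).T @ dprop
        D = _regularized_inverse_solve(0.5 * (Ppred + Ppred.T), C)
        xs = xk + D @ (sm[k + 1].mean - xpred)
        Ps = Pk + D @ (sm[k + 1].cov - Ppred) @ D.T
        sm[k] = GaussianComponent.unchecked(xs, 0.5 * (Ps + Ps.T))
    return GaussianTrack(track.start_frame, sm, list(track.detected))
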