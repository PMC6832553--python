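"""Single-object and multi-object model ingredients.

Labels, Gaussian components and the motion / observation / birth / spawn /
clutter / detection models used by the GLMB filter and the per-trajectory
smoother.  The canonical planar state ordering is ``[px, py, vx, vy]`` (plus
a trailing turn rate ``w`` for the constant-turn model); block matrices over
``I2`` are written in that order.

Units are metres/seconds for radar-style scenarios and pixels/frames for
image scenarios; the numerics are unit-agnostic.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Label",
    "GaussianComponent",
    "MotionModel",
    "ObservationModel",
    "BirthComponent",
    "BirthModel",
    "SpawnModel",
    "ClutterModel",
    "DetectionModel",
    "RectSupport",
    "PolarSupport",
    "make_cv_model",
    "make_ct_model",
    "make_linear_position_model",
    "make_bearing_range_model",
    "make_image_psf_model",
    "clutter_intensity",
    "wrap_angle",
]


def wrap_angle(a):
    """Wrap an angle (or array of angles) to the interval (-pi, pi]."""
    out = -np.mod(-np.asarray(a, dtype=float) + np.pi, 2.0 * np.pi) + np.pi
    return out


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


@functools.total_ordering
@dataclass(frozen=True)
class Label:
    """Track identity: birth label ``(time, index)`` or spawn label
    ``(parent, time, index)``.

    Spawn labels recursively encode full ancestry, so a daughter-of-daughter
    carries its whole lineage.  Labels are hashable and totally ordered by
    their ancestry chain.
    """

    time: int
    index: int
    parent: Optional["Label"] = None

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("label index must be a positive integer")
        if self.parent is not None and self.time <= self.parent.time:
            raise ValueError("spawn label time must exceed parent birth time")
        # cached ordering key; frozen dataclass, so set via object.__setattr__
        object.__setattr__(self, "_key", self.ancestry())

    @property
    def sort_key(self) -> tuple:
        return self._key

    @property
    def is_spawn(self) -> bool:
        return self.parent is not None

    def ancestry(self) -> tuple:
        """Chain of (time, index) pairs from the founding birth label down."""
        chain = []
        lab: Optional[Label] = self
        while lab is not None:
            chain.append((lab.time, lab.index))
            lab = lab.parent
        return tuple(reversed(chain))

    def root(self) -> "Label":
        lab = self
        while lab.parent is not None:
            lab = lab.parent
        return lab

    def __lt__(self, other: "Label") -> bool:
        return self._key < other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __eq__(self, other) -> bool:
        return isinstance(other, Label) and self._key == other._key

    def __str__(self) -> str:
        return "/".join(f"{t}.{i}" for t, i in self.ancestry())


# ---------------------------------------------------------------------------
# Gaussian component
# ---------------------------------------------------------------------------


def _check_psd(M: np.ndarray, name: str, tol: float = 1e-9) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-8 * (1.0 + np.abs(M).max())):
        raise ValueError(f"{name} must be symmetric")
    M = 0.5 * (M + M.T)
    w = np.linalg.eigvalsh(M)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(f"{name} must be positive semi-definite (min eig {w.min():.3g})")
    return M


@dataclass(eq=False)
class GaussianComponent:
    """Single-object Gaussian density with mean ``x`` and covariance ``P``."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = _check_psd(self.cov, "covariance")
        if self.mean.size != self.cov.shape[0]:
            raise ValueError("mean dimension must equal covariance dimension")

    @property
    def dim(self) -> int:
        return self.mean.size

    def copy(self) -> "GaussianComponent":
        return GaussianComponent.unchecked(self.mean.copy(), self.cov.copy())

    @classmethod
    def unchecked(cls, mean: np.ndarray, cov: np.ndarray) -> "GaussianComponent":
        """Construct without symmetry/PSD validation (internal hot paths;
        callers guarantee a symmetrized covariance)."""
        obj = object.__new__(cls)
        obj.mean = mean
        obj.cov = cov
        return obj


# ---------------------------------------------------------------------------
# Motion models
# ---------------------------------------------------------------------------


@dataclass
class MotionModel:
    """Motion model: linear (``x+ = F x + q``) or constant-turn (``x+ = f(x) + q``)."""

    kind: str  # "linear" | "constant-turn"
    dt: float
    Q: np.ndarray
    F: Optional[np.ndarray] = None
    f: Optional[Callable[[np.ndarray], np.ndarray]] = None
    sigma_v: float = 0.0
    sigma_w: float = 0.0

    def __post_init__(self):
        self.Q = _check_psd(self.Q, "Q")

    @property
    def is_linear(self) -> bool:
        return self.kind == "linear"

    @property
    def dim(self) -> int:
        return self.Q.shape[0]

    def propagate(self, x: np.ndarray) -> np.ndarray:
        """Noise-free state propagation."""
        x = np.asarray(x, dtype=float)
        if self.is_linear:
            return self.F @ x
        return self.f(x)


def make_cv_model(dt: float, sigma_v: float) -> MotionModel:
    """Nearly-constant-velocity model on state [px, py, vx, vy].

    F couples position to velocity with step ``dt``; Q is the white-noise
    acceleration covariance ``sigma_v**2 * G G^T`` with per-axis
    G = [dt^2/2, dt]^T.
    """
    if dt <= 0:
        raise ValueError("step duration dt must be positive")
    if sigma_v < 0:
        raise ValueError("sigma_v must be nonnegative")
    I2 = np.eye(2)
    F = np.block([[I2, dt * I2], [np.zeros((2, 2)), I2]])
    G = np.vstack([dt**2 / 2 * I2, dt * I2])  # 4x2
    Q = sigma_v**2 * (G @ G.T)
    return MotionModel(kind="linear", dt=dt, Q=Q, F=F, sigma_v=sigma_v)


def ct_transition_matrix(w: float, dt: float) -> np.ndarray:
    """Constant-turn transition matrix on [px, py, vx, vy, w].

    Uses series limits sin(w dt)/w -> dt and (1-cos(w dt))/w -> 0 as w -> 0,
    so the w = 0 case reduces exactly to constant velocity.
    """
    wd = w * dt
    if abs(wd) < 1e-10:
        swo = dt * (1.0 - wd * wd / 6.0)
        cwo = 0.5 * w * dt * dt * (1.0 - wd * wd / 12.0)
    else:
        swo = math.sin(wd) / w
        cwo = (1.0 - math.cos(wd)) / w
    c, s = math.cos(wd), math.sin(wd)
    F = np.array(
        [
            [1.0, 0.0, swo, -cwo, 0.0],
            [0.0, 1.0, cwo, swo, 0.0],
            [0.0, 0.0, c, -s, 0.0],
            [0.0, 0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.0],
        ]
    )
    return F


def make_ct_model(dt: float, sigma_w: float, sigma_v: float) -> MotionModel:
    """Constant-turn model on [px, py, vx, vy, w] (w = turn rate, rad/s).

    Planar components follow the turn-rate-dependent rotation; the turn rate
    is a random walk with std ``sigma_w * dt`` per step.
    """
    if dt <= 0:
        raise ValueError("step duration dt must be positive")
    if sigma_w < 0 or sigma_v < 0:
        raise ValueError("noise stds must be nonnegative")
    I2 = np.eye(2)
    G = np.vstack([dt**2 / 2 * I2, dt * I2])  # 4x2
    Q = np.zeros((5, 5))
    Q[:4, :4] = sigma_v**2 * (G @ G.T)
    Q[4, 4] = (sigma_w * dt) ** 2

    def f(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return ct_transition_matrix(float(x[4]), dt) @ x

    return MotionModel(kind="constant-turn", dt=dt, Q=Q, f=f, sigma_v=sigma_v, sigma_w=sigma_w)


# ---------------------------------------------------------------------------
# Observation models
# ---------------------------------------------------------------------------


@dataclass
class ObservationModel:
    """Observation model: linear position, bearing-range, or image PSF.

    Bearing convention: theta = atan2(px, py), i.e. measured clockwise from
    the +y axis, wrapped to (-pi, pi].  This suits half-disc surveillance of
    the upper half-plane (theta in (-pi/2, pi/2)).
    """

    kind: str  # "linear" | "bearing-range" | "image-psf"
    R: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None
    sigma_theta: float = 0.0
    sigma_r: float = 0.0
    # image-psf parameters
    intensity: float = 0.0
    sigma_h: float = 0.0
    sigma_y: float = 0.0
    width: int = 0
    height: int = 0
    template_radius: float = 0.0

    def __post_init__(self):
        if self.R is not None:
            self.R = _check_psd(self.R, "R")
            if np.linalg.eigvalsh(self.R).min() <= 0:
                raise ValueError("R must be positive definite")
        if self.kind == "image-psf" and self.sigma_h <= 0:
            raise ValueError("PSF spread sigma_h must be positive")

    @property
    def meas_dim(self) -> int:
        if self.kind == "linear":
            return self.H.shape[0]
        if self.kind == "bearing-range":
            return 2
        raise ValueError("image-psf model has no point-measurement dimension")

    def h(self, x: np.ndarray) -> np.ndarray:
        """Noise-free measurement function."""
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.H @ x
        if self.kind == "bearing-range":
            px, py = x[0], x[1]
            r = math.hypot(px, py)
            if r == 0.0:
                raise ValueError("bearing undefined at the sensor origin")
            return np.array([math.atan2(px, py), r])
        raise ValueError("image-psf model has no point-measurement function")

    @property
    def peak_amplitude(self) -> float:
        """Noiseless template value at the object pixel: I / (2 pi sigma_h)."""
        return self.intensity / (2.0 * math.pi * self.sigma_h)

    def template_value(self, px: float, py: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """PSF contribution at pixel centres (a, b) from an object at (px, py)."""
        d2 = (np.asarray(a, float) - px) ** 2 + (np.asarray(b, float) - py) ** 2
        return self.peak_amplitude * np.exp(-d2 / (2.0 * self.sigma_h**2))


def make_linear_position_model(sigma_eps: float, state_dim: int = 4) -> ObservationModel:
    """Position-only linear observation z = [px, py] + noise, R = sigma_eps^2 I."""
    if sigma_eps <= 0:
        raise ValueError("sigma_eps must be positive")
    H = np.zeros((2, state_dim))
    H[0, 0] = 1.0
    H[1, 1] = 1.0
    return ObservationModel(kind="linear", H=H, R=sigma_eps**2 * np.eye(2))


def make_bearing_range_model(sigma_theta: float, sigma_r: float) -> ObservationModel:
    """Bearing-range observation z = [theta, r], R = diag(sigma_theta^2, sigma_r^2)."""
    if sigma_theta <= 0 or sigma_r <= 0:
        raise ValueError("sigma_theta and sigma_r must be positive")
    return ObservationModel(
        kind="bearing-range",
        R=np.diag([sigma_theta**2, sigma_r**2]),
        sigma_theta=sigma_theta,
        sigma_r=sigma_r,
    )


def make_image_psf_model(
    intensity: float,
    sigma_h: float,
    sigma_y: float,
    width: int,
    height: int,
    template_radius: Optional[float] = None,
) -> ObservationModel:
    """Point-spread-function image model: Gaussian blob of spread ``sigma_h``
    (pixels), peak ``intensity/(2 pi sigma_h)``, additive pixel noise std
    ``sigma_y``.  The evaluation template is truncated at ``template_radius``
    (default 3 sigma_h)."""
    if template_radius is None:
        template_radius = 3.0 * sigma_h
    return ObservationModel(
        kind="image-psf",
        intensity=intensity,
        sigma_h=sigma_h,
        sigma_y=sigma_y,
        width=int(width),
        height=int(height),
        template_radius=float(template_radius),
    )


# ---------------------------------------------------------------------------
# Birth / spawn models
# ---------------------------------------------------------------------------


@dataclass
class BirthComponent:
    r: float
    mean: np.ndarray
    cov: np.ndarray
    index: int

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("birth probability must lie in [0, 1]")
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = _check_psd(self.cov, "birth covariance")


@dataclass
class BirthModel:
    """Labelled multi-Bernoulli birth: static components, or measurement-driven
    (adaptive) births centred on the previous scan's measurements.

    Adaptive mode: component ``j`` at frame ``k+1`` sits at measurement
    ``z_j`` from frame ``k`` with existence probability
    ``min(r_cap, r0 * (1 - association mass of z_j))``.  During the first
    ``n_init_frames`` updates the cap is ``r_init`` (close to 1) instead, so
    the initial population — including objects missed in the very first
    scan — is bootstrapped from unassociated measurements.
    """

    components: Sequence[BirthComponent] = field(default_factory=list)
    adaptive: bool = False
    r_init: float = 0.99
    r_cap: float = 1e-7
    r0: float = 1.0
    n_init_frames: int = 3
    birth_cov: Optional[np.ndarray] = None
    pos_to_state: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        idx = [c.index for c in self.components]
        if len(set(idx)) != len(idx):
            raise ValueError("birth component labels must be distinct within a frame")
        if self.birth_cov is not None:
            self.birth_cov = _check_psd(self.birth_cov, "adaptive birth covariance")

    def static_components(self) -> Sequence[BirthComponent]:
        return list(self.components)

    def adaptive_components(
        self,
        prev_measurements: np.ndarray,
        assoc_mass: np.ndarray,
        init_phase: bool,
    ) -> list[BirthComponent]:
        """Measurement-driven birth components for the next update."""
        comps = []
        if prev_measurements is None or len(prev_measurements) == 0:
            return comps
        cap = self.r_init if init_phase else self.r_cap
        for j, z in enumerate(np.atleast_2d(prev_measurements)):
            r = min(cap, self.r0 * (1.0 - float(assoc_mass[j])))
            if r <= 1e-12:
                continue
            mean = self.pos_to_state(z) if self.pos_to_state is not None else np.asarray(z, float)
            comps.append(BirthComponent(r=r, mean=mean, cov=self.birth_cov, index=j + 1))
        return comps


@dataclass
class SpawnModel:
    """Per-parent spawning (cell division): each existing object generates up
    to ``max_offspring`` daughters per frame, each with probability ``p_t``
    and state ``f_t(parent) + N(0, Q_t)`` (``f_t`` defaults to identity)."""

    p_t: float
    Q_t: np.ndarray
    f_t: Optional[Callable[[np.ndarray], np.ndarray]] = None
    max_offspring: int = 1

    def __post_init__(self):
        if not 0.0 <= self.p_t <= 1.0:
            raise ValueError("spawn probability must lie in [0, 1]")
        self.Q_t = _check_psd(self.Q_t, "Q_t")

    @property
    def q_t(self) -> float:
        return 1.0 - self.p_t

    def offspring_map(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float) if self.f_t is None else self.f_t(x)


# ---------------------------------------------------------------------------
# Clutter / detection models
# ---------------------------------------------------------------------------


@dataclass
class RectSupport:
    """Axis-aligned box support in measurement space."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        self.lo = np.asarray(self.lo, dtype=float).ravel()
        self.hi = np.asarray(self.hi, dtype=float).ravel()
        if np.any(self.hi <= self.lo):
            raise ValueError("support must have positive measure")

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    def contains(self, z: np.ndarray) -> bool:
        z = np.asarray(z, dtype=float).ravel()
        return bool(np.all(z >= self.lo) and np.all(z <= self.hi))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, self.lo.size))


@dataclass
class PolarSupport:
    """Half-disc surveillance expressed in (theta, r) measurement space;
    clutter uniform in polar coordinates over (theta_lo, theta_hi] x [0, r_max]."""

    r_max: float
    theta_lo: float = -np.pi / 2
    theta_hi: float = np.pi / 2

    @property
    def volume(self) -> float:
        return (self.theta_hi - self.theta_lo) * self.r_max

    def contains(self, z: np.ndarray) -> bool:
        th, r = float(z[0]), float(z[1])
        return self.theta_lo <= th <= self.theta_hi and 0.0 <= r <= self.r_max

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        th = rng.uniform(self.theta_lo, self.theta_hi, size=n)
        r = rng.uniform(0.0, self.r_max, size=n)
        return np.column_stack([th, r])


@dataclass
class ClutterModel:
    """Poisson clutter: ``rate`` expected false alarms per scan, uniform over
    the support; intensity kappa(z) = rate / V inside, 0 outside."""

    rate: float
    support: object

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("clutter rate must be nonnegative")

    def intensity(self, z: np.ndarray) -> float:
        return clutter_intensity(z, self)

    def log_intensity_floor(self) -> float:
        """log kappa used in association ratios; uniform so constant."""
        if self.rate == 0.0:
            # A zero-clutter model still needs a finite reference density so
            # detection ratios stay well-defined; use an arbitrarily small one.
            return math.log(1e-300)
        return math.log(self.rate / self.support.volume)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        n = rng.poisson(self.rate)
        return self.support.sample(rng, n)


def clutter_intensity(z: np.ndarray, model: ClutterModel) -> float:
    """Clutter intensity kappa(z) = rate / V for z in the support, else 0."""
    if model.support.volume <= 0:
        raise ValueError("clutter support must have positive measure")
    if model.rate == 0.0:
        return 0.0
    return model.rate / model.support.volume if model.support.contains(z) else 0.0


@dataclass
class DetectionModel:
    p_d: float
    p_s: float

    def __post_init__(self):
        for name, v in (("p_d", self.p_d), ("p_s", self.p_s)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def q_d(self) -> float:
        return 1.0 - self.p_d

    @property
    def q_s(self) -> float:
        return 1.0 - self.p_s
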