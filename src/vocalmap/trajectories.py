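"""Motor and perceptual trajectories: sampled time functions through the spaces.

A trajectory is a function from a time interval [0, T] into motor or
perceptual space, represented on a uniform sample grid.  Motor trajectories
are continuous (the vocal tract moves through intermediate states) and are
evaluated by linear interpolation; perceptual trajectories may be
discontinuous (stop closures, periodicity switches) and are evaluated by
nearest sample.

Absolute duration is not meaningful in the model: two motor trajectories are
*equivalent* when one is a uniform temporal stretch of the other.  Each
equivalence class has a canonical representative whose domain is [0, s],
where s is the syllable count read off the jaw-cycle coordinate jdir.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .spaces import (
    N_ARTIC,
    N_SOUND,
    JDIR_IDX,
    ValidationError,
    d_artic,
    d_sounds,
)

__all__ = [
    "MotorTrajectory",
    "PerceptualTrajectory",
    "syllable_count",
    "normalize_time",
    "equivalent",
    "traj_distance_motor",
    "traj_distance_perceptual",
    "continuity_violation",
]

#: default grid resolution (samples per syllable / per unit normalized time)
DEFAULT_SAMPLES_PER_SYLLABLE = 64
#: default quadrature grid for trajectory distances (odd -> includes t=0.5)
DEFAULT_QUAD_POINTS = 513
#: hysteresis around 0 when classifying jdir sign for syllable counting
JDIR_HYSTERESIS = 0.05
#: default Lipschitz bound for the sampled-continuity surrogate (d_artic units
#: per unit normalized time); generous enough for sharp consonantal closures,
#: whose derivative coordinates change fastest
DEFAULT_KAPPA = 200.0

_ids = itertools.count()


def fresh_id(prefix: str) -> str:
    return f"{prefix}{next(_ids):06d}"


@dataclass(frozen=True)
class _BaseTrajectory:
    times: np.ndarray
    values: np.ndarray
    id: str = ""

    _DIM = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 2 or len(t) != len(v):
            raise ValidationError("times must be (n,), values (n, dim) with matching n")
        if v.shape[1] != self._DIM:
            raise ValidationError(f"expected {self._DIM} coordinates, got {v.shape[1]}")
        if len(t) < 2:
            raise ValidationError("a trajectory needs at least two samples")
        if abs(t[0]) > 1e-12:
            raise ValidationError("time grid must start at 0")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if np.max(dt) - np.min(dt) > 1e-9 * max(t[-1], 1.0):
            raise ValidationError("time grid must be uniform")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if not self.id:
            object.__setattr__(self, "id", fresh_id("traj-"))

    @property
    def domain_end(self) -> float:
        return float(self.times[-1])

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def _check_domain(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-9) or np.any(t > self.domain_end + 1e-9):
            raise ValidationError(
                f"time outside domain [0, {self.domain_end}]"
            )
        return np.clip(t, 0.0, self.domain_end)

    def at_relative(self, u) -> np.ndarray:
        """Evaluate at relative times u in [0, 1] (u scaled by the domain)."""
        return self.evaluate(np.asarray(u, dtype=float) * self.domain_end)


@dataclass(frozen=True)
class MotorTrajectory(_BaseTrajectory):
    """A sampled continuous excursion through motor space."""

    _DIM = N_ARTIC

    def evaluate(self, t) -> np.ndarray:
        """Linear interpolation between bracketing samples."""
        t = self._check_domain(t)
        scalar = t.ndim == 0
        tq = np.atleast_1d(t)
        step = self.times[1] - self.times[0]
        pos = np.clip(tq / step, 0.0, len(self.times) - 1.0)
        lo = np.minimum(pos.astype(int), len(self.times) - 2)
        frac = (pos - lo)[:, None]
        out = (1.0 - frac) * self.values[lo] + frac * self.values[lo + 1]
        return out[0] if scalar else out


@dataclass(frozen=True)
class PerceptualTrajectory(_BaseTrajectory):
    """A sampled (possibly discontinuous) excursion through perceptual space."""

    _DIM = N_SOUND
    #: syllable count, known only for self-productions (set via the map)
    syllables: int | None = None

    def evaluate(self, t) -> np.ndarray:
        """Nearest-sample evaluation (discontinuities are allowed)."""
        t = self._check_domain(t)
        scalar = t.ndim == 0
        tq = np.atleast_1d(t)
        step = self.times[1] - self.times[0]
        idx = np.clip(np.round(tq / step).astype(int), 0, len(self.times) - 1)
        out = self.values[idx]
        return out[0] if scalar else out


def evaluate(traj, t):
    """Functional form of trajectory evaluation (dispatches on the object)."""
    return traj.evaluate(t)


def continuity_violation(m: MotorTrajectory, kappa: float) -> float:
    """Max excess of adjacent-sample articulatory speed over the bound kappa.

    Returns max(d_artic(adjacent samples) - kappa * dt); non-positive values
    mean the sampled curve satisfies the Lipschitz continuity surrogate.
    """
    dt = m.times[1] - m.times[0]
    step = d_artic(m.values[:-1], m.values[1:])
    return float(np.max(step) - kappa * dt)


def syllable_count(m: MotorTrajectory, hysteresis: float = JDIR_HYSTERESIS) -> int:
    """Count complete open-close jaw cycles from the jdir coordinate.

    A syllable is a maximal run of jaw opening (jdir > hysteresis) followed —
    after optional neutral spans — by a run of jaw closing (jdir < -hysteresis).
    The hysteresis band ignores numerical chatter around zero.
    """
    j = m.values[:, JDIR_IDX]
    signs = np.where(j > hysteresis, 1, np.where(j < -hysteresis, -1, 0))
    runs = [s for s, _ in itertools.groupby(signs) if s != 0]
    return sum(1 for a, b in zip(runs, runs[1:]) if a == 1 and b == -1)


def normalize_time(m: MotorTrajectory, hysteresis: float = JDIR_HYSTERESIS) -> MotorTrajectory:
    """Uniformly stretch m so its domain is [0, s], s its syllable count.

    The result is the canonical representative of m's equivalence class.
    Raises for zero-syllable trajectories, for which no representative exists.
    """
    s = syllable_count(m, hysteresis)
    if s < 1:
        raise ValidationError("cannot normalize a trajectory with 0 syllables")
    if abs(m.domain_end - s) < 1e-12:
        return m
    scale = s / m.domain_end
    return replace(m, times=m.times * scale)


def equivalent(
    m: MotorTrajectory,
    n: MotorTrajectory,
    tol: float = 1e-3,
    n_check: int = DEFAULT_QUAD_POINTS,
) -> bool:
    """True iff n is (within tol) a uniform temporal stretch of m.

    Checked as max_t d_artic(m(T t), n(U t)) <= tol on a dense relative grid.
    """
    u = np.linspace(0.0, 1.0, n_check)
    d = d_artic(m.at_relative(u), n.at_relative(u))
    return bool(np.max(d) <= tol)


def _pair_quadrature(a, b, dist, n_quad):
    u = np.linspace(0.0, 1.0, n_quad)
    d = dist(a.at_relative(u), b.at_relative(u))
    return float(np.trapezoid(d, u))


def traj_distance_motor(
    m: MotorTrajectory, m2: MotorTrajectory, n_quad: int = DEFAULT_QUAD_POINTS
) -> float:
    """Motor trajectory pseudometric: integral of d_artic on aligned relative time.

    Zero exactly on uniform-stretch equivalent pairs, so it induces a true
    metric on equivalence classes.
    """
    return _pair_quadrature(m, m2, d_artic, n_quad)


def traj_distance_perceptual(
    p: PerceptualTrajectory, p2: PerceptualTrajectory, n_quad: int = DEFAULT_QUAD_POINTS
) -> float:
    """Perceptual trajectory pseudometric: integral of d_sounds on relative time."""
    return _pair_quadrature(p, p2, d_sounds, n_quad)
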