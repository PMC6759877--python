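"""The perceptual-motor map: linked motor/perceptual trajectory pairs.

Every vocalization leaves a motor memory trace and an auditory memory trace
associated in time; the map is the bijection between the two trajectory sets.
Exemplars (adult word forms) live in the same perceptual space but have no
motor partner and are stored outside the bijection.

The auditory consequence of a motor trajectory is produced by a fixed
deterministic *forward map* from articulatory configurations to instantaneous
sounds.  The model's claims do not depend on its details, only on it being a
fixed continuous function, so a simple affine surrogate is used: periodicity
follows glottal width, formants follow the mid/rear tract areas and velum,
noise spectrum follows the front tract areas and glottis, and loudness change
follows the jaw.  All coefficients are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spaces import ValidationError, apply_sound_zeroing
from .trajectories import MotorTrajectory, PerceptualTrajectory, normalize_time, syllable_count

__all__ = ["ForwardMap", "PerceptualMotorMap"]


@dataclass(frozen=True)
class ForwardMap:
    """Deterministic continuous surrogate ArticConfig -> SoundPoint.

    per = 1 iff g < g_voicing (a narrow glottis vibrates); when periodic the
    three formants are affine in (c4, c5, c6, v); when aperiodic the spectral
    center of gravity and peak width are affine in (c7, c8, g); the loudness
    derivative is proportional to jdir.  Spectral time derivatives are finite
    differences of the raw spectral series along the trajectory, computed
    before the periodicity zeroing is applied.
    """

    g_voicing: float = 0.5
    # rows: Z1, Z2, Z3; columns: bias, c4, c5, c6, v
    formant_coef: tuple = (
        (2.0, 3.0, 1.0, 0.0, 0.5),
        (6.0, 1.0, 4.0, 1.0, -0.5),
        (10.0, 0.5, 1.0, 3.0, 1.0),
    )
    # rows: cog, width; columns: bias, c7, c8, g
    noise_coef: tuple = (
        (3.0, 4.0, 2.0, 1.0),
        (1.0, 1.0, 2.0, 0.5),
    )
    loudness_gain: float = 1.0

    def sound_fields(self, artic: np.ndarray) -> dict[str, np.ndarray]:
        """Raw (pre-zeroing) acoustic fields for an (n, 20) configuration array."""
        a = np.atleast_2d(np.asarray(artic, dtype=float))
        g, v, j = a[:, 0], a[:, 9], a[:, 19]
        per = (g < self.g_voicing).astype(float)
        fc = np.asarray(self.formant_coef)
        X = np.column_stack([np.ones(len(a)), a[:, 4], a[:, 5], a[:, 6], v])
        Z = X @ fc.T  # (n, 3)
        nc = np.asarray(self.noise_coef)
        Y = np.column_stack([np.ones(len(a)), a[:, 7], a[:, 8], g])
        NW = Y @ nc.T  # (n, 2)
        return {
            "dLoud": self.loudness_gain * j,
            "per": per,
            "Z": Z,
            "cog": NW[:, 0],
            "width": NW[:, 1],
        }

    def __call__(self, m: MotorTrajectory) -> PerceptualTrajectory:
        """Map a motor trajectory samplewise to its perceptual trajectory."""
        f = self.sound_fields(m.values)
        t = m.times
        dZ = np.gradient(f["Z"], t, axis=0)
        dCog = np.gradient(f["cog"], t)
        dWidth = np.gradient(f["width"], t)
        raw = np.column_stack(
            [f["dLoud"], f["per"], f["Z"], f["cog"], f["width"], dZ, dCog, dWidth]
        )
        vals = apply_sound_zeroing(raw)
        return PerceptualTrajectory(times=t.copy(), values=vals, syllables=None)


class PerceptualMotorMap:
    """Registry of linked (motor id <-> perceptual id) trajectory token pairs.

    Every recorded vocalization creates a fresh token pair even when its
    content duplicates an existing trajectory; the link structure is a
    bijection at all times.  Exemplars are stored separately, unlinked.
    """

    def __init__(self, forward_map: ForwardMap | None = None):
        self.forward_map = forward_map or ForwardMap()
        self.motor: dict[str, MotorTrajectory] = {}
        self.perceptual: dict[str, PerceptualTrajectory] = {}
        self._partner: dict[str, str] = {}
        self._counter = 0

    # -- core operations ---------------------------------------------------

    def record_vocalization(self, m: MotorTrajectory) -> tuple[str, str]:
        """Store a vocalization: normalized motor trace + linked auditory trace."""
        mn = normalize_time(m)
        s = syllable_count(mn)
        self._counter += 1
        mid, pid = f"m{self._counter:06d}", f"p{self._counter:06d}"
        mn = replace(mn, id=mid)
        p = self.forward_map(mn)
        p = replace(p, id=pid, syllables=s)
        self.motor[mid] = mn
        self.perceptual[pid] = p
        self._partner[mid] = pid
        self._partner[pid] = mid
        return mid, pid

    def linked(self, trajectory_id: str) -> str:
        """The unique partner id of a registered trajectory id."""
        try:
            return self._partner[trajectory_id]
        except KeyError:
            raise ValidationError(f"unknown trajectory id {trajectory_id!r}") from None

    # -- access ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.motor)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(mid, self._partner[mid]) for mid in self.motor]

    def get(self, trajectory_id: str):
        if trajectory_id in self.motor:
            return self.motor[trajectory_id]
        if trajectory_id in self.perceptual:
            return self.perceptual[trajectory_id]
        raise ValidationError(f"unknown trajectory id {trajectory_id!r}")

    def check_bijection(self) -> bool:
        """Invariant: partner-of-partner is the identity and ids are disjoint."""
        if set(self.motor) & set(self.perceptual):
            return False
        if len(self._partner) != len(self.motor) + len(self.perceptual):
            return False
        return all(self._partner[self._partner[x]] == x for x in self._partner)
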