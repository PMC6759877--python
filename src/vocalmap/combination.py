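"""Piecewise combination of motor trajectories through near-crossings.

A novel motor trajectory is built by concatenating juncture-delimited pieces
of existing trajectories, connected by short linear bridging segments of
normalized duration delta between configurations that lie within eps of each
other in motor space.  The raw concatenation is then uniformly stretched by
u = s / raw_duration so the result occupies its canonical domain [0, s], where
s is the syllable count of the assembled curve (recomputed from its jaw
coordinate, never assumed).  The bridge endpoints become junctures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from math import gcd

import numpy as np

from .junctures import ClusterState, Juncture
from .spaces import ValidationError, d_artic
from .trajectories import MotorTrajectory, syllable_count

__all__ = ["Piece", "CombineSpec", "CombineResult", "bridge", "combine", "stretch_param"]

DEFAULT_DELTA = 0.1


@dataclass(frozen=True)
class Piece:
    """A sub-path of a stored trajectory: enter at ``start``, exit at ``end``."""

    traj_id: str
    start: float
    end: float

    def __post_init__(self):
        if not 0.0 <= self.start < self.end:
            raise ValidationError("piece requires 0 <= start < end")


@dataclass(frozen=True)
class CombineSpec:
    """An ordered list of pieces plus the bridge durations between them."""

    pieces: tuple
    deltas: tuple = ()

    def __post_init__(self):
        if len(self.pieces) < 2:
            raise ValidationError("a combination needs at least two pieces")
        deltas = self.deltas or (DEFAULT_DELTA,) * (len(self.pieces) - 1)
        if len(deltas) != len(self.pieces) - 1:
            raise ValidationError("need one bridge duration per seam")
        if any(d <= 0 for d in deltas):
            raise ValidationError("bridge durations must be positive")
        object.__setattr__(self, "pieces", tuple(self.pieces))
        object.__setattr__(self, "deltas", tuple(deltas))

    @classmethod
    def two_piece(cls, id1, exit_t, id2, entry_t, end2, delta=DEFAULT_DELTA):
        """The canonical case: leave trajectory 1 at exit_t, enter 2 at entry_t."""
        return cls(
            pieces=(Piece(id1, 0.0, exit_t), Piece(id2, entry_t, end2)),
            deltas=(delta,),
        )

    def signature(self) -> tuple:
        return tuple(
            (p.traj_id, round(p.start, 9), round(p.end, 9)) for p in self.pieces
        ) + tuple(round(d, 9) for d in self.deltas)


@dataclass(frozen=True)
class CombineResult:
    trajectory: MotorTrajectory
    u: float
    raw_duration: float
    s: int
    junctures: tuple
    #: seam times on the *stretched* result: [(exit time, entry time), ...]
    seams: tuple


def bridge(a1, a2, t_start: float, t_end: float):
    """The linear bridging segment (1 - lam(t)) a1 + lam(t) a2 on [t_start, t_end].

    lam is affine with lam(t_start) = 0 and lam(t_end) = 1; for the window
    [0.6, 0.7] this is lam(t) = 10 t - 6.  Returns the callable segment.
    """
    if not t_start < t_end:
        raise ValidationError("bridge requires t_start < t_end")
    a1 = np.asarray(getattr(a1, "values", a1), dtype=float)
    a2 = np.asarray(getattr(a2, "values", a2), dtype=float)

    def segment(t):
        lam = (np.asarray(t, dtype=float) - t_start) / (t_end - t_start)
        return (1.0 - lam)[..., None] * a1 + lam[..., None] * a2 if lam.ndim else (
            (1.0 - lam) * a1 + lam * a2
        )

    return segment


def stretch_param(raw_duration: float, s_target: int) -> float:
    """Stretching parameter u mapping the raw timeline onto the domain [0, s]."""
    if raw_duration <= 0 or s_target < 1:
        raise ValidationError("raw_duration must be > 0 and s_target >= 1")
    return s_target / raw_duration


def _aligned_grid(breakpoints: list[float], min_step: float) -> np.ndarray:
    """Uniform grid over [0, breakpoints[-1]] whose step divides every breakpoint.

    Breakpoints are approximated by small-denominator rationals; when that is
    possible within 1e-9 the seam times land exactly on grid samples (so the
    piecewise formula is reproduced exactly at the seams).  Otherwise a plain
    uniform grid at the requested resolution is returned.
    """
    total = breakpoints[-1]
    fracs = [Fraction(b).limit_denominator(4096) for b in breakpoints]
    if all(abs(float(f) - b) < 1e-9 for f, b in zip(fracs, breakpoints)):
        den = 1
        for f in fracs:
            den = den * f.denominator // gcd(den, f.denominator)
        # refine to at least the requested resolution, cap the sample count
        mult = max(1, int(np.ceil(1.0 / (min_step * den))))
        n = int(round(total * den * mult))
        if 2 <= n <= 20000:
            return np.linspace(0.0, total, n + 1)
    n = max(2, int(np.ceil(total / min_step)))
    return np.linspace(0.0, total, n + 1)


def combine(
    spec: CombineSpec,
    pm,
    state: ClusterState | None = None,
    *,
    eps: float = 0.15,
    samples_per_syllable: int | None = None,
    record: bool = True,
) -> CombineResult:
    """Execute a combination: assemble, renormalize, record, register junctures.

    Every bridge's endpoint configurations must be within eps of each other
    (the achievability condition); otherwise the combination is rejected.
    When ``record`` is true the result is stored in the perceptual-motor map
    (creating its auditory partner) and the bridge endpoints become junctures
    in ``state``.
    """
    trajs = [pm.get(p.traj_id) for p in spec.pieces]
    for p, tr in zip(spec.pieces, trajs):
        if p.end > tr.domain_end + 1e-9:
            raise ValidationError(f"piece end {p.end} outside domain of {p.traj_id}")

    # raw timeline: piece 1 | bridge | piece 2 | bridge | ...
    exits = [tr.evaluate(p.end) for p, tr in zip(spec.pieces[:-1], trajs[:-1])]
    entries = [tr.evaluate(p.start) for p, tr in zip(spec.pieces[1:], trajs[1:])]
    for i, (a1, a2) in enumerate(zip(exits, entries)):
        d = d_artic(a1, a2)
        if d >= eps:
            raise ValidationError(
                f"bridge {i} endpoints are {d:.4f} apart (>= eps = {eps}); "
                "combination not eligible"
            )

    breaks = [0.0]
    for i, p in enumerate(spec.pieces):
        breaks.append(breaks[-1] + (p.end - p.start))
        if i < len(spec.deltas):
            breaks.append(breaks[-1] + spec.deltas[i])
    raw_duration = breaks[-1]

    # default resolution: the finest source grid, so piece samples land on
    # source sample times wherever the seams allow it
    if samples_per_syllable is None:
        min_step = min(float(tr.times[1] - tr.times[0]) for tr in trajs)
    else:
        min_step = 1.0 / samples_per_syllable
    times = _aligned_grid(breaks[1:], min_step=min_step)
    values = np.empty((len(times), trajs[0].values.shape[1]))
    seg = 0  # alternating: even -> piece seg//2, odd -> bridge (seg-1)//2
    for k, t in enumerate(times):
        while seg < len(breaks) - 2 and t > breaks[seg + 1] + 1e-12:
            seg += 1
        if seg % 2 == 0:
            p, tr = spec.pieces[seg // 2], trajs[seg // 2]
            values[k] = tr.evaluate(min(p.start + (t - breaks[seg]), p.end))
        else:
            i = (seg - 1) // 2
            values[k] = bridge(exits[i], entries[i], breaks[seg], breaks[seg + 1])(t)

    raw = MotorTrajectory(times=times, values=values)
    s = syllable_count(raw)
    if s < 1:
        raise ValidationError("combined trajectory has no complete syllable")
    u = stretch_param(raw_duration, s)
    stretched = replace(raw, times=times * u)

    seam_times = []
    for i in range(len(spec.deltas)):
        t_exit = breaks[2 * i + 1] * u
        t_entry = breaks[2 * i + 2] * u
        seam_times.append((t_exit, t_entry))

    junctures = []
    if record:
        mid, _ = pm.record_vocalization(stretched)
        stretched = pm.motor[mid]
        for i, ((t_exit, t_entry), a1, a2) in enumerate(zip(seam_times, exits, entries)):
            origin = f"combination:{stretched.id}:seam{i}"
            junctures.append(
                Juncture(spec.pieces[i].traj_id, spec.pieces[i].end, np.asarray(a1), origin)
            )
            junctures.append(
                Juncture(spec.pieces[i + 1].traj_id, spec.pieces[i + 1].start, np.asarray(a2), origin)
            )
        if state is not None:
            state.register_combination_junctures(junctures)

    return CombineResult(
        trajectory=stretched,
        u=u,
        raw_duration=raw_duration,
        s=s,
        junctures=tuple(junctures),
        seams=tuple(seam_times),
    )
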