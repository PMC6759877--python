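"""Matching and selection: how a word attempt picks a linked trajectory pair.

Given a concept's exemplar (a perceptual target with a salience weighting),
the speaker searches the trajectories they can actually produce — previously
recorded vocalizations plus combinations reachable through near-crossings —
for the linked pair best fulfilling:

1. achievability (the motor trajectory exists or is an eps-eligible
   combination of existing pieces),
2. a small salience-weighted perceptual distance to the exemplar,
3. favoredness (practiced trajectories and chunk sequences are preferred),
4/4*. when a schema or silhouette for the concept exists, a good alignment of
   that motor form with a span of the candidate.

"Best fulfill" is operationalized as the weighted sum
w_perc * c2 - w_fav * favoredness + w_fit * c4, with a lexicographic mode as
an alternative; the thresholds theta are feasibility gates for modeling
communicative success, not part of the argmin.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentSpan, best_span
from .combination import CombineSpec, Piece, combine
from .phonforms import Schema, Silhouette
from .spaces import ValidationError, d_artic, d_sounds
from .trajectories import (
    DEFAULT_QUAD_POINTS,
    MotorTrajectory,
    PerceptualTrajectory,
    normalize_time,
)
from .junctures import find_near_crossings

__all__ = [
    "SalienceFn",
    "Exemplar",
    "MatchConfig",
    "UsageStats",
    "weighted_perceptual_distance",
    "favoredness",
    "schema_fit",
    "silhouette_fit",
    "select",
    "Candidate",
    "SelectionResult",
]


class SalienceFn:
    """Time-varying attention weight on an exemplar: [0, T] -> [0, 1]."""

    def __init__(self, fn, domain_end: float):
        self._fn = fn
        self.domain_end = float(domain_end)

    def __call__(self, t):
        out = np.asarray(self._fn(np.asarray(t, dtype=float)), dtype=float)
        if out.size and (out.min() < -1e-9 or out.max() > 1 + 1e-9):
            raise ValidationError("salience values must lie in [0, 1]")
        return np.clip(out, 0.0, 1.0)

    @classmethod
    def constant(cls, value: float, domain_end: float) -> "SalienceFn":
        return cls(lambda t: np.full_like(np.asarray(t, dtype=float), value), domain_end)

    @classmethod
    def step(cls, domain_end: float, boundary: float | None = None) -> "SalienceFn":
        """Fully salient first portion, non-salient remainder.

        With the default boundary T/2 this is the canonical case of an infant
        attending only to the first syllable of a two-syllable target.
        """
        b = domain_end / 2.0 if boundary is None else boundary
        return cls(lambda t: np.where(np.asarray(t, dtype=float) <= b, 1.0, 0.0), domain_end)

    @classmethod
    def from_samples(cls, times: np.ndarray, values: np.ndarray) -> "SalienceFn":
        times = np.asarray(times, dtype=float)
        values = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
        return cls(lambda t: np.interp(t, times, values), times[-1])

    def sampled(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, self.domain_end, n)
        return t, self(t)


@dataclass(frozen=True)
class Exemplar:
    """An adult perceptual word form: trajectory + concept link, no motor partner."""

    trajectory: PerceptualTrajectory
    concept: str
    salience: SalienceFn

    def __post_init__(self):
        if abs(self.salience.domain_end - self.trajectory.domain_end) > 1e-9:
            raise ValidationError("salience domain must match the exemplar domain")


@dataclass
class MatchConfig:
    """Weights, thresholds and search resolutions for matching and selection."""

    w_perc: float = 1.0
    w_fav: float = 0.2
    w_fit: float = 1.0
    theta_2: float = 0.5  # "small enough" gate for criterion 2 (success model)
    theta_4: float = 0.3  # gate for criteria 4 / 4*
    k: float = 0.5  # minimum alignment span, in syllables
    n_quad: int = DEFAULT_QUAD_POINTS  # quadrature for criterion 2
    fit_span_points: int = 9  # alpha/beta grid for criteria 4 / 4*
    fit_quad_points: int = 9
    max_pivots: int = 2  # L: bridges allowed per combination candidate
    max_combination_candidates: int = 24
    hits_per_pair: int = 2
    delta: float = 0.1  # bridge duration for combination candidates
    min_piece: float = 0.25  # shortest usable piece, in syllables
    pivot_pool_size: int = 16
    eps: float = 0.15
    mode: str = "additive"  # or "lexicographic"

    def __post_init__(self):
        if min(self.w_perc, self.w_fav, self.w_fit) < 0:
            raise ValidationError("weights must be non-negative")
        if min(self.theta_2, self.theta_4) <= 0:
            raise ValidationError("thresholds must be positive")
        if self.mode not in ("additive", "lexicographic"):
            raise ValidationError("mode must be 'additive' or 'lexicographic'")


# ---------------------------------------------------------------------------
# criterion 2

def weighted_perceptual_distance(
    e: Exemplar, p: PerceptualTrajectory, n_quad: int = DEFAULT_QUAD_POINTS
) -> float:
    """Salience-weighted perceptual distance (criterion 2).

    Both trajectories are stretched onto [0, 1] (start aligned to start, end
    to end) and the pointwise perceptual distance, weighted by the exemplar's
    salience at the corresponding time, is averaged:

        integral_0^1 salience(T t) * d_sounds(e(T t), p(s t)) dt.

    With salience identically 1 this reduces to the perceptual trajectory
    pseudometric.
    """
    u = np.linspace(0.0, 1.0, n_quad)
    T = e.trajectory.domain_end
    sal = e.salience(T * u)
    d = d_sounds(e.trajectory.at_relative(u), p.at_relative(u))
    return float(np.trapezoid(sal * d, u))


# ---------------------------------------------------------------------------
# criterion 3

def seam_key(piece_a: Piece, piece_b: Piece) -> tuple:
    return (piece_a.traj_id, round(piece_a.end, 6), piece_b.traj_id, round(piece_b.start, 6))


@dataclass
class UsageStats:
    """Traversal counts per trajectory and co-traversal counts per seam."""

    traversals: Counter = field(default_factory=Counter)
    co_traversals: Counter = field(default_factory=Counter)

    def record_traversal(self, traj_id: str, n: int = 1):
        self.traversals[traj_id] += n

    def record_combination(self, spec: CombineSpec, n: int = 1):
        for a, b in zip(spec.pieces, spec.pieces[1:]):
            self.co_traversals[seam_key(a, b)] += n
        for p in spec.pieces:
            self.traversals[p.traj_id] += n


def favoredness(candidate, usage: UsageStats) -> float:
    """Monotone practice score (criterion 3): log(1 + count).

    For a plain trajectory the count is its traversal count; for a combination
    it is the smallest co-traversal count over the combination's seams (a
    chain is only as practiced as its least-practiced join).
    """
    if isinstance(candidate, CombineSpec):
        count = min(
            usage.co_traversals[seam_key(a, b)]
            for a, b in zip(candidate.pieces, candidate.pieces[1:])
        )
    else:
        count = usage.traversals[candidate]
    return math.log1p(count)


# ---------------------------------------------------------------------------
# criteria 4 and 4*

def schema_fit(
    m1: MotorTrajectory,
    schema,
    k: float,
    n_span: int = 17,
    n_quad: int = 17,
) -> tuple[float, AlignmentSpan]:
    """Criterion 4: best mean distance of the schema aligned onto a span of m1."""
    traj = normalize_time(m1)
    sch = schema.trajectory if isinstance(schema, Schema) else schema
    sch = normalize_time(sch)

    def pointwise(ts, hs):
        return d_artic(traj.evaluate(ts), sch.evaluate(hs))

    value, span = best_span(traj.domain_end, sch.domain_end, k, pointwise, n_span, n_quad)
    return value, span


def silhouette_fit(
    m: MotorTrajectory,
    sil: Silhouette,
    k: float,
    n_span: int = 17,
    n_quad: int = 17,
) -> tuple[float, AlignmentSpan]:
    """Criterion 4*: like criterion 4, but distance to the silhouette's regions.

    The integrand is the distance from m(t) to the *region* of the silhouette
    at the aligned time — a generalization of criterion 4 that coincides with
    it when every region is a single point.
    """
    traj = normalize_time(m)

    def pointwise(ts, hs):
        return sil.distance_profile(hs, traj.evaluate(ts))

    value, span = best_span(traj.domain_end, sil.domain_end, k, pointwise, n_span, n_quad)
    return value, span


# ---------------------------------------------------------------------------
# candidate search and selection

@dataclass(frozen=True)
class Candidate:
    cid: str
    kind: str  # "existing" | "combination"
    motor: MotorTrajectory
    perceptual: PerceptualTrajectory
    spec: CombineSpec | None = None


@dataclass
class SelectionResult:
    candidate: Candidate
    objective: float
    c2: float
    fav: float
    fit: float | None
    fit_span: AlignmentSpan | None


def _pivot_pool(pm, usage: UsageStats, size: int) -> list[str]:
    ids = [mid for mid in pm.motor if usage.traversals[mid] > 0]
    ids.sort(key=lambda i: (-usage.traversals[i], i))
    return ids[:size]


def enumerate_combination_specs(
    pm,
    usage: UsageStats,
    config: MatchConfig,
    crossing_cache: dict | None = None,
) -> list[CombineSpec]:
    """Combination candidates reachable with at most L pivots.

    Pivots are near-crossings (d_artic < eps, local minimum) between
    trajectories in a bounded, most-practiced pivot pool; each bridge
    satisfies the eps eligibility rule by construction.  Results are capped
    and ordered by total bridge distance (closest pivots first).  Among
    equally close pivots, those whose entry time is exit + delta are
    preferred: they keep the stretch parameter at 1, so the donor
    trajectory's content stays phase-aligned after renormalization.
    """
    pool = _pivot_pool(pm, usage, config.pivot_pool_size)
    cache = crossing_cache if crossing_cache is not None else {}

    def crossings(id_a, id_b):
        key = (id_a, id_b)
        if key not in cache:
            hits = find_near_crossings(pm.motor[id_a], pm.motor[id_b], config.eps)
            good = [
                (t1, t2, d)
                for t1, t2, d in hits
                if t1 >= config.min_piece
                and pm.motor[id_b].domain_end - t2 >= config.min_piece
            ]
            good.sort(
                key=lambda h: (round(h[2], 9), abs(h[1] - h[0] - config.delta), h[0], h[1])
            )
            cache[key] = good[: config.hits_per_pair]
        return cache[key]

    # partial chains: (pieces so far, last id, entry time on last id, total d)
    specs: list[tuple[float, CombineSpec]] = []
    chains = [([], a, 0.0, 0.0) for a in pool]
    for _ in range(config.max_pivots):
        next_chains = []
        for pieces, last, entry, dist in chains:
            for b in pool:
                if b == last:
                    continue
                for t1, t2, d in crossings(last, b):
                    if t1 - entry < config.min_piece:
                        continue
                    new_pieces = pieces + [Piece(last, entry, t1)]
                    total = dist + d
                    end_b = pm.motor[b].domain_end
                    n_seams = len(new_pieces)
                    specs.append(
                        (
                            total,
                            CombineSpec(
                                tuple(new_pieces + [Piece(b, t2, end_b)]),
                                deltas=(config.delta,) * n_seams,
                            ),
                        )
                    )
                    next_chains.append((new_pieces, b, t2, total))
        chains = next_chains
        if len(specs) > 4 * config.max_combination_candidates:
            break
    specs.sort(key=lambda s: (s[0], s[1].signature()))
    seen, out = set(), []
    for _, spec in specs:
        sig = spec.signature()
        if sig not in seen:
            seen.add(sig)
            out.append(spec)
        if len(out) >= config.max_combination_candidates:
            break
    return out


def build_candidates(
    pm,
    usage: UsageStats,
    config: MatchConfig,
    crossing_cache: dict | None = None,
    combo_cache: dict | None = None,
) -> list[Candidate]:
    """All existing linked pairs plus eps-eligible combination candidates."""
    cands = [
        Candidate(cid=mid, kind="existing", motor=pm.motor[mid], perceptual=pm.perceptual[pid])
        for mid, pid in pm.pairs
    ]
    cache = combo_cache if combo_cache is not None else {}
    for spec in enumerate_combination_specs(pm, usage, config, crossing_cache):
        sig = spec.signature()
        if sig not in cache:
            try:
                res = combine(spec, pm, eps=config.eps, record=False)
            except ValidationError:
                continue
            cache[sig] = (res.trajectory, pm.forward_map(res.trajectory))
        motor, perc = cache[sig]
        cands.append(
            Candidate(cid=f"combo:{sig}", kind="combination", motor=motor,
                      perceptual=perc, spec=spec)
        )
    return cands


def select(
    exemplar: Exemplar,
    pm,
    state=None,
    usage: UsageStats | None = None,
    bias=None,
    config: MatchConfig | None = None,
    crossing_cache: dict | None = None,
    combo_cache: dict | None = None,
    value_cache: dict | None = None,
) -> SelectionResult:
    """Pick the linked pair that best fulfills the selection criteria.

    ``bias`` is None (first-word mode), a Schema (second attempt) or a
    Silhouette (adult-like mode); when present the fit term (criterion 4 or
    4*) joins the objective.  The additive objective is minimized exactly:
    candidates are scanned in order of their fit-free partial score and the
    scan stops once no remaining candidate can beat the best full objective
    (the fit term is non-negative).  Ties break on candidate id.
    """
    config = config or MatchConfig()
    usage = usage or UsageStats()
    candidates = build_candidates(pm, usage, config, crossing_cache, combo_cache)
    if not candidates:
        raise ValidationError("no candidates available for selection")

    def fit_of(cand):
        if bias is None:
            return None, None
        if isinstance(bias, Silhouette):
            return silhouette_fit(
                cand.motor, bias, config.k, config.fit_span_points, config.fit_quad_points
            )
        return schema_fit(
            cand.motor, bias, config.k, config.fit_span_points, config.fit_quad_points
        )

    # criterion-2 scores; candidate trajectories are immutable, so their
    # relative-time sample matrices are cached across calls
    u = np.linspace(0.0, 1.0, config.n_quad)
    T = exemplar.trajectory.domain_end
    sal = exemplar.salience(T * u)
    cache = value_cache if value_cache is not None else {}
    ekey = ("e", exemplar.trajectory.id, config.n_quad)
    if ekey not in cache:
        cache[ekey] = exemplar.trajectory.at_relative(u)
    evals = cache[ekey]

    scored = []
    for cand in candidates:
        ckey = ("c", cand.cid, config.n_quad)
        if ckey not in cache:
            cache[ckey] = cand.perceptual.at_relative(u)
        c2 = float(np.trapezoid(sal * d_sounds(evals, cache[ckey]), u))
        fav = favoredness(cand.spec if cand.spec is not None else cand.cid, usage)
        scored.append((config.w_perc * c2 - config.w_fav * fav, c2, fav, cand))

    if config.mode == "lexicographic":
        results = []
        for _, c2, fav, cand in scored:
            fit, span = fit_of(cand)
            results.append(
                SelectionResult(cand, c2, c2, fav, fit, span)
            )
        results.sort(
            key=lambda r: (round(r.c2, 10), -r.fav, r.fit if r.fit is not None else 0.0,
                           r.candidate.cid)
        )
        best = results[0]
        best.objective = best.c2
        return best

    scored.sort(key=lambda s: (s[0], s[3].cid))
    best: SelectionResult | None = None
    for partial, c2, fav, cand in scored:
        if best is not None and partial >= best.objective - 1e-12:
            break  # fit >= 0: no remaining candidate can improve
        fit, span = fit_of(cand)
        objective = partial + (config.w_fit * fit if fit is not None else 0.0)
        if best is None or (objective, cand.cid) < (best.objective, best.candidate.cid):
            best = SelectionResult(cand, objective, c2, fav, fit, span)
    return best
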