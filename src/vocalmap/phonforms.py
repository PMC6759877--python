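"""Motor phonological forms: schemas and silhouettes.

A *schema* is the motor trace of a vocalization that successfully
communicated a concept — the same function as the executed trajectory, plus
the concept link.  Repeated successes yield new schemas; these are aligned
and folded into the *silhouette*, the concept's composite motor form: a
function from time to a convex region of motor space.  The silhouette starts
as the singleton-region image of the first schema and grows by the recursion

    SIL_{n+1}(t) = Conv( {schema_{n+1}(t)} ∪ SIL_n(h(t)) ) ∩ ARTIC   on [alpha, beta]
    SIL_{n+1}(t) = { schema_{n+1}(t) }                               elsewhere,

where (alpha, beta) is the optimal alignment of the whole current silhouette
onto a span of the new schema.  Regions are stored as finite generating
vertex sets; hulls in 20 dimensions are never facet-enumerated — only
membership/distance queries are needed, and those are answered exactly by a
small simplex-constrained least-squares solve.  Since the valid box is convex
and all vertices are valid configurations, the ∩ ARTIC step reduces to
clipping vertices to the box.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignment import AlignmentSpan, best_span, h_align
from .spaces import JDIR_IDX, UNIT_BOX_IDX, ValidationError
from .trajectories import MotorTrajectory, normalize_time

__all__ = [
    "Schema",
    "Silhouette",
    "execute_with_noise",
    "make_schema",
    "init_silhouette",
    "align_schema",
    "update_silhouette",
    "region_distance",
    "region_distances",
    "silhouette_widths",
]


# ---------------------------------------------------------------------------
# noisy execution

def execute_with_noise(m: MotorTrajectory, sigma: float, seed: int) -> MotorTrajectory:
    """The trajectory actually executed: m plus smooth implementation noise.

    Immature peripheral motor control perturbs the planned trajectory; the
    perturbation is modeled as a low-frequency random field (three sinusoidal
    modes per coordinate) with per-coordinate RMS amplitude sigma, so the
    executed curve remains continuous.  Bounded coordinates are clipped to
    their valid ranges.  Deterministic given the seed.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return m
    rng = np.random.default_rng(seed)
    T = m.domain_end
    n_modes = 3
    amps = rng.normal(size=(n_modes, m.values.shape[1]))
    amps *= sigma / np.sqrt(np.sum(amps**2, axis=0, keepdims=True) / 2.0).clip(1e-12)
    phases = rng.uniform(0, 2 * np.pi, size=(n_modes, m.values.shape[1]))
    t = m.times[:, None]
    noise = sum(
        amps[f] * np.sin(np.pi * (f + 1) * t / T + phases[f]) for f in range(n_modes)
    )
    vals = m.values + noise
    vals[:, UNIT_BOX_IDX] = np.clip(vals[:, UNIT_BOX_IDX], 0.0, 1.0)
    vals[:, JDIR_IDX] = np.clip(vals[:, JDIR_IDX], -1.0, 1.0)
    return replace(m, values=vals, id="")


# ---------------------------------------------------------------------------
# schemas

@dataclass(frozen=True)
class Schema:
    """A concept-linked motor trace of a successful production."""

    trajectory: MotorTrajectory
    concept: str
    index: int = 1


def make_schema(
    m_executed: MotorTrajectory, concept: str, success: bool, index: int = 1
) -> Schema | None:
    """Create a schema iff the vocalization communicated the concept."""
    if not success:
        return None
    return Schema(trajectory=m_executed, concept=concept, index=index)


# ---------------------------------------------------------------------------
# region geometry

def _prune_duplicates(V: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    _, idx = np.unique(np.round(V / tol).astype(np.int64), axis=0, return_index=True)
    return V[np.sort(idx)]


def _simplex_lsq(V: np.ndarray, x: np.ndarray) -> float:
    """Exact distance from x to the convex hull of rows of V (active set).

    Solves min ||V^T w - x|| over the simplex by an equality-constrained
    active-set iteration (Lawson–Hanson style with the sum-to-one constraint
    folded into the KKT system).
    """
    k = len(V)
    G = V @ V.T
    b = V @ x
    # start at the nearest single vertex
    S = [int(np.argmin(np.sum((V - x) ** 2, axis=1)))]
    w = np.zeros(k)
    w[S[0]] = 1.0
    for _ in range(50 * k + 50):
        # KKT solve on the working set
        m = len(S)
        K = np.zeros((m + 1, m + 1))
        K[:m, :m] = G[np.ix_(S, S)]
        K[:m, m] = 1.0
        K[m, :m] = 1.0
        rhs = np.concatenate([b[S], [1.0]])
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
        wS, lam = sol[:m], sol[m]
        if np.min(wS) < -1e-12:
            # step from current w toward wS until a coordinate hits zero
            cur = w[S]
            dirn = wS - cur
            neg = dirn < -1e-15
            theta = np.min(-cur[neg] / dirn[neg])
            cur = cur + min(theta, 1.0) * dirn
            cur[cur < 1e-14] = 0.0
            w[:] = 0.0
            w[S] = cur
            S = [S[i] for i in range(m) if cur[i] > 0.0]
            if not S:  # numerical corner: restart from best vertex
                S = [int(np.argmin(np.sum((V - x) ** 2, axis=1)))]
                w[:] = 0.0
                w[S[0]] = 1.0
            continue
        w[:] = 0.0
        w[S] = wS
        # KKT check for excluded vertices: reduced gradient must be >= 0
        mu = G @ w - b + lam
        outside = [j for j in range(k) if j not in S]
        if outside:
            j_best = min(outside, key=lambda j: mu[j])
            if mu[j_best] < -1e-10:
                S.append(j_best)
                continue
        break
    return float(np.linalg.norm(V.T @ w - x))


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(a + t * ab - p))


def region_distance(a, region: np.ndarray) -> float:
    """Exact distance from a configuration to the convex hull of the vertices."""
    x = np.asarray(getattr(a, "values", a), dtype=float)
    V = np.atleast_2d(np.asarray(region, dtype=float))
    if len(V) == 0:
        raise ValidationError("empty region")
    V = _prune_duplicates(V)
    if len(V) == 1:
        return float(np.linalg.norm(V[0] - x))
    if len(V) == 2:
        return _point_segment_distance(x, V[0], V[1])
    return _simplex_lsq(V, x)


def _project_simplex(Y: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of Y onto the probability simplex."""
    B, k = Y.shape
    u = -np.sort(-Y, axis=1)
    css = np.cumsum(u, axis=1)
    j = np.arange(1, k + 1)
    rho = np.sum(u + (1.0 - css) / j > 0, axis=1) - 1
    tau = (css[np.arange(B), rho] - 1.0) / (rho + 1)
    return np.maximum(Y - tau[:, None], 0.0)


def _batched_hull_distances(X: np.ndarray, V: np.ndarray, iters: int = 300) -> np.ndarray:
    """Distances from points X (B, d) to hulls of vertex stacks V (B, k, d).

    Accelerated projected gradient on the simplex-constrained least squares;
    the returned value uses the final feasible weights, so it is always an
    upper bound that converges to the exact distance.  Used on the candidate
    search's hot path; the exact active-set solver remains the reference.
    """
    B, k, _ = V.shape
    G = V @ V.transpose(0, 2, 1)
    b = np.einsum("bkd,bd->bk", V, X)
    L = np.maximum(np.abs(G).sum(axis=2).max(axis=1), 1e-12)[:, None]
    w = np.full((B, k), 1.0 / k)
    y = w.copy()
    t_prev = 1.0
    for _ in range(iters):
        grad = np.einsum("bij,bj->bi", G, y) - b
        w_new = _project_simplex(y - grad / L)
        t = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_prev**2))
        y = w_new + ((t_prev - 1.0) / t) * (w_new - w)
        w, t_prev = w_new, t
    res = np.einsum("bkd,bk->bd", V, w) - X
    return np.sqrt(np.sum(res**2, axis=1))


def region_distances(points: np.ndarray, regions: list[np.ndarray]) -> np.ndarray:
    """Distance from each point to its own region, grouped and vectorized.

    Singleton and two-vertex regions use exact closed forms; larger vertex
    sets use the batched accelerated projected-gradient solve.
    """
    points = np.atleast_2d(points)
    out = np.empty(len(points))
    sizes = np.array([len(V) for V in regions])
    for k in np.unique(sizes):
        idx = np.nonzero(sizes == k)[0]
        X = points[idx]
        V = np.stack([regions[i] for i in idx])
        if k == 1:
            out[idx] = np.linalg.norm(V[:, 0, :] - X, axis=1)
        elif k == 2:
            a, bb = V[:, 0, :], V[:, 1, :]
            ab = bb - a
            denom = np.maximum(np.sum(ab**2, axis=1), 1e-300)
            tt = np.clip(np.sum((X - a) * ab, axis=1) / denom, 0.0, 1.0)
            out[idx] = np.linalg.norm(a + tt[:, None] * ab - X, axis=1)
        else:
            out[idx] = _batched_hull_distances(X, V)
    return out


# ---------------------------------------------------------------------------
# silhouettes

@dataclass(frozen=True)
class Silhouette:
    """A concept's composite motor form: per-time convex regions over motor space."""

    concept: str
    n: int
    times: np.ndarray
    regions: tuple  # tuple of (k_i, 20) vertex arrays

    def __post_init__(self):
        if len(self.times) != len(self.regions):
            raise ValidationError("one region per grid time required")
        if any(len(r) == 0 for r in self.regions):
            raise ValidationError("regions must be nonempty")

    @property
    def domain_end(self) -> float:
        return float(self.times[-1])

    def region_at(self, t) -> np.ndarray:
        """Region at the nearest grid time (regions do not interpolate)."""
        return self.regions[self._index_of(t)]

    def _index_of(self, t) -> int:
        step = self.times[1] - self.times[0]
        return int(np.clip(round(float(t) / step), 0, len(self.times) - 1))

    def distance_profile(self, ts, points: np.ndarray) -> np.ndarray:
        """d(point_i, region at time ts_i) for paired arrays of times/points."""
        regs = [self.regions[self._index_of(t)] for t in np.atleast_1d(ts)]
        return region_distances(points, regs)


def init_silhouette(schema: Schema) -> Silhouette:
    """First silhouette: the singleton-region image of the first schema."""
    traj = normalize_time(schema.trajectory)
    return Silhouette(
        concept=schema.concept,
        n=1,
        times=traj.times.copy(),
        regions=tuple(row[None, :].copy() for row in traj.values),
    )


def align_schema(
    sil: Silhouette,
    schema_next: Schema,
    k: float,
    n_span: int = 17,
    n_quad: int = 17,
) -> tuple[AlignmentSpan, float]:
    """Optimal linear alignment of the whole silhouette onto a schema span.

    Minimizes the mean distance from the schema to the nearest point of the
    (time-aligned) silhouette region, over spans [alpha, beta] of the schema
    with beta - alpha >= k.
    """
    traj = normalize_time(schema_next.trajectory)

    def pointwise(ts, hs):
        return sil.distance_profile(hs, traj.evaluate(ts))

    value, span = best_span(traj.domain_end, sil.domain_end, k, pointwise, n_span, n_quad)
    return span, value


def update_silhouette(sil: Silhouette, schema_next: Schema, span: AlignmentSpan) -> Silhouette:
    """Fold a new schema into the silhouette along the chosen alignment span.

    On [alpha, beta] the region becomes the hull of the old region's vertices
    plus the schema's point (old regions never shrink); outside the span the
    schema alone defines the region.  Vertices are clipped to the valid box,
    which realizes the intersection with the set of possible configurations.
    """
    traj = normalize_time(schema_next.trajectory)
    regions = []
    for t, point in zip(traj.times, traj.values):
        if span.alpha - 1e-9 <= t <= span.beta + 1e-9:
            h = h_align(t, span.alpha, span.beta, sil.domain_end)
            old = sil.region_at(h)
            verts = np.vstack([old, point[None, :]])
            verts[:, UNIT_BOX_IDX] = np.clip(verts[:, UNIT_BOX_IDX], 0.0, 1.0)
            verts[:, JDIR_IDX] = np.clip(verts[:, JDIR_IDX], -1.0, 1.0)
            regions.append(_prune_duplicates(verts))
        else:
            regions.append(point[None, :].copy())
    return Silhouette(
        concept=sil.concept, n=sil.n + 1, times=traj.times.copy(), regions=tuple(regions)
    )


def silhouette_widths(sil: Silhouette) -> np.ndarray:
    """Mean (over time) per-coordinate vertex spread — the swath width readout.

    Zero width in a coordinate means every schema agreed on that coordinate at
    every time (the swath is narrow where production is consistent).
    """
    spread = np.array([V.max(axis=0) - V.min(axis=0) for V in sil.regions])
    return spread.mean(axis=0)
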