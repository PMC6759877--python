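"""Linear time-alignment spans used by the schema and silhouette criteria.

A candidate trajectory with domain [0, s1] is compared to a target form
(a schema or a silhouette) with domain [0, s'] by choosing a span [alpha,
beta] of the candidate, with beta - alpha >= k, and mapping the *whole*
target linearly onto that span via

    h(t) = s' (t - alpha) / (beta - alpha),

then averaging a pointwise distance over the span.  Only linear stretching is
allowed so the target's internal relative timing is preserved; the span floor
k prevents compressing the target onto an arbitrarily short slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spaces import ValidationError

__all__ = ["AlignmentSpan", "h_align", "best_span"]


@dataclass(frozen=True)
class AlignmentSpan:
    """A chosen comparison span: 0 <= alpha <= beta - k <= domain - k."""

    alpha: float
    beta: float
    k: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= self.beta - self.k + 1e-12):
            raise ValidationError("span must satisfy 0 <= alpha <= beta - k")


def h_align(t, alpha: float, beta: float, target_end: float):
    """Map span times [alpha, beta] linearly onto the target domain [0, s']."""
    return target_end * (np.asarray(t, dtype=float) - alpha) / (beta - alpha)


def best_span(
    source_end: float,
    target_end: float,
    k: float,
    pointwise,
    n_span: int = 17,
    n_quad: int = 17,
) -> tuple[float, AlignmentSpan]:
    """Exhaustive grid search for the span minimizing the mean aligned distance.

    ``pointwise(ts, hs)`` must return the distances between the candidate at
    span times ``ts`` and the target at mapped times ``hs``.  The mean is the
    normalized integral (1/(beta-alpha)) * integral over [alpha, beta].  Ties
    (within 1e-10) are broken toward the widest span, then the smallest alpha.
    """
    if k <= 0 or k > source_end + 1e-12:
        raise ValidationError(f"infeasible minimum span k={k} for domain [0, {source_end}]")
    grid = np.linspace(0.0, source_end, max(2, n_span))
    spans = [
        (alpha, beta)
        for ia, alpha in enumerate(grid)
        for beta in grid[ia + 1 :]
        if beta - alpha >= k - 1e-12
    ]
    if not spans:
        raise ValidationError("no feasible span of length >= k")
    # one batched distance call for all spans (the integrand may be expensive)
    ts = np.stack([np.linspace(a, b, n_quad) for a, b in spans])
    hs = np.stack([h_align(row, a, b, target_end) for row, (a, b) in zip(ts, spans)])
    d = np.asarray(pointwise(ts.ravel(), hs.ravel())).reshape(ts.shape)
    best = None
    for row, drow, (alpha, beta) in zip(ts, d, spans):
        val = float(np.trapezoid(drow, row)) / (beta - alpha)
        key = (round(val, 10), -(beta - alpha), alpha)
        if best is None or key < best[0]:
            best = (key, val, AlignmentSpan(float(alpha), float(beta), float(k)))
    return best[1], best[2]
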