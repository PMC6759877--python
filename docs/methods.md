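# Methods

`vocalmap` implements a formal model of speech production in which word forms
are represented holistically — as whole trajectories through perceptual and
motor spaces — and discrete-seeming perceptual-motor units *emerge* from the
geometry of motor space over developmental time, rather than being postulated
as phonological primitives.  This note documents the model as implemented,
the numerical choices, what the synthetic data does and does not emulate, and
the design decisions taken where the formal model leaves matters open.

## Spaces and distances

An **articulatory configuration** is a 20-tuple: glottal width `g`, eight
normalized cross-sectional tract areas `c1..c8`, velum height `v` (all in
[0, 1]), their nine time derivatives (unbounded), and the signed jaw-cycle
coordinate `jdir` in [−1, 1] (positive while opening, negative while closing,
magnitude ~ force).  An **instantaneous sound** is a 12-tuple: the loudness
derivative, a binary periodicity flag, three Bark-scale formants `Z1..Z3`,
spectral center of gravity and peak width, and the time derivatives of the
five spectral quantities.  Periodicity imposes zeroing rules: aperiodic
sounds carry no formants (and no formant derivatives); periodic sounds carry
no noise-spectrum fields.  Constructors enforce these rules; they are
invariants, not conventions.

Motor distance `d_artic` is plain Euclidean distance over all 20
coordinates.  Perceptual distance `d_sounds` is Euclidean over an
11-component difference vector: the nine non-formant coordinates plus the
differences of `Z3 − Z1` and `Z3 − Z2`.  Because the formants enter only
through these two relative values, the distance is blind to a uniform
translation of all three formants — a built-in normalization for vocal-tract
size across speakers.  The model constrains only *which* differences the
perceptual distance may use; the unweighted Euclidean combination is this
package's choice (component weights are exposed for callers who want
otherwise).  All units are abstract/normalized: the model's claims rest on
the topology the distances induce, not on psychoacoustic calibration, so no
Bark/phon conversions are performed.

## Trajectories, time normalization, and trajectory metrics

Trajectories are sampled functions on uniform grids (default 64–80 samples
per syllable).  Motor trajectories are continuous and evaluated by linear
interpolation; a testable surrogate for continuity is the Lipschitz bound
max adjacent-sample `d_artic` ≤ κ·Δt with κ = 200 by default — generous
enough for sharp consonantal closures, whose *derivative* coordinates change
fastest.  Perceptual trajectories may be discontinuous (stop closures,
periodicity switches) and are evaluated by nearest sample.

Two motor trajectories are equivalent when one is a uniform temporal stretch
of the other.  Syllable count is read off `jdir`: a syllable is a maximal
opening run followed (after optional neutral spans) by a closing run, with a
hysteresis band of 0.05 to ignore numerical chatter.  The canonical
representative of an equivalence class is the uniform stretch with domain
[0, s], s the syllable count.  The trajectory pseudometrics are

- motor:      ∫₀¹ d_artic(m(s·t), m′(s′·t)) dt
- perceptual: ∫₀¹ d_sounds(p(T·t), p′(T′·t)) dt

computed by trapezoidal quadrature on a shared relative-time grid (default
513 points; halving the step changes smooth-fixture distances by < 1e−4).
Both vanish exactly on uniform-stretch pairs, hence induce true metrics on
equivalence classes.  Nonlinear time warping is deliberately out of scope:
uniform stretch is the model's equivalence.

## The perceptual-motor map and the forward surrogate

Every vocalization leaves a motor trace and an auditory trace linked at each
point in time; the map is the resulting bijection between trajectory tokens
(duplicated content still yields fresh tokens).  Exemplars — perceptual word
forms acquired from the ambient language — live in the same perceptual space
but have no motor partner and stay outside the bijection.

The model is agnostic about how articulation produces sound, so the
articulatory-to-acoustic step is a fixed, deterministic, continuous
surrogate: periodicity iff `g` < 0.5; formants affine in (`c4`,`c5`,`c6`,`v`)
when periodic; center of gravity and width affine in (`c7`,`c8`,`g`) when
aperiodic; loudness derivative proportional to `jdir`; spectral derivatives
by finite differences along the trajectory before the zeroing rules.  Any
fixed continuous map supports the model's claims; affine keeps independent
oracles trivial.  Coefficients are configurable.  A consequence worth
knowing: with the default coefficients, a closure at `c7`/`c8` is acoustically
silent while voicing persists — an extreme, but not absurd, neutralization.

## Junctures, clusters, chunks, and combination

A combination concatenates pieces of existing trajectories with short linear
bridges: on a bridge window [t₁, t₂] the value is (1−λ(t))a₁ + λ(t)a₂ with λ
affine, λ(t₁)=0, λ(t₂)=1 (for the window [0.6, 0.7] this is λ(t)=10t−6).
A bridge is only admissible when its endpoint configurations are within ε
(default 0.15 in `d_artic` units; the formal model gives no value).  The raw
concatenation is stretched by u = s / raw-duration so the result occupies
[0, s]; s is *recomputed* from the assembled jaw cycle, never assumed.  The
sampled result uses a uniform grid whose step divides the seam times when
those are small-denominator rationals (via `fractions.Fraction`), so seam
identities like m(0.6)=a₁ hold exactly; otherwise a plain uniform grid at
the sources' resolution is used and seams hold to interpolation tolerance.

Bridge endpoints become **junctures**.  Junctures cluster by single linkage
at threshold ε — two junctures share a cluster iff chained by pairwise
distances < ε — maintained incrementally by union-find; insertion order is
irrelevant (the partition always equals the ε-graph's connected components,
which equals the single-linkage dendrogram cut just below ε).  Note that an
incoming juncture can *merge* existing clusters, so the cluster count is not
monotone even though the juncture set only grows.  Junctures partition their
host trajectories into **articulatory chunks**; clusters plus their linked
perceptual points are the emergent perceptual-motor units, usable as pivots.

Candidate pivots are found by `find_near_crossings`: grid pairs (t₁, t₂)
where the inter-trajectory distance is below ε *and* a local minimum over
its grid neighborhood — the minimum filter prevents a continuum of junctures
along shared valleys.  Junctures are created only by *executed* combinations;
near-crossing search is the combiner's candidate search.

## Matching and selection

Attempting a word means finding a linked pair (m, p) that best fulfills:

1. **Achievability** — m is stored, or an ε-admissible combination of stored
   pieces (at most L = 2 bridges; pieces at least 0.25 syllables).
2. **Salience-weighted perceptual closeness** —
   ∫₀¹ salience(T·t) · d_sounds(e(T·t), p(s·t)) dt, endpoints aligned.  With
   salience ≡ 1 this is exactly the perceptual trajectory pseudometric.
3. **Favoredness** — log(1 + count), where the count is the trajectory's
   traversal count, or for a combination the *minimum* co-traversal count
   over its seams (a chain is as practiced as its weakest join).  The model
   requires only monotonicity; the log form and min-aggregation are this
   package's choice.
4. / 4*. **Motor-form fit** — once a schema (single successful trace) or
   silhouette (region composite) exists for the concept, the candidate must
   contain a span [α, β], β − α ≥ k (default 0.5 syllables), onto which the
   whole motor form maps linearly with small mean distance; for silhouettes
   the integrand is the distance to the *region* at the aligned time.  The
   span search is exhaustive on a grid.

"Best fulfill" is deliberately unspecified in the formal model; the default
here is the additive objective w_perc·(2) − w_fav·(3) + w_fit·(4), with
weights (1, 0.2, 1), and a lexicographic mode as an alternative.  Since the
fit term is non-negative, the argmin is found exactly while evaluating the
expensive fit only where it could matter: candidates are scanned in order of
their fit-free partial score and the scan stops when no remaining candidate
can beat the best full objective.  Among equally close pivots the search
prefers duration-preserving ones (entry = exit + bridge duration, hence
u = 1), which keep the donor trajectory's content phase-aligned — the same
choice the worked example's parameters embody.  Thresholds θ₂, θ₄ gate the
*success* model only, never the argmin.

## Schemas and silhouettes

Executed trajectories are the selected ones plus smooth implementation noise
(three random sinusoidal modes per coordinate, RMS amplitude σ, clipped to
valid ranges) — a stand-in for immature peripheral control that also explores
motor space around the plan.  Success (weighted perceptual distance to the
exemplar < θ_succ, default 0.5 — the model never operationalizes
"successful communication") turns the executed trace into a schema.  The
first schema initializes the silhouette with singleton regions; each later
schema is aligned (whole silhouette onto the *optimal* schema span, ties to
the widest span then smallest α) and folded in:

    SIL_{n+1}(t) = Conv({schema_{n+1}(t)} ∪ SIL_n(h(t))) ∩ ARTIC  on [α, β],
                   {schema_{n+1}(t)}                              elsewhere.

Regions are stored as generating vertex sets; 20-dimensional hulls are never
facet-enumerated because only membership/distance queries are needed.  The
distance from a point to a region is the simplex-constrained least-squares
minimum ‖Vᵀw − x‖ over w ≥ 0, Σw = 1, solved exactly by an active-set
iteration (`region_distance`); the hot search path uses a batched accelerated
projected-gradient solve accurate to ~1e−5, with exact closed forms for one-
and two-vertex regions.  Since all vertices are valid configurations and the
valid box is convex, the ∩ ARTIC step reduces to clipping vertices to the
box.  Aligned regions only ever grow (old vertices remain generators), which
yields the monotone-growth property: swaths are narrow in coordinates that
production holds constant and wide where it varies.

## Synthetic data: what it emulates, what it does not

The babble generator produces consonant-vowel alternations: `jdir` runs
through the requested number of open-close cycles (amplitude 0.9, vowel
center mid-syllable); all babbles share a vowel posture (per-babble jitter
σ = 0.02) — the "shared vowel target" condition under which near-crossings,
and hence units, can arise; one constriction site per syllable (from three
sites: c4, c6, c8-like) dips to near closure in a cos² window of half-width
0.15 syllables around the syllable onset.  Babbles are strongly reduplicated
(repetition bias 0.9), while the hidden adult forms behind exemplars are
mostly variegated (bias 0.2): canonical babbling repeats, adult words do not,
and it is exactly this asymmetry that makes piecewise combination necessary
rather than incidental.  Exemplars are hidden adult motor trajectories pushed
through the forward map, their motor side discarded; initial salience is the
step function (first syllable fully salient), and after each attempt salience
shifts toward poorly matched spans (new = 0.9·old + 0.1·residual/max,
rescaled to maximum 1; a perfect match changes nothing).

The acquisition loop records 20 babbles, then iterates (default 200 times):
sample a concept and exemplar, select under the concept's silhouette bias if
one exists, execute with noise σ = 0.04·0.995^iteration (slowly maturing
control), record the vocalization as a new linked pair, test success, update
schema/silhouette, register junctures for executed combinations, update
salience.  Runs are bit-reproducible from (config, seed); all randomness
flows from one root seed through named substreams.

What passing these simulations does **not** show about real speech: the
spaces are low-dimensional abstractions with a made-up forward map; noise is
stationary smooth sinusoids, not motor noise; exemplars come from the same
generator family as babbles, so the infant's target distribution is
unrealistically reachable; there is no auditory segmentation, no lexical
competition, no real acoustics.  The simulations demonstrate the *mechanism*
— that units and improvement emerge from trajectory geometry plus matching —
not developmental timelines or phonetic detail.

One measurement subtlety: the *selected* candidate's weighted distance is not
comparable across iterations, because the evolving salience integrates
mismatch over a growing portion of the exemplar (attention spreads from the
stressed syllable outward — the model's own account of "ba" → "baba").  The
improvement statistic therefore uses the executed attempt's criterion-2
value; the unweighted metric-(ii) error is recorded alongside and shows the
same decline.

## Numerical choices and degenerate inputs

- Quadrature: trapezoid on relative-time grids; 513 points for metrics, 161
  for the simulation's matching scores (grid-aligned with 80-sample
  syllables); span searches use 5–17-point α/β grids.
- Equivalence tolerance 1e−3 (`d_artic` units); juncture ε = 0.15; bridge
  duration δ = 0.1 normalized time.
- Zero-syllable trajectories have no canonical representative: normalization
  and recording raise; the simulation skips an iteration if noise destroys
  the jaw cycle (not observed at default σ).
- Ties: span search breaks ties (1e−10) toward the widest span then smallest
  α; selection breaks objective ties by candidate id; combination candidate
  enumeration orders by bridge distance, then timing skew, then times.
- Degenerate regions (duplicate vertices) are pruned at 1e−9 resolution; the
  active-set solver falls back to least squares on singular KKT systems.

## Known limitations

- Multi-piece combination folds bridges pairwise on a shared raw timeline;
  no globally optimal re-timing is attempted.
- The pivot pool for combination candidates is bounded (default 20 most
  practiced trajectories) and near-crossings are cached per ordered pair;
  with very large maps the search is heuristic, though always ε-sound.
- Silhouette regions grow one vertex per success; in 20 dimensions nearly
  all vertices are extreme, so very long runs make region queries costlier
  (the batched solver keeps this manageable at the default scale).
- Salience evolution is one concrete instantiation of the attention
  narrative (residual-proportional with decay 0.9) and is replaceable.
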