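# vocalmap

Simulation of how discrete perceptual-motor units of speech can *emerge* from
holistic word representations.  The package is for researchers in speech
motor control and language acquisition who want a runnable formalization of
the whole-word production hypothesis: word forms are stored and retrieved as
entire trajectories — perceptual **exemplars** and motor **silhouettes** —
linked through a **perceptual-motor map**, and the syllable- and
segment-sized units that adult speech seems built from arise as a byproduct
of trajectory geometry, not as phonological primitives.

## The model in brief

- Motor space `ARTIC` is the set of articulatory configurations
  `(g, c1..c8, v, dc1..dc8, dv, j_dir)` — glottal width, eight tract areas,
  velum height, their derivatives, and the signed jaw-cycle coordinate — with
  the Euclidean metric `d_ARTIC`.  Perceptual space `SOUNDS` holds 12-tuples
  of acoustic descriptors; its distance `d_SOUNDS` uses the non-formant
  coordinates plus the speaker-normalizing differences `Z3−Z1` and `Z3−Z2`.
- Trajectories `m: [0, s] → ARTIC`, `p: [0, T] → SOUNDS` code relative time;
  uniform stretches are equivalent, and the class representative has domain
  `[0, s]` with `s` the jaw-cycle (syllable) count.  Trajectory distances are
  the normalized-time integrals ∫₀¹ d(m(s·t), m′(s′·t)) dt — pseudometrics
  that become metrics on equivalence classes.
- Babbling initializes the map: every vocalization records a motor trace
  linked pointwise in time to its auditory trace (a bijection on tokens).
- Novel productions **combine** pieces of stored trajectories through short
  linear bridges `(1−λ(t))a₁ + λ(t)a₂` wherever two trajectories pass within
  ε of each other in motor space; the result is uniformly stretched by
  `u = s / raw duration` onto its canonical domain.  Bridge endpoints become
  **junctures**; single-linkage clusters of junctures (cut just below ε),
  with their linked perceptual points, are the emergent perceptual-motor
  units, and the juncture-delimited sub-paths are articulatory **chunks**.
- Word attempts pick the linked pair minimizing a weighted combination of
  the salience-weighted perceptual distance to the exemplar
  ∫₀¹ salience(T·t)·d_SOUNDS(e(T·t), p(s·t)) dt, a practice (favoredness)
  bonus, and — once the concept has a motor form — an alignment criterion
  that maps the whole schema/silhouette linearly onto a span `[α, β]`
  (β − α ≥ k) of the candidate.  Successful attempts become schemas; aligned
  schemas accumulate into the silhouette, a time-varying convex region
  `SIL_c(t) = Conv(schemas) ∩ ARTIC` that narrows where production is
  consistent and widens where it varies.

See `docs/methods.md` for the full account, all defaults, and limitations.

## Worked example: [bɑbɑ] + [dɑdɑ] → [bɑdɑ]

Two reduplicated two-syllable babbles whose mid-first-vowel configurations
nearly coincide in motor space are combined by exiting the first at relative
time 0.6 and entering the second at 0.7 across a 0.1-long bridge:

```python
import numpy as np
from vocalmap import PerceptualMotorMap, CombineSpec, ClusterState, combine, d_artic
from vocalmap.devsim import SimConfig, _babble

pm = PerceptualMotorMap()
baba = _babble(np.random.default_rng(3),
               SimConfig(seed=1, vowel_center=0.6, repetition_bias=1.0), syllables=2)
dada = _babble(np.random.default_rng(4),
               SimConfig(seed=1, vowel_center=0.7, repetition_bias=1.0), syllables=2)
(bid, _), (did, _) = pm.record_vocalization(baba), pm.record_vocalization(dada)

a1, a2 = pm.motor[bid].evaluate(0.6), pm.motor[did].evaluate(0.7)
print(f"pivot distance d_artic(a1, a2) = {d_artic(a1, a2):.6f}")

state = ClusterState(eps=0.15)
res = combine(CombineSpec.two_piece(bid, 0.6, did, 0.7, end2=2.0, delta=0.1),
              pm, state, eps=0.15)
print(f"raw duration = {res.raw_duration:.1f}, stretch u = {res.u:.1f}, syllables = {res.s}")
print(f"result domain = [0, {res.trajectory.domain_end:.0f}], "
      f"junctures = {len(state)}, clusters = {state.n_clusters}")
```

prints

```
pivot distance d_artic(a1, a2) = 0.088383
raw duration = 2.0, stretch u = 1.0, syllables = 2
result domain = [0, 2], junctures = 2, clusters = 1
```

The pivot configurations are 0.088 apart — inside the ε = 0.15 admissibility
threshold, so the combination is achievable.  The assembled curve spans raw
time 0.6 + 0.1 + 1.3 = 2.0 and its jaw cycle counts two syllables, so the
stretch parameter is u = 1 and the new trajectory occupies [0, 2].  On the
bridge window the interpolant is λ(t) = 10t − 6.  Both bridge endpoints
become junctures, and since they are within ε of each other they form a
single cluster — the first emergent perceptual-motor unit.

## Developmental simulation

```bash
cat > cfg.yaml <<EOF
seed: 1
iterations: 200
EOF
vocalmap simulate --config cfg.yaml --out rundir/
vocalmap report --run rundir/
```

`simulate` prints the median matching error of the executed attempts over
the first and last iteration quartiles (for seed 1: 0.445 → 0.259) and writes
a per-iteration JSONL history (selection scores, success flags, juncture and
cluster counts, silhouette widths); `report` plots cluster count and matching
error against iteration.  Other subcommands: `babble` (generate and store a
babble repertoire), `combine` (run one combination from a JSON spec),
`cluster` (cluster report), `attempt` (a single matching-and-selection step).

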