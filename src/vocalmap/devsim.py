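"""Synthetic vocal data and the developmental acquisition loop.

The generator produces babble-like motor trajectories: repetitive
consonant-vowel alternations in which the jaw coordinate oscillates through
the requested number of open-close cycles, a per-syllable constriction is
superimposed on a shared vowel posture, and reduplication is controlled by a
repetition bias.  Exemplars are produced from *hidden* adult motor
trajectories passed through the forward map; the motor side is discarded, so
exemplars are unlinked perceptual forms, exactly as acquired word targets.

``simulate_acquisition`` runs the whole developmental story at desk scale:
babbling initializes the perceptual-motor map; each iteration attempts one
concept by matching and selection (biased by the concept's silhouette once it
exists), executes the choice with slowly decaying motor noise, records the
vocalization, forms a schema on communicative success, folds it into the
silhouette, updates juncture clusters when a combination was used, and shifts
the exemplar's salience toward poorly matched spans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .junctures import ClusterState, chunks_of
from .matching import (
    Exemplar,
    MatchConfig,
    SalienceFn,
    UsageStats,
    select,
    weighted_perceptual_distance,
)
from .phonforms import (
    align_schema,
    execute_with_noise,
    init_silhouette,
    make_schema,
    silhouette_widths,
    update_silhouette,
)
from .pm_map import ForwardMap, PerceptualMotorMap
from .combination import combine
from .spaces import ValidationError, d_sounds
from .trajectories import MotorTrajectory, normalize_time, traj_distance_perceptual

__all__ = [
    "SimConfig",
    "History",
    "babble_generator",
    "exemplar_generator",
    "update_salience",
    "simulate_acquisition",
]

#: constriction sites available to the babble generator (1-based c indices):
#: lips-like (c8), tongue-tip-like (c6), tongue-body-like (c4)
CONSONANT_SITES = (8, 6, 4)

#: a mid-open, back-vowel-like tract posture (c1 glottal end .. c8 lips)
VOWEL_TARGET = (0.45, 0.5, 0.6, 0.7, 0.8, 0.85, 0.85, 0.8)


class SimConfig(BaseModel):
    """Conditions of a developmental run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    n_babbles: int = 20
    syllable_min: int = 2
    syllable_max: int = 2
    n_concepts: int = 5
    exemplars_per_concept: int = 2
    iterations: int = 200
    #: babbling is canonically reduplicative; adult word forms are mostly
    #: variegated — it is this asymmetry that makes combination necessary
    repetition_bias: float = 0.9
    exemplar_repetition_bias: float = 0.2
    vowel_jitter: float = 0.02
    jaw_amplitude: float = 0.9
    vowel_center: float = 0.5
    consonant_depth: float = 0.95
    closure_halfwidth: float = 0.15
    samples_per_syllable: int = 80
    sigma0: float = 0.04
    sigma_decay: float = 0.995
    theta_succ: float = 0.5
    salience_decay: float = 0.9
    initial_salience: str = "step"  # "step" or "uniform"
    eps: float = 0.15
    k: float = 0.5
    w_perc: float = 1.0
    w_fav: float = 0.2
    w_fit: float = 1.0
    n_quad: int = 161
    fit_span_points: int = 5
    fit_quad_points: int = 7
    pivot_pool_size: int = 20
    hits_per_pair: int = 1
    max_combination_candidates: int = 400
    bridge_delta: float = 0.1

    def match_config(self) -> MatchConfig:
        return MatchConfig(
            w_perc=self.w_perc,
            w_fav=self.w_fav,
            w_fit=self.w_fit,
            theta_2=self.theta_succ,
            k=self.k,
            n_quad=self.n_quad,
            fit_span_points=self.fit_span_points,
            fit_quad_points=self.fit_quad_points,
            max_combination_candidates=self.max_combination_candidates,
            pivot_pool_size=self.pivot_pool_size,
            hits_per_pair=self.hits_per_pair,
            eps=self.eps,
            delta=self.bridge_delta,
        )


@dataclass
class History:
    """Append-only per-iteration records of a simulation, plus its config."""

    config: dict
    records: list = field(default_factory=list)
    #: final simulation state (map, cluster state, usage, silhouettes) for
    #: post-hoc inspection; not part of the serialized history
    final: dict | None = None

    def append(self, **row):
        self.records.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r, sort_keys=True) for r in self.records)

    def matching_error_quartile_medians(self) -> tuple[float, float]:
        """Median criterion-2 value of the executed attempts, first vs last quartile.

        The executed attempt's salience-weighted distance to the exemplar is
        the stationary readout of matching skill.  (The *selected* candidate's
        value is not comparable across iterations: as attention spreads from
        the initially salient syllable to the rest of the word, the weighted
        distance integrates mismatch over a growing portion of the exemplar.)
        """
        c2 = [r["executed_error"] for r in self.records if "executed_error" in r]
        q = max(1, len(c2) // 4)
        return float(np.median(c2[:q])), float(np.median(c2[-q:]))


# ---------------------------------------------------------------------------
# generators

def _babble(
    rng: np.random.Generator,
    cfg: SimConfig,
    syllables: int | None = None,
    repetition_bias: float | None = None,
) -> MotorTrajectory:
    rep = cfg.repetition_bias if repetition_bias is None else repetition_bias
    s = int(syllables or rng.integers(cfg.syllable_min, cfg.syllable_max + 1))
    n = cfg.samples_per_syllable * s + 1
    t = np.linspace(0.0, float(s), n)
    vowel = np.asarray(VOWEL_TARGET) + rng.normal(0.0, cfg.vowel_jitter, size=8)
    vowel = np.clip(vowel, 0.05, 0.95)
    # consonant site per syllable, with reduplication bias toward the first
    sites = [CONSONANT_SITES[rng.integers(len(CONSONANT_SITES))]]
    for _ in range(s - 1):
        if rng.random() < rep:
            sites.append(sites[0])
        else:
            sites.append(CONSONANT_SITES[rng.integers(len(CONSONANT_SITES))])

    c = np.tile(vowel, (n, 1))
    for j, site in enumerate(sites):
        x = (t - j) / cfg.closure_halfwidth
        bump = np.where(np.abs(x) <= 1.0, np.cos(np.pi * x / 2.0) ** 2, 0.0)
        c[:, site - 1] *= 1.0 - cfg.consonant_depth * bump

    jdir = -cfg.jaw_amplitude * np.sin(2.0 * np.pi * (t - cfg.vowel_center))
    g = np.full(n, 0.25)  # narrow glottis: voiced throughout
    v = np.full(n, 1.0)  # velum raised: oral
    dc = np.gradient(c, t, axis=0)
    dv = np.gradient(v, t)
    values = np.column_stack([g, c, v, dc, dv, jdir])
    return MotorTrajectory(times=t, values=values)


def babble_generator(cfg: SimConfig, seed: int | None = None) -> list[MotorTrajectory]:
    """Generate ``n_babbles`` reduplicated CV babble trajectories."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return [_babble(rng, cfg) for _ in range(cfg.n_babbles)]


def exemplar_generator(
    cfg: SimConfig, seed: int | None = None, forward_map: ForwardMap | None = None
) -> dict[str, list[Exemplar]]:
    """Adult word targets: hidden motor forms -> forward map -> unlinked exemplars."""
    rng = np.random.default_rng((cfg.seed + 1) if seed is None else seed)
    fm = forward_map or ForwardMap()
    out: dict[str, list[Exemplar]] = {}
    for ci in range(cfg.n_concepts):
        concept = f"concept-{ci}"
        out[concept] = []
        for ei in range(cfg.exemplars_per_concept):
            hidden = normalize_time(
                _babble(rng, cfg, repetition_bias=cfg.exemplar_repetition_bias)
            )
            p = fm(hidden)
            p = replace(p, id=f"ex-{ci}-{ei}", syllables=None)
            T = p.domain_end
            sal = (
                SalienceFn.step(T)
                if cfg.initial_salience == "step"
                else SalienceFn.constant(1.0, T)
            )
            out[concept].append(Exemplar(trajectory=p, concept=concept, salience=sal))
    return out


# ---------------------------------------------------------------------------
# salience evolution

def update_salience(
    salience: SalienceFn,
    residual_times: np.ndarray,
    residual: np.ndarray,
    decay: float = 0.9,
    n_grid: int = 129,
    tol: float = 1e-12,
) -> SalienceFn:
    """Shift salience mass toward poorly matched spans of the exemplar.

    The residual profile is the pointwise perceptual distance from the last
    attempt.  New salience = decay * old + (1 - decay) * residual / max
    residual, rescaled to maximum 1 — so attention drifts toward what still
    mismatches while well-matched spans decay relatively.  A perfect match
    leaves salience unchanged.
    """
    if np.max(residual) <= tol:
        return salience
    t = np.linspace(0.0, salience.domain_end, n_grid)
    old = salience(t)
    res = np.interp(t, residual_times, residual)
    raw = decay * old + (1.0 - decay) * res / np.max(res)
    raw = raw / max(np.max(raw), tol)
    return SalienceFn.from_samples(t, raw)


# ---------------------------------------------------------------------------
# the acquisition loop

def simulate_acquisition(cfg: SimConfig) -> History:
    """Run the developmental loop; bit-reproducible for a given config."""
    root = np.random.SeedSequence(cfg.seed)
    s_babble, s_exemplar, s_loop, s_noise = root.spawn(4)
    rng = np.random.default_rng(s_loop)
    noise_seeds = np.random.default_rng(s_noise).integers(0, 2**31 - 1, size=cfg.iterations)

    pm = PerceptualMotorMap()
    usage = UsageStats()
    state = ClusterState(eps=cfg.eps)
    for b in babble_generator(cfg, seed=np.random.default_rng(s_babble).integers(2**31)):
        mid, _ = pm.record_vocalization(b)
        usage.record_traversal(mid)

    exemplars = exemplar_generator(
        cfg, seed=np.random.default_rng(s_exemplar).integers(2**31), forward_map=pm.forward_map
    )
    concepts = sorted(exemplars)
    match_cfg = cfg.match_config()
    silhouettes: dict[str, object] = {}
    success_counts: dict[str, int] = {c: 0 for c in concepts}
    crossing_cache: dict = {}
    combo_cache: dict = {}
    value_cache: dict = {}
    history = History(config=cfg.model_dump())

    for it in range(cfg.iterations):
        concept = concepts[int(rng.integers(len(concepts)))]
        ex_idx = int(rng.integers(len(exemplars[concept])))
        exemplar = exemplars[concept][ex_idx]
        bias = silhouettes.get(concept)

        sel = select(
            exemplar, pm, state, usage, bias, match_cfg,
            crossing_cache=crossing_cache, combo_cache=combo_cache,
            value_cache=value_cache,
        )
        cand = sel.candidate
        if cand.kind == "combination":
            res = combine(cand.spec, pm, state, eps=cfg.eps, record=True)
            usage.record_combination(cand.spec)
            base = res.trajectory
            usage.record_traversal(base.id)
        else:
            base = cand.motor
            usage.record_traversal(cand.cid)

        sigma = cfg.sigma0 * cfg.sigma_decay**it
        executed = execute_with_noise(base, sigma, int(noise_seeds[it]))
        try:
            mid, pid = pm.record_vocalization(executed)
        except ValidationError:  # noise destroyed the jaw cycle; rare, skip
            history.append(iteration=it, concept=concept, skipped=True)
            continue
        usage.record_traversal(mid)
        p_exec = pm.perceptual[pid]

        err = weighted_perceptual_distance(exemplar, p_exec, cfg.n_quad)
        plain_err = traj_distance_perceptual(exemplar.trajectory, p_exec, cfg.n_quad)
        success = err < cfg.theta_succ
        sil_width = float("nan")
        if success:
            success_counts[concept] += 1
            schema = make_schema(pm.motor[mid], concept, True, index=success_counts[concept])
            if concept not in silhouettes:
                silhouettes[concept] = init_silhouette(schema)
            else:
                span, _ = align_schema(
                    silhouettes[concept], schema, cfg.k,
                    n_span=cfg.fit_span_points, n_quad=cfg.fit_quad_points,
                )
                silhouettes[concept] = update_silhouette(silhouettes[concept], schema, span)
            sil_width = float(np.mean(silhouette_widths(silhouettes[concept])))

        # attention shifts toward what still mismatches
        u = np.linspace(0.0, 1.0, cfg.n_quad)
        T = exemplar.trajectory.domain_end
        res_profile = d_sounds(
            exemplar.trajectory.at_relative(u), p_exec.at_relative(u)
        )
        new_sal = update_salience(exemplar.salience, T * u, res_profile, cfg.salience_decay)
        exemplars[concept][ex_idx] = replace(exemplar, salience=new_sal)

        history.append(
            iteration=it,
            concept=concept,
            candidate_kind=cand.kind,
            candidate_id=cand.cid,
            c2_selected=sel.c2,
            favoredness=sel.fav,
            fit=sel.fit,
            executed_error=err,
            plain_error=plain_err,
            success=bool(success),
            sigma=sigma,
            n_junctures=len(state),
            n_clusters=state.n_clusters,
            n_pairs=len(pm),
            silhouette_mean_width=sil_width,
        )

    history.final = {
        "pm": pm,
        "state": state,
        "usage": usage,
        "silhouettes": silhouettes,
    }
    return history


def subword_chunks(pm: PerceptualMotorMap, state: ClusterState) -> list:
    """Chunks of syllable size or smaller induced by the current junctures."""
    out = []
    for mid, traj in pm.motor.items():
        if state.junctures_on(mid):
            out.extend(ch for ch in chunks_of(traj, state) if ch.duration <= 1.0 + 1e-9)
    return out
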