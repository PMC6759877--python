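"""Selection criteria: salience weighting, favoredness, schema/silhouette fit."""

import dataclasses

import numpy as np
import pytest

from vocalmap.alignment import AlignmentSpan
from vocalmap.combination import CombineSpec, Piece
from vocalmap.matching import (
    Exemplar,
    MatchConfig,
    SalienceFn,
    UsageStats,
    favoredness,
    schema_fit,
    select,
    silhouette_fit,
    weighted_perceptual_distance,
)
from vocalmap.phonforms import Schema, init_silhouette
from vocalmap.pm_map import PerceptualMotorMap
from vocalmap.spaces import ValidationError
from vocalmap.trajectories import (
    MotorTrajectory,
    PerceptualTrajectory,
    traj_distance_perceptual,
)
from vocalmap.devsim import SimConfig, babble_generator
from .conftest import sine_motor_trajectory


def exemplar_from(p, salience=None, concept="c"):
    sal = salience or SalienceFn.constant(1.0, p.domain_end)
    return Exemplar(trajectory=p, concept=concept, salience=sal)


@pytest.fixture
def linked_map():
    pm = PerceptualMotorMap()
    usage = UsageStats()
    for b in babble_generator(SimConfig(seed=4, n_babbles=5), seed=4):
        mid, _ = pm.record_vocalization(b)
        usage.record_traversal(mid)
    return pm, usage


class TestWeightedPerceptualDistance:
    def test_zero_salience_gives_zero(self, linked_map):
        pm, _ = linked_map
        pids = list(pm.perceptual)
        e = exemplar_from(pm.perceptual[pids[0]], SalienceFn.constant(0.0, 2.0))
        assert weighted_perceptual_distance(e, pm.perceptual[pids[1]]) == 0.0

    def test_step_salience_ignores_changes_on_second_half(self, linked_map):
        # the canonical half/half salience: only the first syllable matters
        pm, _ = linked_map
        pids = list(pm.perceptual)
        e = exemplar_from(pm.perceptual[pids[0]], SalienceFn.step(2.0))
        p = pm.perceptual[pids[1]]
        base = weighted_perceptual_distance(e, p)
        altered_vals = p.values.copy()
        second_half = p.times > p.domain_end / 2
        altered_vals[second_half, 0] += 37.0  # arbitrary change, dLoud
        altered = dataclasses.replace(p, values=altered_vals, id="")
        assert weighted_perceptual_distance(e, altered) == pytest.approx(base, abs=1e-12)

    def test_full_salience_equals_trajectory_pseudometric(self, linked_map):
        pm, _ = linked_map
        pids = list(pm.perceptual)
        e = exemplar_from(pm.perceptual[pids[0]])
        p = pm.perceptual[pids[1]]
        assert weighted_perceptual_distance(e, p) == pytest.approx(
            traj_distance_perceptual(e.trajectory, p), abs=1e-12
        )

    def test_salience_values_validated(self):
        with pytest.raises(ValidationError):
            SalienceFn(lambda t: np.full_like(t, 1.5), 2.0)(np.array([0.3]))


class TestFavoredness:
    def test_zero_counts_give_minimum(self):
        usage = UsageStats()
        assert favoredness("m1", usage) == 0.0

    def test_monotone_in_counts(self):
        usage = UsageStats()
        prev = favoredness("m1", usage)
        for _ in range(5):
            usage.record_traversal("m1")
            cur = favoredness("m1", usage)
            assert cur >= prev
            prev = cur

    def test_combination_uses_min_seam_count_log_formula(self):
        spec = CombineSpec(
            pieces=(Piece("a", 0.0, 0.7), Piece("b", 0.8, 1.7), Piece("c", 1.6, 2.0)),
            deltas=(0.1, 0.1),
        )
        usage = UsageStats()
        usage.record_combination(spec, n=3)
        usage.co_traversals[("a", 0.7, "b", 0.8)] += 4  # one seam more practiced
        assert favoredness(spec, usage) == pytest.approx(np.log1p(3))


class TestSchemaFit:
    def test_exact_sub_stretch_found_with_value_zero(self):
        # m1's first syllable is a uniform stretch of the schema
        m1 = sine_motor_trajectory(domain_end=2.0, syllables=2, n=161)
        sub_vals = m1.evaluate(np.linspace(0.0, 1.0, 81))
        schema = MotorTrajectory(times=np.linspace(0, 1, 81), values=sub_vals)
        value, span = schema_fit(m1, schema, k=0.5, n_span=5, n_quad=41)
        assert value == pytest.approx(0.0, abs=1e-9)
        assert (span.alpha, span.beta) == (0.0, 1.0)

    def test_identical_schema_full_span_zero(self):
        m1 = sine_motor_trajectory()
        value, span = schema_fit(m1, m1, k=0.5, n_span=5, n_quad=33)
        assert value == pytest.approx(0.0, abs=1e-12)
        assert (span.alpha, span.beta) == (0.0, 2.0)

    def test_grid_search_equals_exhaustive_oracle(self):
        m1 = sine_motor_trajectory(phase=0.0, n=33)
        schema = sine_motor_trajectory(phase=0.7, n=33)
        n_span, n_quad, k = 7, 9, 0.5
        value, span = schema_fit(m1, schema, k=k, n_span=n_span, n_quad=n_quad)
        # independent brute force over the same span grid
        from vocalmap.spaces import d_artic

        grid = np.linspace(0, 2, n_span)
        best = np.inf
        for a in grid:
            for b in grid:
                if b - a < k - 1e-12:
                    continue
                ts = np.linspace(a, b, n_quad)
                hs = 2.0 * (ts - a) / (b - a)
                d = d_artic(m1.evaluate(ts), schema.evaluate(hs))
                best = min(best, float(np.trapezoid(d, ts)) / (b - a))
        assert value == pytest.approx(best, abs=1e-12)

    def test_invariant_to_uniform_stretch_of_candidate(self):
        m1 = sine_motor_trajectory(phase=0.3)
        schema = sine_motor_trajectory(phase=0.9)
        stretched = dataclasses.replace(m1, times=m1.times * 1.8, id="")
        v1, _ = schema_fit(m1, schema, k=0.5)
        v2, _ = schema_fit(stretched, schema, k=0.5)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_span_bound_enforced(self):
        with pytest.raises(ValidationError):
            AlignmentSpan(alpha=1.0, beta=1.2, k=0.5)
        m = sine_motor_trajectory()
        with pytest.raises(ValidationError):
            schema_fit(m, m, k=3.0)  # k exceeds the domain


class TestSilhouetteFit:
    def test_single_schema_silhouette_equals_schema_fit(self):
        # criterion 4* on singleton regions reduces exactly to criterion 4
        m = sine_motor_trajectory(phase=0.4)
        schema_traj = sine_motor_trajectory(phase=0.0)
        sil = init_silhouette(Schema(schema_traj, "c"))
        v_sil, span_sil = silhouette_fit(m, sil, k=0.5, n_span=5, n_quad=21)
        v_sch, span_sch = schema_fit(m, schema_traj, k=0.5, n_span=5, n_quad=21)
        # nearest-grid region lookup vs linear schema interpolation differ at
        # sub-grid-step level only
        assert v_sil == pytest.approx(v_sch, abs=5e-3)
        assert span_sil == span_sch

    def test_contained_trajectory_fits_with_value_zero(self):
        m = sine_motor_trajectory()
        sil = init_silhouette(Schema(m, "c"))
        # quadrature points aligned with the silhouette grid: containment exact
        value, span = silhouette_fit(m, sil, k=0.5, n_span=5, n_quad=129)
        assert value == pytest.approx(0.0, abs=1e-9)
        assert (span.alpha, span.beta) == (0.0, 2.0)


class TestSelect:
    def test_single_candidate_returned(self, linked_map):
        pm, usage = linked_map
        lone = PerceptualMotorMap()
        mid, pid = lone.record_vocalization(sine_motor_trajectory())
        e = exemplar_from(lone.perceptual[pid])
        res = select(e, lone, usage=UsageStats(), config=MatchConfig())
        assert res.candidate.cid == mid

    def test_planted_target_wins_with_zero_distance(self, linked_map):
        pm, usage = linked_map
        pids = list(pm.perceptual)
        e = exemplar_from(pm.perceptual[pids[2]])
        res = select(e, pm, usage=usage, config=MatchConfig())
        assert res.candidate.cid == pm.linked(pids[2])
        assert res.c2 == pytest.approx(0.0, abs=1e-12)

    def test_tie_on_distance_broken_by_traversal_counts(self, linked_map):
        pm, _ = linked_map
        mids = list(pm.motor)
        # two identical-content candidates, one more practiced
        pm2 = PerceptualMotorMap()
        m = sine_motor_trajectory()
        id1, p1 = pm2.record_vocalization(m)
        id2, _ = pm2.record_vocalization(m)
        usage = UsageStats()
        usage.record_traversal(id1, 1)
        usage.record_traversal(id2, 5)
        e = exemplar_from(pm2.perceptual[p1])
        res = select(e, pm2, usage=usage, config=MatchConfig())
        assert res.candidate.cid == id2

    def test_empty_map_rejected(self):
        e = exemplar_from(
            PerceptualTrajectory(times=np.linspace(0, 1, 5), values=np.zeros((5, 12)))
        )
        with pytest.raises(ValidationError):
            select(e, PerceptualMotorMap(), usage=UsageStats(), config=MatchConfig())

    def test_lexicographic_mode_orders_by_distance_first(self, linked_map):
        pm, usage = linked_map
        pids = list(pm.perceptual)
        e = exemplar_from(pm.perceptual[pids[1]])
        res = select(e, pm, usage=usage, config=MatchConfig(mode="lexicographic"))
        assert res.candidate.cid == pm.linked(pids[1])

    def test_combination_candidates_respect_eps_and_practice(self):
        # vocal-motor-scheme behavior: every piece of the winner is practiced
        cfg = SimConfig(seed=6, n_babbles=8)
        pm = PerceptualMotorMap()
        usage = UsageStats()
        for b in babble_generator(cfg, seed=6):
            mid, _ = pm.record_vocalization(b)
            usage.record_traversal(mid)
        # an exemplar that no single babble matches: variegated hidden form
        from vocalmap.devsim import exemplar_generator

        exs = exemplar_generator(cfg, seed=99, forward_map=pm.forward_map)
        mc = MatchConfig(pivot_pool_size=8, max_combination_candidates=100)
        for concept in exs:
            e = dataclasses.replace(
                exs[concept][0],
                salience=SalienceFn.constant(1.0, exs[concept][0].trajectory.domain_end),
            )
            res = select(e, pm, usage=usage, config=mc)
            if res.candidate.kind == "combination":
                spec = res.candidate.spec
                for piece in spec.pieces:
                    assert usage.traversals[piece.traj_id] > 0
                # eps eligibility held by construction
                for (p1, p2) in zip(spec.pieces, spec.pieces[1:]):
                    a1 = pm.motor[p1.traj_id].evaluate(p1.end)
                    a2 = pm.motor[p2.traj_id].evaluate(p2.start)
                    from vocalmap.spaces import d_artic

                    assert d_artic(a1, a2) < mc.eps
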