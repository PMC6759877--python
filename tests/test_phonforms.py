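"""Schemas, silhouettes, noisy execution, and hull-region geometry."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize

from vocalmap.phonforms import (
    Schema,
    Silhouette,
    align_schema,
    execute_with_noise,
    init_silhouette,
    make_schema,
    region_distance,
    region_distances,
    silhouette_widths,
    update_silhouette,
)
from vocalmap.spaces import ValidationError, d_artic
from vocalmap.trajectories import continuity_violation, DEFAULT_KAPPA
from .conftest import sine_motor_trajectory


class TestExecuteWithNoise:
    def test_zero_sigma_is_identity(self):
        m = sine_motor_trajectory()
        assert execute_with_noise(m, 0.0, seed=1) is m

    def test_deterministic_given_seed(self):
        m = sine_motor_trajectory()
        a = execute_with_noise(m, 0.05, seed=42)
        b = execute_with_noise(m, 0.05, seed=42)
        assert np.array_equal(a.values, b.values)
        c = execute_with_noise(m, 0.05, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_mean_deviation_scales_with_sigma(self):
        # Monte-Carlo: doubling sigma doubles the expected pointwise deviation
        m = sine_motor_trajectory()
        def mean_dev(sigma):
            devs = []
            for seed in range(40):
                e = execute_with_noise(m, sigma, seed=seed)
                devs.append(np.mean(d_artic(e.values, m.values)))
            return np.mean(devs)
        r = mean_dev(0.04) / mean_dev(0.02)
        assert 1.7 < r < 2.3

    def test_outputs_stay_in_valid_ranges_and_continuous(self):
        m = sine_motor_trajectory(amp=0.95)
        e = execute_with_noise(m, 0.2, seed=7)
        assert np.all(e.values[:, :10] >= 0) and np.all(e.values[:, :10] <= 1)
        assert np.all(np.abs(e.values[:, 19]) <= 1)
        assert continuity_violation(e, DEFAULT_KAPPA) <= 0.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            execute_with_noise(sine_motor_trajectory(), -0.1, seed=1)


class TestSchema:
    def test_no_schema_without_success(self):
        m = sine_motor_trajectory()
        assert make_schema(m, "dog", success=False) is None

    def test_schema_content_identical_to_execution(self):
        m = sine_motor_trajectory()
        s = make_schema(m, "dog", success=True)
        assert s.concept == "dog"
        assert np.array_equal(s.trajectory.values, m.values)

    def test_repeated_successes_index_increments(self):
        m = sine_motor_trajectory()
        schemas = [make_schema(m, "dog", True, index=i) for i in (1, 2, 3)]
        assert [s.index for s in schemas] == [1, 2, 3]


class TestRegionDistance:
    def test_vertex_gives_zero(self, rng):
        V = rng.normal(size=(4, 20))
        assert region_distance(V[2], V) == pytest.approx(0.0, abs=1e-9)

    def test_two_vertex_segment_closed_form(self):
        a = np.zeros(20)
        b = np.zeros(20)
        b[0] = 2.0
        x = np.zeros(20)
        x[0], x[1] = 1.0, 1.5  # above the segment midpoint
        assert region_distance(x, np.stack([a, b])) == pytest.approx(1.5)

    def test_matches_simplex_grid_oracle(self, rng):
        # brute-force minimization over a fine barycentric grid
        for _ in range(5):
            V = rng.normal(size=(3, 20))
            x = rng.normal(size=20) * 0.5
            got = region_distance(x, V)
            g = np.linspace(0, 1, 81)
            best = np.inf
            for w1 in g:
                for w2 in g:
                    if w1 + w2 <= 1:
                        p = w1 * V[0] + w2 * V[1] + (1 - w1 - w2) * V[2]
                        best = min(best, np.linalg.norm(p - x))
            assert got <= best + 1e-12
            assert got == pytest.approx(best, abs=1e-3)

    def test_matches_slsqp_oracle(self, rng):
        # independent constrained-optimization solver as the reference
        for _ in range(10):
            k = int(rng.integers(3, 9))
            V = rng.normal(size=(k, 20))
            x = rng.normal(size=20) * 0.7
            got = region_distance(x, V)
            res = minimize(
                lambda w: np.sum((w @ V - x) ** 2),
                np.full(k, 1 / k),
                constraints=[{"type": "eq", "fun": lambda w: np.sum(w) - 1}],
                bounds=[(0, 1)] * k,
                method="SLSQP",
            )
            assert got == pytest.approx(np.sqrt(res.fun), abs=1e-5)

    def test_batched_solver_agrees_with_exact(self, rng):
        pts = rng.normal(size=(30, 20)) * 0.5
        regions = [rng.normal(size=(int(rng.integers(1, 12)), 20)) for _ in range(30)]
        batched = region_distances(pts, regions)
        exact = [region_distance(p, V) for p, V in zip(pts, regions)]
        assert np.allclose(batched, exact, atol=1e-4)

    def test_empty_region_rejected(self):
        with pytest.raises(ValidationError):
            region_distance(np.zeros(20), np.zeros((0, 20)))


class TestSilhouetteLifecycle:
    def test_init_singleton_regions(self):
        m = sine_motor_trajectory()
        sil = init_silhouette(Schema(m, "c"))
        assert sil.n == 1
        assert sil.domain_end == m.domain_end
        assert all(len(r) == 1 for r in sil.regions)

    def test_identical_schema_realigns_to_full_span_with_zero_value(self):
        m = sine_motor_trajectory()
        sil = init_silhouette(Schema(m, "c"))
        span, value = align_schema(sil, Schema(m, "c", 2), k=0.5, n_span=5, n_quad=129)
        assert (span.alpha, span.beta) == (0.0, 2.0)
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_identical_noiseless_updates_keep_singletons(self):
        # repeated perfect executions: the silhouette stays the schema curve
        m = sine_motor_trajectory()
        sil = init_silhouette(Schema(m, "c"))
        for i in range(3):
            span, _ = align_schema(sil, Schema(m, "c", i + 2), k=0.5, n_span=5, n_quad=129)
            sil = update_silhouette(sil, Schema(m, "c", i + 2), span)
        assert sil.n == 4
        assert all(len(r) == 1 for r in sil.regions)
        assert np.allclose(silhouette_widths(sil), 0.0)

    def test_offset_schema_produces_segment_regions_with_contained_midpoint(self):
        m = sine_motor_trajectory()
        sil = init_silhouette(Schema(m, "c"))
        dv = np.zeros(20)
        dv[3] = 0.05  # constant offset in c3
        shifted = dataclasses.replace(m, values=np.clip(m.values + dv, None, 1.0), id="")
        span, _ = align_schema(sil, Schema(shifted, "c", 2), k=0.5, n_span=5, n_quad=129)
        sil2 = update_silhouette(sil, Schema(shifted, "c", 2), span)
        # each aligned region is the segment [old point, old point + dv]
        for t, region in zip(sil2.times, sil2.regions):
            if span.alpha <= t <= span.beta:
                assert len(region) == 2
                mid = region.mean(axis=0)
                assert region_distance(mid, region) == pytest.approx(0.0, abs=1e-9)

    def test_growth_pattern_extension_by_one_syllable(self):
        # "banana" pattern: the new schema appends a syllable; the old
        # silhouette aligns with the overlapping portion at value ~0
        short = sine_motor_trajectory(domain_end=1.0, syllables=1, n=81)
        sil = init_silhouette(Schema(short, "c"))
        longer = sine_motor_trajectory(domain_end=2.0, syllables=2, n=161)
        span, value = align_schema(sil, Schema(longer, "c", 2), k=0.5, n_span=9, n_quad=81)
        assert value == pytest.approx(0.0, abs=1e-9)
        assert span.beta - span.alpha == pytest.approx(1.0)

    def test_monotone_growth_of_aligned_regions(self):
        # noisy schema iterations only ever grow the regions
        m = sine_motor_trajectory()
        sil = init_silhouette(Schema(m, "c"))
        for i in range(6):
            noisy = execute_with_noise(m, 0.03, seed=100 + i)
            span, _ = align_schema(sil, Schema(noisy, "c", i + 2), k=0.5, n_span=3, n_quad=65)
            new = update_silhouette(sil, Schema(noisy, "c", i + 2), span)
            if (span.alpha, span.beta) == (0.0, 2.0):
                for old_region, new_region in zip(sil.regions, new.regions):
                    for vert in old_region:
                        assert region_distance(vert, new_region) < 1e-9
            sil = new

    def test_narrow_where_consistent_wide_where_noisy(self):
        # coordinates held constant across schemas give zero-width regions;
        # perturbed coordinates give width on the order of the perturbation
        m = sine_motor_trajectory()
        sil = init_silhouette(Schema(m, "c"))
        rng = np.random.default_rng(0)
        for i in range(5):
            vals = m.values.copy()
            vals[:, 5] = np.clip(vals[:, 5] + rng.normal(0, 0.05), 0, 1)  # c5 varies
            noisy = dataclasses.replace(m, values=vals, id="")
            span, _ = align_schema(sil, Schema(noisy, "c", i + 2), k=0.5, n_span=3, n_quad=65)
            sil = update_silhouette(sil, Schema(noisy, "c", i + 2), span)
        widths = silhouette_widths(sil)
        assert widths[5] > 0.02  # the perturbed coordinate is wide
        consistent = [i for i in range(20) if i != 5]
        assert np.all(widths[consistent] < 1e-12)  # everything else is narrow

    def test_empty_or_mismatched_regions_rejected(self):
        with pytest.raises(ValidationError):
            Silhouette("c", 1, np.array([0.0, 1.0]), (np.zeros((1, 20)),))
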