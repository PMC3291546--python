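"""Unit and property tests for the distance-based niche statistics.

Brute-force oracles here are deliberate reimplementations with explicit
loops and no shared code with the package.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoniche.metrics import (
    GroupKey,
    InsufficientTissuesError,
    IsotopePoint,
    all_group_metrics,
    centroid_distances,
    difference_dispersion,
    group_centroid,
    individual_contrast,
    individual_contrasts,
    individual_ratios,
    specialization_index,
    total_niche_width,
    within_individual_component,
)
from isoniche.samples import IsotopeSample, SampleSet

from conftest import random_sample_set

COASTAL = GroupKey("coastal", "adult")


# ---------------------------------------------------------------------------
# independent oracles (explicit loops)
# ---------------------------------------------------------------------------


def brute_force_distances(rows):
    """rows: (id, group_label, x, y) -> list of distances, same order."""
    groups = {}
    for _, g, x, y in rows:
        groups.setdefault(g, []).append((x, y))
    centroids = {}
    for g, pts in groups.items():
        sx = sy = 0.0
        for x, y in pts:
            sx += x
            sy += y
        centroids[g] = (sx / len(pts), sy / len(pts))
    out = []
    for _, g, x, y in rows:
        cx, cy = centroids[g]
        out.append(math.sqrt((x - cx) ** 2 + (y - cy) ** 2))
    return out


def translate(s: SampleSet, dc: float, dn: float) -> SampleSet:
    return SampleSet(
        tuple(
            IsotopeSample(x.individual_id, x.province, x.habitat, x.age, x.tissue,
                          x.d13c + dc, x.d15n + dn)
            for x in s
        )
    )


def scale_about_centroid(s: SampleSet, k: float) -> SampleSet:
    cx = sum(x.d13c for x in s) / len(s)
    cy = sum(x.d15n for x in s) / len(s)
    return SampleSet(
        tuple(
            IsotopeSample(x.individual_id, x.province, x.habitat, x.age, x.tissue,
                          cx + k * (x.d13c - cx), cy + k * (x.d15n - cy))
            for x in s
        )
    )


class TestGroupCentroid:
    def test_singleton(self):
        c = group_centroid([IsotopePoint(-20.0, 8.0)])
        assert (c.c, c.n) == (-20.0, 8.0)

    def test_coastal_prey_mean(self):
        # componentwise mean of four printed coastal prey signatures
        pts = [IsotopePoint(-17.41, 14.28), IsotopePoint(-15.75, 15.91),
               IsotopePoint(-14.47, 11.42), IsotopePoint(-19.99, 8.99)]
        c = group_centroid(pts)
        assert c.c == pytest.approx(-16.905, abs=1e-9)
        assert c.n == pytest.approx(12.650, abs=1e-9)

    def test_shared_prey_mean(self):
        pts = [IsotopePoint(-23.72, 2.81), IsotopePoint(-25.11, 7.04),
               IsotopePoint(-24.52, 7.12), IsotopePoint(-24.84, 10.28)]
        c = group_centroid(pts)
        assert c.c == pytest.approx(-24.5475, abs=1e-9)
        assert c.n == pytest.approx(6.8125, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_centroid([])


class TestCentroidDistances:
    def test_worked_four_point_group(self, worked_example):
        records = centroid_distances(worked_example, "habitat_age")
        got = sorted(r.distance for r in records)
        assert got == pytest.approx([1.5811, 2.9155, 2.9155, 4.3012], abs=1e-4)

    def test_identical_points_zero(self):
        s = SampleSet(
            tuple(
                IsotopeSample(f"i{i}", "P1", "inland", "adult", t, -22.0, 7.0)
                for i, t in enumerate(["fur", "muscle", "collagen"])
            )
        )
        assert all(r.distance == pytest.approx(0.0, abs=1e-12)
                   for r in centroid_distances(s, "habitat_age"))

    def test_translation_invariance(self, worked_example):
        base = [r.distance for r in centroid_distances(worked_example, "habitat_age")]
        moved = [r.distance for r in centroid_distances(translate(worked_example, 5.0, 3.0),
                                                        "habitat_age")]
        assert moved == pytest.approx(base, abs=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            centroid_distances(SampleSet(()))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        s = random_sample_set(rng, n_individuals=rng.integers(8, 60))
        for grouping in ("habitat_age", "habitat_age_tissue"):
            records = centroid_distances(s, grouping)
            rows = [
                (x.individual_id,
                 (x.habitat, x.age, x.tissue if grouping == "habitat_age_tissue" else None),
                 x.d13c, x.d15n)
                for x in s
            ]
            expected = {
                (row[0], x.tissue): d
                for row, x, d in zip(rows, s, brute_force_distances(rows))
            }
            got = {(r.individual_id, r.tissue): r.distance for r in records}
            assert got == pytest.approx(expected, abs=1e-9)

    def test_order_permutation_invariant(self):
        rng = np.random.default_rng(7)
        s = random_sample_set(rng, n_individuals=12)
        shuffled = SampleSet(tuple(np.random.default_rng(1).permutation(np.array(s.samples, dtype=object))))
        base = {(r.individual_id, r.tissue): r.distance for r in centroid_distances(s)}
        perm = {(r.individual_id, r.tissue): r.distance for r in centroid_distances(shuffled)}
        assert perm == pytest.approx(base, abs=1e-12)


class TestTotalNicheWidth:
    def test_worked_example(self, worked_example):
        assert total_niche_width(worked_example, COASTAL) == pytest.approx(2.9283, abs=1e-4)

    def test_identical_points_zero(self):
        s = SampleSet(
            (
                IsotopeSample("a", "P1", "coastal", "adult", "muscle", -20, 8),
                IsotopeSample("b", "P1", "coastal", "adult", "muscle", -20, 8),
            )
        )
        assert total_niche_width(s, COASTAL) == 0.0

    def test_single_sample_rejected(self):
        s = SampleSet((IsotopeSample("a", "P1", "coastal", "adult", "muscle", -20, 8),))
        with pytest.raises(ValueError):
            total_niche_width(s, COASTAL)

    def test_doubling_about_centroid_doubles(self, worked_example):
        base = total_niche_width(worked_example, COASTAL)
        doubled = total_niche_width(scale_about_centroid(worked_example, 2.0), COASTAL)
        assert doubled == pytest.approx(2.0 * base, abs=1e-9)


class TestIndividualContrast:
    def test_worked_example(self, worked_example):
        c = individual_contrast(worked_example, "A")
        assert (c.diff.c, c.diff.n) == (-2.0, -2.0)
        assert c.breadth == pytest.approx(2.8284, abs=1e-4)

    def test_equal_tissues_zero(self, worked_example):
        c = individual_contrast(worked_example, "B")
        assert c.breadth == 0.0

    def test_missing_collagen_rejected(self):
        s = SampleSet(
            (
                IsotopeSample("a", "P1", "coastal", "adult", "fur", -20, 8),
                IsotopeSample("a", "P1", "coastal", "adult", "muscle", -20, 8),
            )
        )
        with pytest.raises(InsufficientTissuesError, match="'a'"):
            individual_contrast(s, "a")

    def test_contrasts_report_skipped(self, worked_example):
        extra = SampleSet(
            worked_example.samples
            + (IsotopeSample("c", "P1", "coastal", "adult", "fur", -20, 8),)
        )
        contrasts, skipped = individual_contrasts(extra)
        assert [c.individual_id for c in contrasts] == ["A", "B"]
        assert skipped == ["c"]


class TestWithinIndividualComponent:
    def test_worked_example(self, worked_example):
        assert within_individual_component(worked_example, COASTAL) == pytest.approx(0.7071, abs=1e-4)

    def test_identical_tissue_pairs_zero(self):
        s = SampleSet(
            (
                IsotopeSample("a", "P1", "coastal", "adult", "muscle", -20, 8),
                IsotopeSample("a", "P1", "coastal", "adult", "collagen", -20, 8),
            )
        )
        assert within_individual_component(s, COASTAL) == 0.0

    def test_single_individual_half_pair_distance(self):
        s = SampleSet(
            (
                IsotopeSample("a", "P1", "coastal", "adult", "muscle", -20, 8),
                IsotopeSample("a", "P1", "coastal", "adult", "collagen", -17, 4),
            )
        )
        assert within_individual_component(s, COASTAL) == pytest.approx(5.0 / 2, abs=1e-12)

    def test_breadth_is_twice_per_sample_contribution(self, worked_example):
        wic = within_individual_component(worked_example, COASTAL)
        breadths = [individual_contrast(worked_example, i).breadth for i in ("A", "B")]
        assert wic == pytest.approx(np.mean(breadths) / 2.0, abs=1e-12)

    def test_no_paired_individual_rejected(self):
        s = SampleSet((IsotopeSample("a", "P1", "coastal", "adult", "fur", -20, 8),))
        with pytest.raises(ValueError):
            within_individual_component(s, COASTAL)


class TestDifferenceDispersion:
    def test_worked_example(self, worked_example):
        contrasts, _ = individual_contrasts(worked_example)
        dists = [r.distance for r in difference_dispersion(contrasts)]
        assert dists == pytest.approx([1.4142, 1.4142], abs=1e-4)

    def test_identical_diffs_zero(self):
        s = SampleSet(
            (
                IsotopeSample("a", "P1", "coastal", "adult", "muscle", -20, 8),
                IsotopeSample("a", "P1", "coastal", "adult", "collagen", -21, 9),
                IsotopeSample("b", "P1", "coastal", "adult", "muscle", -23, 5),
                IsotopeSample("b", "P1", "coastal", "adult", "collagen", -24, 6),
            )
        )
        contrasts, _ = individual_contrasts(s)
        assert all(r.distance == pytest.approx(0, abs=1e-12)
                   for r in difference_dispersion(contrasts))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            difference_dispersion([])

    def test_constant_shift_of_diffs_invariant(self, worked_example):
        contrasts, _ = individual_contrasts(worked_example)
        base = sorted(r.distance for r in difference_dispersion(contrasts))
        # shifting all collagen samples by a constant shifts every diff by a
        # constant vector; dispersion distances must not change
        shifted = SampleSet(
            tuple(
                IsotopeSample(x.individual_id, x.province, x.habitat, x.age, x.tissue,
                              x.d13c + (1.3 if x.tissue == "collagen" else 0.0),
                              x.d15n + (-0.7 if x.tissue == "collagen" else 0.0))
                for x in worked_example
            )
        )
        contrasts2, _ = individual_contrasts(shifted)
        moved = sorted(r.distance for r in difference_dispersion(contrasts2))
        assert moved == pytest.approx(base, abs=1e-9)

    def test_global_sign_flip_invariant(self, worked_example):
        # swapping the muscle/collagen roles flips every diff vector's sign
        contrasts, _ = individual_contrasts(worked_example)
        swapped = SampleSet(
            tuple(
                IsotopeSample(x.individual_id, x.province, x.habitat, x.age,
                              {"muscle": "collagen", "collagen": "muscle"}.get(x.tissue, x.tissue),
                              x.d13c, x.d15n)
                for x in worked_example
            )
        )
        contrasts2, _ = individual_contrasts(swapped)
        assert sorted(r.distance for r in difference_dispersion(contrasts2)) == pytest.approx(
            sorted(r.distance for r in difference_dispersion(contrasts)), abs=1e-9
        )


class TestSpecializationIndex:
    def test_worked_example(self, worked_example):
        m = specialization_index(worked_example, COASTAL)
        assert m.wic == pytest.approx(0.7071, abs=1e-4)
        assert m.tnw == pytest.approx(2.9283, abs=1e-4)
        assert m.wic_tnw == pytest.approx(0.2415, abs=1e-4)
        assert m.n_samples == 4
        assert m.n_individuals == 2

    def test_spread_specialists_index_zero(self):
        s = SampleSet(
            (
                IsotopeSample("a", "P1", "coastal", "adult", "muscle", -20, 8),
                IsotopeSample("a", "P1", "coastal", "adult", "collagen", -20, 8),
                IsotopeSample("b", "P1", "coastal", "adult", "muscle", -24, 5),
                IsotopeSample("b", "P1", "coastal", "adult", "collagen", -24, 5),
            )
        )
        assert specialization_index(s, COASTAL).wic_tnw == 0.0

    def test_symmetric_generalists_approach_one(self):
        # individuals share one centroid; each pair straddles it in opposing
        # directions with equal distance -> WIC equals TNW-like spread
        n = 40
        samples = []
        rng = np.random.default_rng(0)
        for i in range(n):
            theta = rng.uniform(0, 2 * np.pi)
            dx, dy = 2.0 * np.cos(theta), 2.0 * np.sin(theta)
            samples.append(IsotopeSample(f"i{i}", "P1", "coastal", "adult", "muscle",
                                         -21 + dx, 8 + dy))
            samples.append(IsotopeSample(f"i{i}", "P1", "coastal", "adult", "collagen",
                                         -21 - dx, 8 - dy))
        m = specialization_index(SampleSet(tuple(samples)), COASTAL)
        assert 0.97 < m.wic_tnw <= 1.0 + 1e-9

    def test_zero_tnw_rejected(self):
        s = SampleSet(
            (
                IsotopeSample("a", "P1", "coastal", "adult", "muscle", -20, 8),
                IsotopeSample("a", "P1", "coastal", "adult", "collagen", -20, 8),
            )
        )
        with pytest.raises(ValueError, match="undefined"):
            specialization_index(s, COASTAL)

    def test_tnw_scope_all_uses_every_tissue(self):
        rng = np.random.default_rng(3)
        s = random_sample_set(rng, n_individuals=16)
        paired = specialization_index(s, COASTAL, tnw_scope="paired")
        pooled = specialization_index(s, COASTAL, tnw_scope="all")
        assert paired.wic == pytest.approx(pooled.wic, abs=1e-12)
        assert paired.tnw != pytest.approx(pooled.tnw, abs=1e-9)

    def test_all_group_metrics_skips_unusable_groups(self, worked_example):
        extra = SampleSet(
            worked_example.samples
            + (IsotopeSample("c", "P2", "inland", "adult", "fur", -24, 6),)
        )
        metrics, skipped = all_group_metrics(extra)
        assert len(metrics) == 1
        assert len(skipped) == 1 and "inland/adult" in skipped[0]


class TestIndividualRatios:
    def test_group_averages_recover_wic_and_tnw_scale(self, worked_example):
        ratios = individual_ratios(worked_example, COASTAL)
        assert set(ratios) == {"A", "B"}
        assert ratios["B"] == 0.0
        assert 0.0 < ratios["A"] < 1.0


# ---------------------------------------------------------------------------
# global properties
# ---------------------------------------------------------------------------


def _paired_points(s: SampleSet):
    """(individual -> 2x2 point array) over muscle+collagen-complete animals."""
    pool = {}
    for x in s:
        if x.tissue in ("muscle", "collagen"):
            pool.setdefault(x.individual_id, {})[x.tissue] = (x.d13c, x.d15n)
    return {
        k: np.array([v["muscle"], v["collagen"]])
        for k, v in pool.items() if len(v) == 2
    }


@pytest.mark.parametrize("seed", range(10))
def test_sum_of_squares_decomposition(seed):
    """Total SS about the grand centroid splits exactly into within-individual
    and between-individual parts on the muscle+collagen subset."""
    rng = np.random.default_rng(seed)
    s = random_sample_set(rng, n_individuals=rng.integers(8, 40))
    paired = _paired_points(s)
    pts = np.concatenate(list(paired.values()))
    grand = pts.mean(axis=0)
    ss_total = float(((pts - grand) ** 2).sum())
    ss_within = sum(float(((p - p.mean(axis=0)) ** 2).sum()) for p in paired.values())
    ss_between = sum(
        len(p) * float(((p.mean(axis=0) - grand) ** 2).sum()) for p in paired.values()
    )
    assert ss_total == pytest.approx(ss_within + ss_between, abs=1e-9)
    # consequence: RMS within-spread never exceeds RMS total spread
    assert math.sqrt(ss_within / len(pts)) <= math.sqrt(ss_total / len(pts)) + 1e-12


@pytest.mark.parametrize("seed", range(3))
def test_metrics_translation_invariant_and_scale_equivariant(seed):
    rng = np.random.default_rng(seed)
    s = random_sample_set(rng, n_individuals=16)
    m0 = specialization_index(s, COASTAL)
    mt = specialization_index(translate(s, -4.2, 2.9), COASTAL)
    assert (mt.tnw, mt.wic, mt.wic_tnw) == pytest.approx((m0.tnw, m0.wic, m0.wic_tnw), abs=1e-9)
    k = 3.0
    ms = specialization_index(scale_about_centroid(s, k), COASTAL)
    assert ms.tnw == pytest.approx(k * m0.tnw, rel=1e-9)
    assert ms.wic == pytest.approx(k * m0.wic, rel=1e-9)
    assert ms.wic_tnw == pytest.approx(m0.wic_tnw, rel=1e-9)


@given(st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_wic_never_exceeds_rms_bound(seed):
    rng = np.random.default_rng(seed)
    s = random_sample_set(rng, n_individuals=12)
    m = specialization_index(s, COASTAL)
    assert m.tnw >= 0 and m.wic >= 0
    assert m.wic_tnw >= 0
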