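"""DIA statistic, noise floor, PCA embedding, k-means, hit flags, deconvolution."""

import itertools

import numpy as np
import pytest

from hsqcscreen.spectra import Peak, PeakList, Spectrum2D, difference_spectrum, render_spectrum
from hsqcscreen.synth import PlexDesign
from hsqcscreen.triage import (
    TriageResult,
    deconvolution_plan,
    dia_statistic,
    estimate_noise_floor,
    flag_hits,
    kmeans_cluster,
    pca_embed,
)

AXIS_H = (6.0, 11.0, 128)
AXIS_N = (100.0, 135.0, 96)


def spec_of(peaks, sample_id="s"):
    return render_spectrum(PeakList(peaks, sample_id=sample_id), AXIS_H, AXIS_N)


class TestDIA:
    def test_zero_difference_gives_zero(self):
        a = spec_of([Peak(8.0, 112.0)])
        assert dia_statistic(difference_spectrum(a, a)) == 0.0

    def test_single_peak_total_matches_grid_sum_oracle(self):
        a = spec_of([Peak(8.0, 112.0, height=3.0)])
        zero = spec_of([])
        d = difference_spectrum(a, zero)
        # independent oracle: direct grid summation
        assert dia_statistic(d, 0.0) == pytest.approx(np.abs(a.grid).sum(), rel=1e-9)

    def test_monotone_nonincreasing_in_floor(self):
        a = spec_of([Peak(8.0, 112.0, 2.0)])
        b = spec_of([Peak(8.05, 112.4, 2.0)])
        d = difference_spectrum(a, b)
        vals = [dia_statistic(d, fl) for fl in (0.0, 0.1, 0.5, 1.0, 2.5)]
        assert all(x >= y for x, y in zip(vals, vals[1:]))
        assert vals[-1] == 0.0


class TestNoiseFloor:
    def test_zero_noise_spectrum_gives_zero(self):
        a = spec_of([])
        assert estimate_noise_floor(a, ((6.2, 7.0), (101.0, 110.0))) == 0.0

    def test_gaussian_noise_estimated_within_20_percent(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(0, 0.25, size=(128, 96))
        spec = Spectrum2D(grid, AXIS_H, AXIS_N, "noise")
        est = estimate_noise_floor(spec, ((6.0, 11.0), (100.0, 135.0)), c=5.0)
        assert est == pytest.approx(5 * 0.25, rel=0.2)

    def test_region_overlapping_peak_inflates_estimate(self):
        a = spec_of([Peak(8.0, 112.0, 50.0)])
        clean = estimate_noise_floor(a, ((9.5, 10.5), (125.0, 134.0)))
        dirty = estimate_noise_floor(a, ((7.5, 8.5), (108.0, 116.0)))
        assert dirty > clean

    def test_region_outside_axes_rejected(self):
        a = spec_of([])
        with pytest.raises(ValueError, match="outside"):
            estimate_noise_floor(a, ((5.0, 7.0), (101.0, 110.0)))

    def test_tiny_region_rejected(self):
        a = spec_of([])
        with pytest.raises(ValueError, match="100"):
            estimate_noise_floor(a, ((8.0, 8.01), (112.0, 112.1)))


class TestPCA:
    def test_identical_spectra_embed_at_origin(self):
        a = spec_of([Peak(8.0, 112.0)])
        coords, evr = pca_embed([a, a, a], n_components=2)
        np.testing.assert_allclose(coords, 0.0)

    def test_two_distinct_spectra_are_symmetric_about_origin(self):
        a = spec_of([Peak(8.0, 112.0)])
        b = spec_of([Peak(9.0, 125.0)])
        coords, evr = pca_embed([a, b], n_components=1)
        assert coords[0, 0] == pytest.approx(-coords[1, 0], rel=1e-5)
        assert evr.sum() <= 1.0 + 1e-9

    def test_embedding_is_reproducible(self):
        rng = np.random.default_rng(1)
        specs = [
            Spectrum2D(rng.normal(size=(16, 12)), (6, 11, 16), (100, 135, 12), f"s{i}")
            for i in range(6)
        ]
        c1, _ = pca_embed(specs, 3, seed=9)
        c2, _ = pca_embed(specs, 3, seed=9)
        np.testing.assert_array_equal(c1, c2)

    def test_axis_mismatch_rejected(self):
        a = spec_of([Peak(8.0, 112.0)])
        b = render_spectrum(PeakList([Peak(8.0, 112.0)], sample_id="x"),
                            AXIS_H, (100.0, 135.0, 64))
        with pytest.raises(Exception, match="axis"):
            pca_embed([a, b], 2)


def brute_force_two_means(points):
    """Best 2-partition by exhaustive enumeration (inertia-minimal)."""
    n = len(points)
    best, best_assign = np.inf, None
    for mask in itertools.product([0, 1], repeat=n):
        if len(set(mask)) < 2:
            continue
        inertia = 0.0
        for g in (0, 1):
            pts = points[[i for i in range(n) if mask[i] == g]]
            inertia += ((pts - pts.mean(axis=0)) ** 2).sum()
        if inertia < best - 1e-12:
            best, best_assign = inertia, mask
    return best_assign


class TestKMeans:
    def test_matches_brute_force_on_small_instance(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.3, (4, 2)), rng.normal(5, 0.3, (4, 2))])
        labels = kmeans_cluster(pts, k=2, seed=0, reference_index=0)
        oracle = brute_force_two_means(pts)
        # same partition up to label naming; cluster 1 holds the reference
        ours = [labels[i] == labels[0] for i in range(8)]
        theirs = [oracle[i] == oracle[0] for i in range(8)]
        assert ours == theirs
        assert labels[0] == 1

    def test_k_equal_one_gives_all_ones(self):
        pts = np.random.default_rng(0).normal(size=(5, 2))
        assert kmeans_cluster(pts, k=1).tolist() == [1] * 5

    def test_same_seed_identical_labels(self):
        pts = np.random.default_rng(2).normal(size=(30, 2))
        a = kmeans_cluster(pts, k=3, seed=5)
        b = kmeans_cluster(pts, k=3, seed=5)
        assert a.tolist() == b.tolist()

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 2)), k=4)


class TestFlagHits:
    def _results(self, rows):
        return [TriageResult(sid, dia, [], cluster=c) for sid, dia, c in rows]

    def test_reference_only_input_yields_no_hits(self):
        res = flag_hits(self._results([("ref", 0.0, 1)]), "ref")
        assert not any(r.is_hit for r in res)

    def test_all_identical_spectra_yield_no_hits(self):
        res = self._results([("ref", 0.0, 1), ("a", 0.0, 1), ("b", 0.0, 1)])
        assert not any(r.is_hit for r in flag_hits(res, "ref"))

    def test_distinct_cluster_with_high_dia_is_flagged(self):
        res = self._results(
            [("ref", 1.0, 1), ("i1", 1.2, 1), ("i2", 0.9, 1), ("hit", 50.0, 2),
             ("lowdia", 2.0, 2)]
        )
        flag_hits(res, "ref", dia_mult=3.0)
        flags = {r.sample_id: r.is_hit for r in res}
        assert flags == {"ref": False, "i1": False, "i2": False,
                         "hit": True, "lowdia": False}

    def test_absolute_threshold_override(self):
        res = self._results([("ref", 0.0, 1), ("a", 10.0, 2), ("b", 30.0, 2)])
        flag_hits(res, "ref", dia_threshold=20.0)
        assert [r.is_hit for r in res] == [False, False, True]

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            flag_hits(self._results([("a", 1.0, 1)]), "missing")


class TestDeconvolution:
    def test_one_12plex_hit_gives_four_triples(self):
        design = PlexDesign({"P1": [f"f{i}" for i in range(12)]}, plex_size=12)
        plan = deconvolution_plan(["P1"], design, next_size=3)
        assert len(plan.assignments) == 4
        assert all(len(v) == 3 for v in plan.assignments.values())
        assert plan.fragment_ids == design.assignments["P1"]  # manifest order

    def test_one_triple_hit_gives_three_singles(self):
        design = PlexDesign({"T1": ["a", "b", "c"]}, plex_size=3)
        plan = deconvolution_plan(["T1"], design, next_size=1)
        assert sorted(plan.fragment_ids) == ["a", "b", "c"]
        assert all(len(v) == 1 for v in plan.assignments.values())

    def test_non_hit_plexes_dropped_and_empty_hits_allowed(self):
        design = PlexDesign({"P1": ["a", "b"], "P2": ["c", "d"]}, plex_size=2)
        plan = deconvolution_plan(["P2"], design, next_size=1)
        assert set(plan.fragment_ids) == {"c", "d"}
        empty = deconvolution_plan([], design, next_size=1)
        assert empty.assignments == {}

    def test_next_size_must_shrink(self):
        design = PlexDesign({"P1": ["a"]}, plex_size=3)
        with pytest.raises(ValueError):
            deconvolution_plan(["P1"], design, next_size=3)
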