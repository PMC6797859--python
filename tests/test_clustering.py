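"""K-means correctness, inertia identities, refinement, overlays."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.cluster import KMeans as SkKMeans

from hetier import (
    CompartmentPixels,
    cluster_compartments,
    kmeans_rgb,
    overlay_clusters,
    refine_compartment,
)


def pixels_of(rgb, compartment="stroma"):
    rgb = np.asarray(rgb, dtype=np.uint8)
    n = len(rgb)
    coords = np.column_stack([np.arange(n), np.zeros(n, int)])
    return CompartmentPixels(compartment=compartment, coordinates=coords, rgb=rgb)


def exhaustive_min_inertia(X, k):
    """Minimum SSE over all set partitions of n points into <= k blocks.

    Blocks are numbered in first-occurrence order so each partition is
    enumerated exactly once; per-block sums and counts are maintained
    incrementally, with SSE = sum(|x|^2) - sum_b |s_b|^2 / n_b.
    """
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    sumsq = float((X**2).sum())
    sums = np.zeros((k, 3))
    counts = np.zeros(k, int)
    best = np.inf

    def rec(i, nblocks):
        nonlocal best
        if i == n:
            between = sum(
                (sums[b] @ sums[b]) / counts[b] for b in range(nblocks)
            )
            best = min(best, sumsq - between)
            return
        for b in range(min(nblocks + 1, k)):
            sums[b] += X[i]
            counts[b] += 1
            rec(i + 1, max(nblocks, b + 1))
            sums[b] -= X[i]
            counts[b] -= 1

    rec(0, 0)
    return best


class TestKmeansRgb:
    def test_k_equals_n_distinct_gives_zero_inertia(self):
        res = kmeans_rgb(pixels_of([(0, 0, 0), (2, 2, 2)]), k=2, seed=1)
        assert res.inertia == 0.0
        assert sorted(map(tuple, res.centroids.astype(int))) == [(0, 0, 0), (2, 2, 2)]

    def test_single_cluster_hand_case(self):
        res = kmeans_rgb(pixels_of([(0, 0, 0), (2, 2, 2)]), k=1, seed=1)
        assert np.allclose(res.centroids, [[1.0, 1.0, 1.0]])
        assert res.inertia == 6.0  # 3 + 3 exactly

    def test_matches_exhaustive_two_partition_optimum(self, rng):
        X = rng.integers(0, 256, size=(6, 3)).astype(np.uint8)
        res = kmeans_rgb(pixels_of(X), k=2, seed=3)
        # independent oracle: all 31 bipartitions of 6 points
        best = np.inf
        pts = X.astype(float)
        for r in range(1, 6):
            for left in combinations(range(6), r):
                left = list(left)
                right = [i for i in range(6) if i not in left]
                sse = sum(
                    ((pts[idx] - pts[idx].mean(axis=0)) ** 2).sum()
                    for idx in (left, right)
                )
                best = min(best, sse)
        assert res.inertia == pytest.approx(best, rel=1e-12)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="2"):
            kmeans_rgb(pixels_of([(5, 5, 5), (5, 5, 5), (9, 9, 9)]), k=3)

    def test_seed_determinism(self, rng):
        X = rng.integers(0, 256, size=(200, 3)).astype(np.uint8)
        a = kmeans_rgb(pixels_of(X), k=3, seed=7)
        b = kmeans_rgb(pixels_of(X), k=3, seed=7)
        assert a.inertia == b.inertia
        assert np.array_equal(a.labels, b.labels)

    def test_best_of_restarts_monotone_in_n_init(self, rng):
        X = rng.integers(0, 256, size=(300, 3)).astype(np.uint8)
        inertias = [
            kmeans_rgb(pixels_of(X), k=4, n_init=n, seed=11).inertia for n in (1, 5, 10)
        ]
        assert inertias[0] >= inertias[1] >= inertias[2]

    def test_inertia_consistent_with_labels_and_centroids(self, rng):
        X = rng.integers(0, 256, size=(500, 3)).astype(np.uint8)
        res = kmeans_rgb(pixels_of(X), k=4, seed=2)
        assert res.inertia == pytest.approx(res.recompute_inertia(X), rel=1e-9)

    def test_law_of_total_variance(self, rng):
        for _ in range(10):
            X = rng.integers(0, 256, size=(80, 3)).astype(np.uint8)
            res = kmeans_rgb(pixels_of(X), k=3, seed=5)
            pts = X.astype(float)
            total = ((pts - pts.mean(axis=0)) ** 2).sum()
            counts = np.bincount(res.labels, minlength=res.k)
            between = sum(
                counts[j] * ((res.centroids[j] - pts.mean(axis=0)) ** 2).sum()
                for j in range(res.k)
            )
            assert total == pytest.approx(res.inertia + between, rel=1e-9)

    def test_inertia_non_increasing_in_k(self, rng):
        X = rng.integers(0, 256, size=(400, 3)).astype(np.uint8)
        inertias = [kmeans_rgb(pixels_of(X), k=k, seed=4).inertia for k in (2, 3, 4, 5)]
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_agrees_with_sklearn_best_of_restarts(self, rng):
        """Independent cross-check against sklearn's own full KMeans."""
        X = rng.integers(0, 256, size=(500, 3)).astype(np.uint8)
        ours = kmeans_rgb(pixels_of(X), k=3, seed=6).inertia
        theirs = SkKMeans(n_clusters=3, n_init=10, max_iter=300, random_state=0).fit(
            X.astype(float)
        ).inertia_
        assert ours == pytest.approx(theirs, rel=1e-3)

    def test_noise_doubling_quadruples_inertia(self):
        rng = np.random.default_rng(0)
        base = np.array([180.0, 120.0, 150.0])
        for sigma in (8.0,):
            a = np.clip(rng.normal(base, sigma, (12000, 3)), 0, 255).astype(np.uint8)
            b = np.clip(rng.normal(base, 2 * sigma, (12000, 3)), 0, 255).astype(np.uint8)
            ia = kmeans_rgb(pixels_of(a), k=3, seed=1).inertia
            ib = kmeans_rgb(pixels_of(b), k=3, seed=1).inertia
            assert ib / ia == pytest.approx(4.0, rel=0.10)


class TestRefineCompartment:
    def test_minority_mode_removed(self):
        rng = np.random.default_rng(1)
        pink = np.clip(rng.normal((230, 150, 200), 5, (900, 3)), 0, 255)
        dark = np.clip(rng.normal((80, 40, 100), 5, (100, 3)), 0, 255)
        pix = pixels_of(np.vstack([pink, dark]).astype(np.uint8))
        out = refine_compartment(pix, seed=2)
        assert len(out) == 900
        assert out.rgb.mean(axis=0)[0] > 200  # only the pink mode survives

    def test_constant_color_unchanged(self):
        pix = pixels_of(np.full((50, 3), 99, np.uint8))
        out = refine_compartment(pix, seed=1)
        assert len(out) == 50

    def test_balanced_bimodal_guarded(self):
        rng = np.random.default_rng(2)
        a = np.clip(rng.normal((230, 150, 200), 5, (500, 3)), 0, 255)
        b = np.clip(rng.normal((80, 40, 100), 5, (500, 3)), 0, 255)
        pix = pixels_of(np.vstack([a, b]).astype(np.uint8))
        out = refine_compartment(pix, seed=3)
        assert len(out) == 1000  # 50/50 split exceeds the retention threshold


class TestClusterCompartments:
    def test_default_k_values_give_eight_results(self, normal_slide):
        out = cluster_compartments(normal_slide, normal_slide.truth_mask, seed=1)
        assert len(out.results) == 8  # 2 compartments x k in {2,3,4,5}
        assert out.flags == {"epithelium": "ok", "stroma": "ok"}

    def test_inertia_decreases_with_k_on_slides(self, normal_slide):
        out = cluster_compartments(normal_slide, normal_slide.truth_mask, seed=1)
        for comp in ("epithelium", "stroma"):
            inertias = [out.results[(comp, k)].inertia for k in (2, 3, 4, 5)]
            assert all(b <= a + 1e-6 for a, b in zip(inertias, inertias[1:]))

    def test_absent_compartment_flagged_not_fatal(self, normal_slide):
        mask = normal_slide.truth_mask.copy()
        mask[mask == 0] = 1  # erase epithelium
        out = cluster_compartments(normal_slide, mask, k_values=(2,), seed=1)
        assert out.flags["epithelium"] == "absent"
        assert ("stroma", 2) in out.results

    def test_tiny_fixture_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        image = np.zeros((256, 256, 3), np.uint8)
        mask = np.full((256, 256), 3, np.uint8)
        # 12 pixels per compartment with distinct colors
        for code, y in ((0, 10), (1, 30)):
            vals = rng.integers(0, 256, size=(12, 3)).astype(np.uint8)
            mask[y, 10:22] = code
            image[y, 10:22] = vals
        from hetier.synthetic import SlideRecord

        rec = SlideRecord(image=image, truth_mask=mask, patient_id="T", state="normal")
        out = cluster_compartments(
            rec, mask, k_values=(2, 3), seed=4, retention_threshold=0.0,
            n_init=50, tol=0.0,
        )
        for comp in ("epithelium", "stroma"):
            pix = out.refined[comp].rgb
            for k in (2, 3):
                expect = exhaustive_min_inertia(pix, k)
                assert out.results[(comp, k)].inertia == pytest.approx(expect, rel=1e-9)


class TestOverlayClusters:
    def test_overlay_palette_and_grayscale(self, normal_slide):
        out = cluster_compartments(normal_slide, normal_slide.truth_mask, k_values=(3,), seed=2)
        pix = out.refined["stroma"]
        labels = out.results[("stroma", 3)].labels
        overlay = overlay_clusters(normal_slide.image, pix, labels)
        assert overlay.shape == normal_slide.image.shape
        ys, xs = pix.coordinates[:, 0], pix.coordinates[:, 1]
        inside = overlay[ys, xs]
        assert len(np.unique(inside, axis=0)) == 3  # one palette color per cluster
        outside = np.ones(overlay.shape[:2], bool)
        outside[ys, xs] = False
        o = overlay[outside]
        assert np.all(o[:, 0] == o[:, 1]) and np.all(o[:, 1] == o[:, 2])

    def test_empty_mask_is_pure_grayscale(self, normal_slide):
        pix = CompartmentPixels(
            compartment="stroma",
            coordinates=np.empty((0, 2), int),
            rgb=np.empty((0, 3), np.uint8),
        )
        overlay = overlay_clusters(normal_slide.image, pix, np.empty(0, int))
        assert np.all(overlay[..., 0] == overlay[..., 1])

    def test_small_palette_rejected(self, normal_slide):
        pix = pixels_of(np.arange(30, dtype=np.uint8).reshape(10, 3))
        with pytest.raises(ValueError, match="palette"):
            overlay_clusters(normal_slide.image, pix, np.arange(10) % 7, palette=((1, 1, 1),))
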