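"""Voronoi activity-granule segmentation and active calls."""

import numpy as np
import pytest

from locustal.preproc import DffMovie, preprocess
from locustal.segmentation import (call_active, find_extrema,
                                   refine_boundaries, sd_projection,
                                   segment_and_quantify, voronoi_partition)
from locustal.synthetic import SceneSpec, generate_calcium_movies

from conftest import responsive_assignment


def dff(stack, stim="s", onset=10, window=(10, 20)):
    stack = np.asarray(stack, float)
    return DffMovie(stack, np.ones(stack.shape[1:]), stim, onset, 1.0, window)


class TestSdProjection:
    def test_constant_is_zero(self):
        assert np.allclose(sd_projection([dff(np.ones((8, 5, 5)))]), 0.0)

    def test_oscillating_pixel_population_sd(self):
        stack = np.zeros((10, 4, 4))
        stack[::2, 1, 2] = 1.0
        stack[1::2, 1, 2] = -1.0
        proj = sd_projection([dff(stack)])
        assert proj[1, 2] == pytest.approx(1.0)

    def test_concatenation_not_mean_of_projections(self):
        # two stimuli, each internally constant but at different levels:
        # per-stimulus s.d. is 0, the concatenated s.d. is not
        a = dff(np.zeros((6, 3, 3)))
        b = dff(np.ones((6, 3, 3)))
        proj = sd_projection([a, b])
        assert np.allclose(proj, 0.5)
        mean_of_projs = (sd_projection([a]) + sd_projection([b])) / 2
        assert not np.allclose(proj, mean_of_projs)


class TestFindExtrema:
    def test_two_bumps_two_maxima(self):
        rr, cc = np.mgrid[0:30, 0:30]
        img = (np.exp(-((rr - 8) ** 2 + (cc - 8) ** 2) / 8.0)
               + np.exp(-((rr - 22) ** 2 + (cc - 22) ** 2) / 8.0))
        mx, _ = find_extrema(img)
        assert len(mx) == 2
        got = {tuple(s) for s in mx}
        assert got == {(8, 8), (22, 22)}

    def test_inversion_swaps_maxima_minima(self):
        rng = np.random.default_rng(0)
        img = rng.random((12, 12))
        mx, mn = find_extrema(img)
        mx2, mn2 = find_extrema(-img)
        assert {tuple(s) for s in mx} == {tuple(s) for s in mn2}
        assert {tuple(s) for s in mn} == {tuple(s) for s in mx2}

    def test_plateau_yields_single_centroid_seed(self):
        img = np.zeros((5, 5))
        img[2, 1] = img[2, 2] = 1.0  # 2-pixel plateau maximum
        mx, _ = find_extrema(img)
        assert len(mx) == 1
        assert tuple(mx[0]) == (2, 2)  # centroid (2, 1.5) rounded

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="no extrema"):
            find_extrema(np.ones((6, 6)))


class TestVoronoi:
    def test_single_seed_covers_frame(self):
        g = voronoi_partition(np.array([[3, 3]]), (7, 7))
        assert np.all(g.labels == 1)

    def test_two_symmetric_seeds_split_at_bisector(self):
        g = voronoi_partition(np.array([[5, 2], [5, 7]]), (10, 10))
        counts = g.pixel_counts()
        assert abs(counts[1] - counts[2]) <= 10
        assert np.all(g.labels[:, :4] == 1)
        assert np.all(g.labels[:, 6:] == 2)

    def test_collinear_seeds_make_bands(self):
        g = voronoi_partition(np.array([[1, 5], [5, 5], [9, 5]]), (11, 11))
        assert np.all(g.labels[0:3] == 1)
        assert np.all(g.labels[4:7] == 2)
        assert np.all(g.labels[8:11] == 3)

    def test_ties_go_to_lowest_seed_id(self):
        g = voronoi_partition(np.array([[0, 0], [0, 2]]), (1, 3))
        assert g.labels[0, 1] == 1  # equidistant pixel

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        seeds = rng.uniform(0, 20, (15, 2))
        g = voronoi_partition(seeds, (20, 20))
        assert np.all(g.labels > 0)
        assert set(np.unique(g.labels)) <= set(range(1, 16))


class TestRefine:
    def test_identical_traces_unchanged(self):
        stack = np.tile(np.sin(np.arange(12))[:, None, None], (1, 8, 8))
        g = voronoi_partition(np.array([[2, 2], [5, 5]]), (8, 8))
        refined = refine_boundaries(g, [dff(stack)], min_size=1)
        assert np.array_equal(refined.labels, g.labels)

    def test_mislabeled_border_pixel_moves(self):
        # granule A carries trace 0, granule B trace 1; one A-labeled border
        # pixel carries trace 1 and must defect to B in the first iteration
        T, h, w = 12, 6, 6
        labels = np.ones((h, w), np.int32)
        labels[:, 3:] = 2
        stack = np.zeros((T, h, w))
        stack[:, :, 3:] = 1.0
        stack[:, 2, 2] = 1.0          # the intruder, labeled 1
        g = voronoi_partition(np.array([[2, 1], [2, 4]]), (h, w))
        assert g.labels[2, 2] == 1
        refined = refine_boundaries(g, [dff(stack)], max_iter=1, min_size=1)
        assert refined.labels[2, 2] == 2

    def test_noiseless_purity_not_degraded(self):
        scene = SceneSpec(n_cells=6, noise_sd=0.0, seed=0,
                          frame_shape=(60, 60))
        movies, truth = generate_calcium_movies(scene)
        dffs = [preprocess(m, align=False)[0] for m in movies]
        proj = sd_projection(dffs)
        mx, mn = find_extrema(proj)
        seeds = np.vstack([mx, mn])
        g0 = voronoi_partition(seeds, proj.shape,
                               ["max"] * len(mx) + ["min"] * len(mn))
        g1 = refine_boundaries(g0, dffs)

        def inconsistent(labels):
            # planted-cell pixels whose granule belongs (by majority of its
            # planted pixels) to a different cell
            bad = 0
            for g in np.unique(labels[labels > 0]):
                cells = truth["labels"][labels == g]
                cells = cells[cells > 0]
                if cells.size == 0:
                    continue
                owner = np.bincount(cells).argmax()
                bad += int((cells != owner).sum())
            return bad

        assert inconsistent(g1.labels) <= inconsistent(g0.labels)

    def test_small_granules_fused(self):
        rng = np.random.default_rng(2)
        stack = rng.normal(0, 0.01, (10, 12, 12))
        seeds = np.array([[1, 1], [1, 2], [8, 8]])
        g = voronoi_partition(seeds, (12, 12))
        refined = refine_boundaries(g, [dff(stack)], max_iter=0, min_size=5)
        counts = refined.pixel_counts()
        assert all(c >= 5 for c in counts.values())


class TestCallActive:
    def test_bimodal_split(self):
        mags = {i: 0.0 for i in range(3)} | {i: 1.0 for i in range(3, 6)}
        act = call_active(mags)
        assert sum(act.values()) == 3
        assert all(act[i] for i in range(3, 6))

    def test_all_equal_warns_all_inactive(self):
        with pytest.warns(UserWarning):
            act = call_active({1: 0.5, 2: 0.5, 3: 0.5})
        assert not any(act.values())

    def test_mask_excluded_never_active(self):
        mags = {1: 0.0, 2: 1.0, 3: 1.0}
        act = call_active(mags, mask_excluded=(3,))
        assert act[2] and not act[3]

    def test_too_few_granules_rejected(self):
        with pytest.raises(ValueError):
            call_active({1: 0.5})


class TestEndToEnd:
    def _recovery(self, noise_sd, seed):
        rng = np.random.default_rng(seed + 50)
        assign = responsive_assignment(rng, 20)
        scene = SceneSpec(seed=seed, motif_assignment=assign, noise_sd=noise_sd)
        movies, truth = generate_calcium_movies(scene)
        dffs = [preprocess(m)[0] for m in movies]
        gmap, resp = segment_and_quantify(dffs)
        act = resp.pivot(index="granule", columns="stimulus",
                         values="active").any(axis=1)
        matched = set()
        for ctr in truth["centers"]:
            g = gmap.labels[int(round(ctr[0])), int(round(ctr[1]))]
            if g > 0 and act.get(g, False) and g not in matched:
                matched.add(g)
        return len(matched) / scene.n_cells

    def test_planted_cells_recovered_as_active_granules(self):
        assert self._recovery(noise_sd=2.0, seed=0) >= 0.9

    def test_silent_stimulus_few_active(self):
        # solvent-like stimulus: no cell responds, so the magnitude
        # distribution is unimodal noise and the bimodality gate holds
        from locustal.synthetic import default_motif_templates

        rng = np.random.default_rng(1)
        assign = responsive_assignment(rng, 10)
        assign[:, 0] = 0  # first stimulus evokes nothing
        scene = SceneSpec(n_cells=10, seed=1, motif_assignment=assign,
                          noise_sd=2.0)
        lib = default_motif_templates(include_silent=True)
        movies, _ = generate_calcium_movies(scene, lib)
        dffs = [preprocess(m)[0] for m in movies]
        _, resp = segment_and_quantify(dffs)
        first = resp[resp.stimulus == scene.stimuli[0]]
        assert first["active"].mean() <= 0.10

    def test_responsive_vs_silent_cells(self):
        # 10 responsive and 10 silent planted cells: the responsive ones are
        # called active, the silent ones not
        from locustal.synthetic import default_motif_templates

        rng = np.random.default_rng(6)
        assign = responsive_assignment(rng, 20)
        assign[10:] = 0
        scene = SceneSpec(n_cells=20, seed=6, motif_assignment=assign,
                          noise_sd=2.0)
        lib = default_motif_templates(include_silent=True)
        movies, truth = generate_calcium_movies(scene, lib)
        dffs = [preprocess(m)[0] for m in movies]
        gmap, resp = segment_and_quantify(dffs)
        act = resp.pivot(index="granule", columns="stimulus",
                         values="active").any(axis=1)
        resp_active = silent_active = 0
        for i, ctr in enumerate(truth["centers"]):
            g = gmap.labels[int(round(ctr[0])), int(round(ctr[1]))]
            flag = bool(act.get(g, False))
            if i < 10:
                resp_active += flag
            else:
                silent_active += flag
        assert resp_active >= 9
        assert silent_active <= 1
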