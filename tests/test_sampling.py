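"""Sample selection: boundary scan, MNF, corner pixels, window sampling."""

import numpy as np
import pytest
from scipy.optimize import linprog

import svddmap as sm
from svddmap.sampling import OUTLIER, TARGET

from conftest import two_class_halfplane


def brute_force_boundary(labels, target_code):
    """Oracle: per-pixel 8-neighbour scan, border counts as non-target."""
    h, w = labels.shape
    out = []
    for r in range(h):
        for c in range(w):
            if labels[r, c] != target_code:
                continue
            edge = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or labels[rr, cc] != target_code:
                        edge = True
            if edge:
                out.append((r, c))
    return sorted(out)


class TestBoundaryPixels:
    def test_isolated_pixel(self):
        arr = np.ones((7, 7), dtype=int)
        arr[3, 3] = 0
        lab = sm.LabelRaster(arr, {0: "t", 1: "o"})
        got = sm.extract_boundary_pixels(lab, 0)
        assert [tuple(c) for c in got] == [(3, 3)]

    def test_solid_block_perimeter_only(self):
        arr = np.ones((9, 9), dtype=int)
        arr[3:6, 3:6] = 0
        lab = sm.LabelRaster(arr, {0: "t", 1: "o"})
        got = {tuple(c) for c in sm.extract_boundary_pixels(lab, 0)}
        block = {(r, c) for r in range(3, 6) for c in range(3, 6)}
        assert got == block - {(4, 4)}
        assert len(got) == 8

    def test_all_target_image_matches_bruteforce(self):
        arr = np.zeros((6, 8), dtype=int)
        lab = sm.LabelRaster(arr, {0: "t"})
        got = sorted(tuple(c) for c in sm.extract_boundary_pixels(lab, 0))
        assert got == brute_force_boundary(arr, 0)
        interior = {(r, c) for r in range(1, 5) for c in range(1, 7)}
        assert not interior & set(got)

    def test_random_labels_match_bruteforce(self, rng):
        arr = (rng.uniform(size=(15, 12)) < 0.5).astype(int)
        arr[0, 0] = 0
        lab = sm.LabelRaster(arr, {0: "t", 1: "o"})
        got = sorted(tuple(c) for c in sm.extract_boundary_pixels(lab, 0))
        assert got == brute_force_boundary(arr, 0)

    def test_absent_target_raises(self):
        lab = sm.LabelRaster(np.ones((3, 3), dtype=int), {1: "o"})
        with pytest.raises(ValueError, match="absent"):
            sm.extract_boundary_pixels(lab, 0)


class TestMNF:
    def _smooth_signal_scene(self, rng, p=4, h=60, w=60, noise_sd=None):
        """Row-wise smooth signal + iid pixel noise, so horizontal
        differences isolate the noise."""
        rows = rng.normal(size=(p, h, 1)) * np.linspace(1, 3, p)[:, None, None]
        signal = np.repeat(rows, w, axis=2)
        if noise_sd is None:
            noise_sd = np.full(p, 0.1)
        noise = rng.normal(size=(p, h, w)) * np.asarray(noise_sd)[:, None, None]
        return sm.MultibandRaster(signal + noise)

    def test_noise_whitening(self, rng):
        raster = self._smooth_signal_scene(rng)
        mnf = sm.mnf_transform(raster)
        white = mnf.transform.T @ mnf.noise_cov @ mnf.transform
        np.testing.assert_allclose(white, np.eye(raster.n_bands), atol=1e-6)

    def test_snr_ordering_nonincreasing(self, rng):
        mnf = sm.mnf_transform(self._smooth_signal_scene(rng))
        assert np.all(np.diff(mnf.eigenvalues) <= 1e-9)

    def test_white_isotropic_noise_matches_pca(self, rng):
        """With isotropic white noise the MNF axes equal PCA axes up to
        sign/scale: compare normalized loading vectors."""
        raster = self._smooth_signal_scene(rng)
        mnf = sm.mnf_transform(raster)
        X = raster.values.reshape(raster.n_bands, -1).T
        _, _, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        for k in range(2):  # leading, well-separated components
            w_mnf = mnf.transform[:, k] / np.linalg.norm(mnf.transform[:, k])
            w_pca = Vt[k]
            assert min(
                np.linalg.norm(w_mnf - w_pca), np.linalg.norm(w_mnf + w_pca)
            ) < 0.05

    def test_low_noise_band_dominates_first_component(self, rng):
        """p=2, independent bands, band 0 clean / band 1 noisy: MNF1 should
        track band 0's signal."""
        h, w = 50, 80
        sig0 = np.repeat(rng.normal(size=(h, 1)), w, axis=1)
        sig1 = np.repeat(rng.normal(size=(h, 1)), w, axis=1)
        band0 = sig0 + 0.01 * rng.normal(size=(h, w))
        band1 = sig1 + 2.0 * rng.normal(size=(h, w))
        raster = sm.MultibandRaster(np.stack([band0, band1]))
        mnf = sm.mnf_transform(raster)
        comp1 = mnf.components.values[0].ravel()
        r0 = abs(np.corrcoef(comp1, sig0.ravel())[0, 1])
        r1 = abs(np.corrcoef(comp1, sig1.ravel())[0, 1])
        assert r0 > 0.9 > r1

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sm.mnf_transform(sm.MultibandRaster(np.ones((3, 10, 10))))


def hull_vertices_lp(points):
    """Oracle: index i is a hull vertex iff p_i is not a convex combination
    of the other points (LP feasibility)."""
    n = len(points)
    verts = []
    for i in range(n):
        others = np.delete(points, i, axis=0)
        A_eq = np.vstack([others.T, np.ones(n - 1)])
        b_eq = np.append(points[i], 1.0)
        res = linprog(np.zeros(n - 1), A_eq=A_eq, b_eq=b_eq, bounds=(0, 1))
        if not res.success:
            verts.append(i)
    return verts


def _mnf_stub(points2d, coords):
    """Wrap given (MNF1, MNF2) points as an MNFResult on a fake grid."""
    n = len(points2d)
    comps = np.zeros((2, 1, n))
    comps[:, 0, :] = np.asarray(points2d).T
    return sm.MNFResult(
        components=sm.MultibandRaster(comps),
        eigenvalues=np.array([2.0, 1.0]),
        noise_cov=np.eye(2),
        transform=np.eye(2),
        mean=np.zeros(2),
    )


class TestCornerPixels:
    def test_square_corners(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        coords = np.array([[0, i] for i in range(4)])
        got = sm.select_corner_pixels(_mnf_stub(pts, coords), coords, 4)
        assert {tuple(c) for c in got} == {tuple(c) for c in coords}

    def test_center_point_never_selected(self):
        pts = np.array([[0, 0], [0, 2], [2, 0], [2, 2], [1, 1]], dtype=float)
        coords = np.array([[0, i] for i in range(5)])
        got = sm.select_corner_pixels(_mnf_stub(pts, coords), coords, 4)
        assert (0, 4) not in {tuple(c) for c in got}

    def test_peeling_matches_first_hull_inclusion(self, rng):
        pts = rng.uniform(size=(100, 2))
        coords = np.array([[0, i] for i in range(100)])
        got = sm.select_corner_pixels(_mnf_stub(pts, coords), coords, 60)
        assert len(got) == 60
        assert len({tuple(c) for c in got}) == 60
        first_hull = hull_vertices_lp(pts)
        chosen_idx = {c[1] for c in got}
        assert set(first_hull) <= chosen_idx

    def test_collinear_fallback(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        coords = np.array([[0, i] for i in range(5)])
        got = sm.select_corner_pixels(_mnf_stub(pts, coords), coords, 2)
        assert {tuple(c) for c in got} == {(0, 0), (0, 4)}

    def test_too_few_candidates(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        coords = np.array([[0, 0], [0, 1]])
        with pytest.raises(ValueError, match="candidates"):
            sm.select_corner_pixels(_mnf_stub(pts, coords), coords, 3)


class TestTrainingSet:
    def test_default_size_is_120(self, small_scene):
        spec, raster, truth = small_scene
        tr = sm.build_training_set(raster, truth.labels, spec.target_index, seed=0)
        assert len(tr) == 120
        assert tr.meta["n_mixed"] == 60 and tr.meta["n_corner"] == 60
        assert np.all(tr.tags == TARGET)

    def test_pure_corner_training(self, small_scene):
        spec, raster, truth = small_scene
        tr = sm.build_training_set(
            raster, truth.labels, spec.target_index, n_mixed=0, n_corner=40, seed=0
        )
        assert len(tr) == 40

    def test_mixed_samples_lie_on_seam(self, halfplane):
        spec, raster, truth = halfplane
        tr = sm.build_training_set(
            raster, truth.labels, 0, n_mixed=10, n_corner=10, seed=0
        )
        mixed = tr.coords[: tr.meta["n_mixed"]]
        seam = 20
        assert np.all(np.abs(mixed[:, 1] - seam) <= 1)

    def test_shortfall_raises(self, halfplane):
        spec, raster, truth = halfplane
        with pytest.raises(ValueError, match="boundary"):
            sm.build_training_set(
                raster, truth.labels, 0, n_mixed=10_000, n_corner=10, seed=0
            )

    def test_thirty_p_rule_warning(self, small_scene):
        spec, raster, truth = small_scene
        with pytest.warns(UserWarning, match="30p"):
            sm.build_training_set(
                raster, truth.labels, spec.target_index, n_mixed=20, n_corner=20, seed=0
            )


def window_union_oracle(train_coords, h, w, win):
    """Brute-force enumeration of the w x w window union minus training."""
    half = win // 2
    cells = set()
    for r, c in train_coords:
        for rr in range(r - half, r + half + 1):
            for cc in range(c - half, c + half + 1):
                if 0 <= rr < h and 0 <= cc < w:
                    cells.add((rr, cc))
    return cells - set(map(tuple, train_coords))


class TestValidationWindows:
    def _sampleset(self, coords, raster):
        coords = np.asarray(coords)
        return sm.SampleSet(
            coords, raster.spectra(coords), np.array([TARGET] * len(coords), dtype=object)
        )

    @pytest.mark.parametrize(
        "coords,expected",
        [([(5, 5)], 8), ([(0, 0)], 3), ([(5, 5), (5, 6)], 10)],
    )
    def test_window_union_counts(self, halfplane, coords, expected):
        spec, raster, truth = halfplane
        tr = self._sampleset(coords, raster)
        val = sm.build_validation_set(tr, raster, truth.labels, 0, w=3)
        assert len(val) == expected
        oracle = window_union_oracle(coords, raster.height, raster.width, 3)
        assert val.coord_set() == oracle

    def test_monotone_in_window_size(self, halfplane):
        spec, raster, truth = halfplane
        tr = sm.build_training_set(raster, truth.labels, 0, n_mixed=8, n_corner=8, seed=1)
        prev = None
        for w in (3, 5, 7):
            val = sm.build_validation_set(tr, raster, truth.labels, 0, w=w)
            assert len(val) <= len(tr) * (w**2 - 1)
            cur = val.coord_set()
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_never_contains_training_coordinates(self, halfplane):
        spec, raster, truth = halfplane
        tr = sm.build_training_set(raster, truth.labels, 0, n_mixed=10, n_corner=10, seed=2)
        val = sm.build_validation_set(tr, raster, truth.labels, 0, w=5)
        assert not val.coord_set() & tr.coord_set()

    def test_tags_follow_reference_labels(self, halfplane):
        spec, raster, truth = halfplane
        tr = self._sampleset([(5, 20)], raster)  # seam pixel: window spans both classes
        val = sm.build_validation_set(tr, raster, truth.labels, 0, w=3)
        for (r, c), tag in zip(val.coords, val.tags):
            assert tag == (TARGET if truth.labels.labels[r, c] == 0 else OUTLIER)
        assert val.n_target > 0 and val.n_outlier > 0

    def test_exclude_codes_drops_pixels(self, halfplane):
        spec, raster, truth = halfplane
        tr = self._sampleset([(5, 20)], raster)
        val = sm.build_validation_set(tr, raster, truth.labels, 0, w=3, exclude_codes=(1,))
        assert val.n_outlier == 0

    @pytest.mark.parametrize("w", [2, 4, 1, -3])
    def test_invalid_window_rejected(self, halfplane, w):
        spec, raster, truth = halfplane
        tr = self._sampleset([(5, 5)], raster)
        with pytest.raises(ValueError, match="window"):
            sm.build_validation_set(tr, raster, truth.labels, 0, w=w)


def test_informative_outliers_nearer_than_random(small_scene):
    """Window-based outliers sit closer to the target spectral mean than
    size-matched random outliers (averaged over seeds)."""
    spec, raster, truth = small_scene
    mu_t = spec.classes[spec.target_index].mean
    closer = 0
    for seed in range(10):
        tr = sm.build_training_set(raster, truth.labels, spec.target_index, seed=seed)
        win = sm.build_validation_set(tr, raster, truth.labels, spec.target_index, w=3)
        rand = sm.build_random_validation_set(
            win, raster, truth.labels, spec.target_index,
            exclude_coords=tr.coord_set(), seed=seed,
        )
        d_win = np.linalg.norm(win.spectra[~win.is_target] - mu_t, axis=1).mean()
        d_rand = np.linalg.norm(rand.spectra[~rand.is_target] - mu_t, axis=1).mean()
        closer += d_win < d_rand
    assert closer >= 9


def test_random_validation_is_size_matched(small_scene):
    spec, raster, truth = small_scene
    tr = sm.build_training_set(raster, truth.labels, spec.target_index, seed=3)
    win = sm.build_validation_set(tr, raster, truth.labels, spec.target_index, w=3)
    rand = sm.build_random_validation_set(
        win, raster, truth.labels, spec.target_index, seed=3
    )
    assert (rand.n_target, rand.n_outlier) == (win.n_target, win.n_outlier)


def test_sampleset_csv_roundtrip(tmp_path, halfplane):
    spec, raster, truth = halfplane
    tr = sm.build_training_set(raster, truth.labels, 0, n_mixed=10, n_corner=10, seed=0)
    path = tr.to_csv(tmp_path / "train.csv")
    back = sm.SampleSet.from_csv(path)
    np.testing.assert_array_equal(back.coords, tr.coords)
    np.testing.assert_allclose(back.spectra, tr.spectra)
    assert list(back.tags) == list(tr.tags)
    assert back.provenance == "training"


def test_sampleset_invariants():
    with pytest.raises(ValueError, match="duplicate"):
        sm.SampleSet(
            np.array([[0, 0], [0, 0]]),
            np.zeros((2, 3)),
            np.array([TARGET, TARGET], dtype=object),
        )
    with pytest.raises(ValueError, match="target"):
        sm.SampleSet(
            np.array([[0, 0]]), np.zeros((1, 3)),
            np.array([OUTLIER], dtype=object), provenance="training",
        )
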