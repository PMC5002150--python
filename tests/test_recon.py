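import numpy as np
import pytest

from petiq.listmode import FractionSchedule, make_ensembles
from petiq.phantom import EventStream
from petiq.recon import (
    ReconGeometry,
    Sinogram,
    bin_image,
    forward_project,
    osem_reconstruct,
    projection_matrix,
    reconstruct_ensembles,
    stream_to_sinogram,
    suv_calibration,
)

GEOM = ReconGeometry(n_pixels=48, n_angles=63, pixel_size=4.0)


def image_stream(indices, n_random=0):
    idx = np.asarray(indices, dtype=np.int64)
    is_random = np.zeros(idx.size + n_random, bool)
    is_random[idx.size:] = True
    return EventStream(bin_index=np.concatenate([idx, np.zeros(n_random, np.int64)]),
                       is_random=is_random)


class TestBinImage:
    def test_empty_stream_gives_zero_image(self):
        img = bin_image(image_stream([]), (4, 4, 4), calibration=1.0)
        assert np.all(img.data == 0)

    def test_counts_times_calibration(self):
        img = bin_image(image_stream([5, 5, 5]), (4, 4, 4), calibration=2.0)
        assert img.data.ravel()[5] == 6.0
        assert img.data.sum() == 6.0

    def test_linearity_in_stream(self, rng):
        a = image_stream(rng.integers(0, 64, 500))
        b = image_stream(rng.integers(0, 64, 300))
        ab = image_stream(np.concatenate([a.bin_index, b.bin_index]))
        grid = (4, 4, 4)
        lhs = bin_image(ab, grid, 1.5).data
        rhs = bin_image(a, grid, 1.5).data + bin_image(b, grid, 1.5).data
        assert np.array_equal(lhs, rhs)

    def test_randoms_excluded(self):
        img = bin_image(image_stream([1, 1], n_random=5), (2, 2, 2), 1.0)
        assert img.data.sum() == 2.0

    def test_out_of_grid_index_reported(self):
        with pytest.raises(IndexError, match="99"):
            bin_image(image_stream([99]), (2, 2, 2), 1.0)

    def test_calibration_recovers_liver_suv(self, small_phantom, small_stream):
        spec = small_phantom.spec
        cal = suv_calibration(small_phantom.suv_map.sum(), spec.total_true_counts)
        img = bin_image(small_stream, spec.grid_shape, cal)
        liver_mean = img.data[small_phantom.label_map == 2].mean()
        assert liver_mean == pytest.approx(spec.liver_suv, rel=0.01)


class TestForwardProject:
    def test_zero_slice_zero_sinogram(self):
        sino = forward_project(np.zeros((48, 48)), GEOM)
        assert np.all(sino.counts == 0)

    def test_adjoint_consistency(self, rng):
        P = projection_matrix(GEOM)
        x = rng.random(48 * 48)
        y = rng.random(P.shape[0])
        lhs = (P @ x) @ y
        rhs = x @ (P.T @ y)
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_single_hot_pixel_one_dominant_bin_per_angle(self):
        img = np.zeros((48, 48))
        img[30, 17] = 1.0
        sino = forward_project(img, GEOM).counts
        for row in sino:
            order = np.argsort(row)[::-1]
            # mass split between at most two adjacent bins
            assert row[order[:2]].sum() == pytest.approx(row.sum())
            assert abs(order[0] - order[1]) <= 1 or row[order[1]] == 0

    def test_uniform_disk_matches_chord_length(self):
        c = (np.arange(48) - 23.5) * 4.0
        X, Y = np.meshgrid(c, c, indexing="ij")
        r = 60.0
        disk = ((X ** 2 + Y ** 2) <= r ** 2).astype(float)
        sino = forward_project(disk, GEOM).counts
        chord = np.where(np.abs(c) < r, 2 * np.sqrt(np.maximum(r ** 2 - c ** 2, 0)), 0.0)
        sel = np.abs(c) < 0.8 * r
        rms = np.sqrt(np.mean((sino[:, sel] - chord[sel]) ** 2))
        assert rms / chord.max() < 0.02

    def test_non_square_slice_rejected(self):
        with pytest.raises(ValueError):
            forward_project(np.zeros((48, 32)), GEOM)


class TestOsemReconstruct:
    def _disk(self):
        c = (np.arange(48) - 23.5) * 4.0
        X, Y = np.meshgrid(c, c, indexing="ij")
        return ((X ** 2 + Y ** 2) <= 60.0 ** 2).astype(float), X, Y

    def test_high_count_disk_recovery(self, rng):
        disk, X, Y = self._disk()
        expected = forward_project(disk, GEOM).counts
        counts = rng.poisson(expected * (1e7 / expected.sum())).astype(float)
        img = osem_reconstruct(Sinogram(counts, GEOM), n_iter=3, n_subsets=21,
                               post_filter_fwhm=5.0)
        inner = (X ** 2 + Y ** 2) <= 42.0 ** 2
        cal = disk[inner].mean() / img.data[inner].mean()
        assert np.mean(np.abs(img.data[inner] * cal - disk[inner])) < 0.05

    def test_zero_iterations_returns_uniform(self):
        sino = Sinogram(np.ones((63, 48)), GEOM)
        img = osem_reconstruct(sino, n_iter=0, post_filter_fwhm=0.0)
        assert np.allclose(img.data, img.data.ravel()[0])

    def test_positivity(self, rng):
        counts = rng.poisson(2.0, size=(63, 48)).astype(float)
        img = osem_reconstruct(Sinogram(counts, GEOM), psf_fwhm=4.0)
        assert img.data.min() >= 0

    def test_empty_sinogram_zero_image_with_warning(self):
        with pytest.warns(UserWarning):
            img = osem_reconstruct(Sinogram(np.zeros((63, 48)), GEOM))
        assert np.all(img.data == 0)
        assert img.provenance.get("empty")

    def test_post_filter_reduces_ensemble_noise(self, rng):
        disk, _, _ = self._disk()
        expected = forward_project(disk, GEOM).counts
        lam = expected * (2e4 / expected.sum())
        sharp, smooth = [], []
        for _ in range(6):
            counts = rng.poisson(lam).astype(float)
            sharp.append(osem_reconstruct(Sinogram(counts, GEOM), post_filter_fwhm=0.0).data)
            smooth.append(osem_reconstruct(Sinogram(counts, GEOM), post_filter_fwhm=5.0).data)
        sd_sharp = np.stack(sharp).std(axis=0, ddof=1).mean()
        sd_smooth = np.stack(smooth).std(axis=0, ddof=1).mean()
        assert sd_smooth < sd_sharp


class TestStreamToSinogram:
    def test_total_counts_preserved(self, rng):
        stream = image_stream(rng.integers(0, 48 * 48, 5000))
        sino = stream_to_sinogram(stream, GEOM, seed=1)
        assert sino.counts.sum() == 5000


class TestReconstructEnsembles:
    def test_counts_and_reference_shapes(self, small_phantom, small_stream):
        schedule = FractionSchedule((0.5, 0.25), n_realizations=3)
        specs = make_ensembles(small_stream, schedule, master_seed=2)
        ensembles = reconstruct_ensembles(small_stream, specs, small_phantom, backend="bin")
        assert len(ensembles) == 2
        for e in ensembles:
            assert e.realizations.shape[0] == 3
            assert e.reference_full.shape == small_phantom.suv_map.shape

    def test_fraction_one_equals_reference(self, small_phantom, small_stream):
        schedule = FractionSchedule((1.0,), n_realizations=2)
        specs = make_ensembles(small_stream, schedule, master_seed=2)
        (ens,) = reconstruct_ensembles(small_stream, specs, small_phantom, backend="bin")
        assert np.array_equal(ens.realizations[0], ens.reference_full)

    def test_realizations_differ(self, small_phantom, small_stream):
        schedule = FractionSchedule((0.5,), n_realizations=2)
        specs = make_ensembles(small_stream, schedule, master_seed=2)
        (ens,) = reconstruct_ensembles(small_stream, specs, small_phantom, backend="bin")
        assert not np.array_equal(ens.realizations[0], ens.realizations[1])
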