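import dataclasses
import math

import numpy as np
import pytest

from petiq import metrics
from petiq.listmode import FractionSchedule, make_ensembles
from petiq.metrics import bias, cnr, cov, ensemble_stats, ste, voi_stats
from petiq.phantom import build_phantom, generate_events
from petiq.recon import reconstruct_ensembles


class TestEnsembleStats:
    def test_identical_realizations_zero_sd(self):
        img = np.ones((4, 4))
        mean, sd = ensemble_stats([img, img, img])
        assert np.all(sd == 0) and np.all(mean == 1)

    def test_two_point_hand_value(self):
        mean, sd = ensemble_stats([np.zeros((2, 2)), np.full((2, 2), 2.0)])
        assert np.all(mean == 1.0)
        assert np.allclose(sd, np.sqrt(2.0))  # sample SD with divisor R-1

    def test_unit_variance_noise_recovered(self, rng):
        stack = rng.normal(0.0, 1.0, size=(10, 40, 40))
        _, sd = ensemble_stats(stack)
        assert sd.mean() == pytest.approx(1.0, rel=0.1)

    def test_single_realization_rejected(self):
        with pytest.raises(ValueError):
            ensemble_stats([np.ones((2, 2))])


class TestVOIStats:
    def test_hand_example(self):
        img = np.array([1.0, 2.0, 3.0, 99.0])
        mask = np.array([True, True, True, False])
        st_ = voi_stats(img, mask)
        assert st_.mean == pytest.approx(2.0)
        assert st_.sd == pytest.approx(np.sqrt(2.0 / 3.0))  # population divisor
        assert st_.snr == pytest.approx(2.0 / np.sqrt(2.0 / 3.0))
        assert st_.suvmax == 3.0

    def test_constant_voi_flagged(self):
        st_ = voi_stats(np.full(5, 2.0), np.ones(5, bool))
        assert st_.degenerate and math.isinf(st_.snr) and st_.sd == 0.0

    def test_single_voxel(self):
        st_ = voi_stats(np.array([0.0, 7.0]), np.array([False, True]))
        assert st_.mean == 7.0 and st_.sd == 0.0

    def test_permutation_invariance(self, rng):
        img = rng.random(50)
        mask = rng.random(50) < 0.5
        perm = rng.permutation(50)
        a = voi_stats(img, mask)
        b = voi_stats(img[perm], mask[perm])
        assert a.mean == pytest.approx(b.mean) and a.sd == pytest.approx(b.sd)


class TestCNR:
    def test_direct_formula(self):
        img = np.array([2.0, 2.0, 1.5, 0.5, 1.0, 1.0])
        lesion = np.array([True, True, False, False, False, False])
        shell = np.array([False, False, True, True, True, True])
        expected = (2.0 - 1.0) / np.array([1.5, 0.5, 1.0, 1.0]).std()
        assert cnr(img, lesion, shell) == pytest.approx(expected)

    def test_zero_contrast(self):
        img = np.array([1.0, 1.0, 0.5, 1.5])
        assert cnr(img, np.array([True, True, False, False]),
                   np.array([False, False, True, True])) == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        img = rng.random(30) + 0.5
        lesion = np.zeros(30, bool)
        lesion[:5] = True
        shell = np.zeros(30, bool)
        shell[10:] = True
        assert cnr(2.0 * img, lesion, shell) == pytest.approx(cnr(img, lesion, shell))

    def test_overlap_rejected(self):
        m = np.ones(4, bool)
        with pytest.raises(ValueError):
            cnr(np.ones(4), m, m)


class TestBiasCovSte:
    @pytest.mark.parametrize("frac,full,expected", [(1.0, 1.0, 0.0), (0.9, 1.0, -10.0), (1.2, 1.0, 20.0)])
    def test_bias_formula(self, frac, full, expected):
        assert bias(frac, full) == pytest.approx(expected)

    def test_bias_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            bias(1.0, 0.0)

    def test_cov_direct(self):
        mean_img = np.full(10, 2.0)
        sd_img = np.full(10, 0.2)
        mask = np.ones(10, bool)
        assert cov(mean_img, sd_img, mask) == pytest.approx(10.0)
        assert cov(mean_img, np.zeros(10), mask) == 0.0

    def test_cov_as_printed_is_reciprocal(self):
        mean_img, sd_img = np.full(5, 2.0), np.full(5, 0.2)
        mask = np.ones(5, bool)
        assert cov(mean_img, sd_img, mask, as_printed=True) == pytest.approx(1000.0)

    def test_cov_poisson_scaling(self, small_phantom, small_stream):
        schedule = FractionSchedule((0.2, 0.05), n_realizations=10)
        specs = make_ensembles(small_stream, schedule, master_seed=3)
        ens = reconstruct_ensembles(small_stream, specs, small_phantom, backend="bin")
        liver = small_phantom.label_map == 2
        covs = [cov(e.mean_image, e.sd_image, liver) for e in ens]
        # quadrupling counts should halve the COV
        assert covs[1] / covs[0] == pytest.approx(2.0, rel=0.1)

    @pytest.mark.parametrize("values,expected", [([1.0, 2.0, 3.0], 50.0), ([2.0, 4.0, 6.0], 50.0),
                                                 ([5.0, 5.0, 5.0], 0.0)])
    def test_ste_values(self, values, expected):
        assert ste(values) == pytest.approx(expected)

    def test_ste_needs_two_values(self):
        with pytest.raises(ValueError):
            ste([1.0])


class TestThresholdSensitivity:
    def _peaked_ensemble(self, small_spec):
        # bright lesion so even the 20 % threshold stays above lung uptake
        from petiq.phantom import LesionSpec
        spec = dataclasses.replace(small_spec, total_true_counts=2_000_000,
                                   lesions=(LesionSpec((14.0, 24.0, 16.0), 4.0, 8.0),))
        phantom = build_phantom(spec)
        stream = generate_events(phantom, seed=50)
        specs = make_ensembles(stream, FractionSchedule((0.5,), 5), master_seed=50)
        (ens,) = reconstruct_ensembles(stream, specs, phantom, backend="bin")
        return phantom, ens

    def test_higher_threshold_higher_cnr_on_peaked_lesion(self, small_spec):
        phantom, ens = self._peaked_ensemble(small_spec)
        # smooth the reference so the lesion profile decreases radially
        from scipy import ndimage
        ens.reference_full = ndimage.gaussian_filter(ens.reference_full, 1.2)
        ens.mean_image = ndimage.gaussian_filter(ens.mean_image, 1.2)
        ens.realizations = np.stack([ndimage.gaussian_filter(r, 1.2) for r in ens.realizations])
        seed_voxel = tuple(int(round(c)) for c in phantom.spec.lesions[0].center)
        table = metrics.threshold_sensitivity(ens, seed_voxel, phantom.spec.voxel_size)
        cnr_by_pct = dict(zip(table["threshold_pct"], table["cnr"]))
        assert cnr_by_pct[80.0] > cnr_by_pct[20.0]

    def test_identical_masks_give_identical_cnr(self, small_spec):
        phantom, ens = self._peaked_ensemble(small_spec)
        # constant lesion: every threshold selects the same voxels
        lesion_mask = phantom.label_map == 3
        ens.reference_full = np.where(lesion_mask, 5.0, 0.1)
        seed_voxel = tuple(int(round(c)) for c in phantom.spec.lesions[0].center)
        table = metrics.threshold_sensitivity(ens, seed_voxel, phantom.spec.voxel_size)
        assert table["n_voxels"].nunique() == 1
        assert table["cnr"].nunique() == 1


class TestSnr2Linearity:
    def test_liver_snr2_proportional_to_counts_binning(self, small_spec):
        # small retention fractions: realizations thinned from one parent are
        # effectively independent and the Poisson SNR^2 ~ N law is clean
        spec = dataclasses.replace(small_spec, total_true_counts=4_000_000)
        phantom = build_phantom(spec)
        stream = generate_events(phantom, seed=88)
        schedule = FractionSchedule((0.02, 0.01, 0.005, 0.0025, 0.00125, 0.000625),
                                    n_realizations=10)
        specs = make_ensembles(stream, schedule, master_seed=13)
        ens = reconstruct_ensembles(stream, specs, phantom, backend="bin")
        liver = phantom.label_map == 2
        counts = np.array([e.mean_counts for e in ens])
        snr2 = np.array([voi_stats(e.mean_image, liver).snr ** 2 for e in ens])
        r = np.corrcoef(counts, snr2)[0, 1]
        assert r ** 2 >= 0.99
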