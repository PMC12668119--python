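"""Derived maps: mixture tensors, DTI/DKI scalars, NODDI scalars, peaks."""

import numpy as np
import pytest

from fibermatch.compartments import Diffusivities
from fibermatch.dictionary import MicrostructureConfig
from fibermatch.maps import (
    CompartmentTensorSet,
    apparent_kurtosis,
    compute_voxel_maps,
    dti_scalars,
    kurtosis_scalars,
    kurtosis_tensor,
    mixture_tensors,
    noddi_style_maps,
    overall_tensor,
    peaks_and_segmentation,
)
from fibermatch.matching import FitConfig


def _config(n_fibers, axes, weights, odis, f_wm=1.0, f_gm=0.0, f_fw=0.0,
            intra=0.75, d_par=2.5e-3, d_perp=0.5e-3):
    return MicrostructureConfig(
        n_fibers=n_fibers, f_wm=f_wm, f_gm=f_gm, f_fw=f_fw,
        fiber_axes=np.asarray(axes, float).reshape(n_fibers, 3),
        fiber_weights=np.asarray(weights, float).reshape(n_fibers),
        odis=np.asarray(odis, float).reshape(n_fibers),
        intra_fraction=intra,
        diffusivities=Diffusivities(d_par=d_par, d_perp_ex=d_perp),
    )


def _fw_config():
    return MicrostructureConfig(
        n_fibers=0, f_wm=0.0, f_gm=0.0, f_fw=1.0,
        fiber_axes=np.zeros((0, 3)), fiber_weights=np.zeros(0), odis=np.zeros(0),
        intra_fraction=0.75, diffusivities=Diffusivities(2.5e-3, 0.5e-3),
    )


def _iso_mix():
    """50/50 mixture of isotropic tensors at 1e-3 and 3e-3 mm^2/s."""
    return CompartmentTensorSet(
        weights=np.array([0.5, 0.5]),
        tensors=np.stack([1e-3 * np.eye(3), 3e-3 * np.eye(3)]),
    )


class TestMixtureTensors:
    def test_pure_free_water_single_ball(self, grid724):
        tset = mixture_tensors(_fw_config(), grid724)
        D, vals, _ = overall_tensor(tset)
        assert np.allclose(D, 3e-3 * np.eye(3), atol=1e-15)
        assert tset.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_weights_sum_to_one_for_fiber_voxels(self, grid724):
        c = _config(1, [[0, 0, 1.0]], [1.0], [0.1])
        tset = mixture_tensors(c, grid724)
        assert tset.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(tset.weights >= 0)

    def test_coherent_stick_dominant_tensor(self, grid724):
        """odi -> 0 with full intra fraction approaches d_par * n n^T."""
        mu = grid724.vertices[42]
        c = _config(1, [mu], [1.0], [1e-5], intra=0.9999999999)
        tset = mixture_tensors(c, grid724)
        D, vals, vecs = overall_tensor(tset)
        assert np.allclose(D, 2.5e-3 * np.outer(mu, mu), atol=1e-6)


class TestDtiScalars:
    def test_free_water_md_and_fa(self, grid724):
        tset = mixture_tensors(_fw_config(), grid724)
        _, vals, _ = overall_tensor(tset)
        s = dti_scalars(vals)
        assert s["md"] == pytest.approx(3e-3, abs=1e-12)
        assert s["fa"] == pytest.approx(0.0, abs=1e-9)

    def test_rank_one_tensor_is_fully_anisotropic(self):
        s = dti_scalars(np.array([2.5e-3, 0.0, 0.0]))
        assert s["fa"] == pytest.approx(1.0)
        assert s["ad"] == pytest.approx(2.5e-3)
        assert s["rd"] == 0.0

    def test_two_ball_average(self):
        _, vals, _ = overall_tensor(_iso_mix())
        s = dti_scalars(vals)
        assert s["md"] == pytest.approx(2e-3, abs=1e-15)
        assert s["fa"] == pytest.approx(0.0, abs=1e-12)

    def test_dispersion_lowers_fa_monotonically(self, grid724):
        """More orientation dispersion means a rounder mean tensor."""
        from fibermatch.dictionary import ODI_LEVELS

        mu = grid724.vertices[7]
        fas = []
        for odi in ODI_LEVELS:
            tset = mixture_tensors(_config(1, [mu], [1.0], [odi]), grid724)
            _, vals, _ = overall_tensor(tset)
            fas.append(dti_scalars(vals)["fa"])
        assert all(a > b for a, b in zip(fas, fas[1:]))


class TestKurtosis:
    def test_single_compartment_has_zero_kurtosis(self, grid724):
        tset = mixture_tensors(_fw_config(), grid724)
        D, _, _ = overall_tensor(tset)
        W = kurtosis_tensor(tset, D)
        assert np.allclose(W, 0.0, atol=1e-12)
        s = kurtosis_scalars(W, D, grid724)
        assert s["mk"] == pytest.approx(0.0, abs=1e-9)
        assert s["ak"] == pytest.approx(0.0, abs=1e-9)
        assert s["rk"] == pytest.approx(0.0, abs=1e-9)

    def test_two_ball_mixture_has_direction_free_kurtosis(self, grid724, rng):
        """K(g) = 3 Var / mean^2 = 0.75 for the 1e-3 / 3e-3 half mixture."""
        tset = _iso_mix()
        D, _, _ = overall_tensor(tset)
        W = kurtosis_tensor(tset, D)
        for _ in range(10):
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            assert apparent_kurtosis(W, D, g[None]) == pytest.approx(0.75, abs=1e-12)
        s = kurtosis_scalars(W, D, grid724)
        assert s["mk"] == pytest.approx(0.75, abs=1e-12)
        assert s["kfa"] == pytest.approx(0.0, abs=1e-9)

    def test_kfa_zero_for_any_isotropic_mixture(self, grid724, rng):
        ds = rng.uniform(0.5e-3, 3e-3, size=5)
        w = rng.dirichlet(np.ones(5))
        tset = CompartmentTensorSet(w, np.stack([d * np.eye(3) for d in ds]))
        D, _, _ = overall_tensor(tset)
        s = kurtosis_scalars(kurtosis_tensor(tset, D), D, grid724)
        assert s["kfa"] == pytest.approx(0.0, abs=1e-9)

    def test_crossing_radial_kurtosis_finite_nonnegative(self, grid724):
        axes = [grid724.vertices[10], grid724.vertices[300]]
        c = _config(2, axes, [0.5, 0.5], [0.2, 0.2], f_wm=0.8, f_fw=0.2, f_gm=0.0)
        tset = mixture_tensors(c, grid724)
        D, _, _ = overall_tensor(tset)
        s = kurtosis_scalars(kurtosis_tensor(tset, D), D, grid724)
        assert np.isfinite(s["rk"]) and s["rk"] >= 0

    def test_zero_md_rejected(self):
        tset = CompartmentTensorSet(np.array([1.0]), np.zeros((1, 3, 3)))
        with pytest.raises(ValueError):
            kurtosis_tensor(tset)


class TestLowBConsistency:
    def test_signal_matches_mean_tensor_to_second_order(self, grid724, gtab151):
        """At low b the mixture signal deviates from exp(-b g^T D g) by at
        most the second-cumulant term (b^2/2) Var_c(D(g))."""
        from fibermatch.dictionary import synthesize_signal
        from fibermatch.acquisition import GradientTable

        c = _config(2, [grid724.vertices[10], grid724.vertices[300]],
                    [0.6, 0.4], [0.1, 0.2], f_wm=0.7, f_gm=0.1, f_fw=0.2)
        tset = mixture_tensors(c, grid724)
        D, _, _ = overall_tensor(tset)
        dirs = gtab151.bvecs[1:]
        dg = np.einsum("ij,ni,nj->n", D, dirs, dirs)
        second = np.einsum("c,cij,ckl->ijkl", tset.weights, tset.tensors, tset.tensors)
        var = np.einsum("ijkl,ni,nj,nk,nl->n", second, dirs, dirs, dirs, dirs) - dg**2
        for b in (10.0, 50.0, 100.0):
            gt = GradientTable(np.full(len(dirs), b), dirs, b0_threshold=1e-9)
            s = synthesize_signal(c, gt, grid724)
            gauss = np.exp(-b * dg)
            bound = 1.5 * (b**2 / 2.0) * var.max() + 1e-9
            assert np.abs(s - gauss).max() <= bound


class TestNoddiStyle:
    def test_fiber_free_voxel_is_fully_dispersed(self):
        m = noddi_style_maps(_fw_config())
        assert m["odi"] == 1.0 and m["ndi"] == 0.0 and m["fw"] == 1.0

    def test_ndi_equals_intra_fraction(self, grid724):
        c = _config(2, [grid724.vertices[0], grid724.vertices[500]],
                    [0.5, 0.5], [0.1, 0.2], f_wm=0.6, f_gm=0.1, f_fw=0.3, intra=0.75)
        m = noddi_style_maps(c)
        assert m["ndi"] == pytest.approx(0.75, abs=1e-12)
        assert m["fw"] == pytest.approx(0.3)

    def test_voxel_odi_is_weight_averaged(self, grid724):
        c = _config(2, [grid724.vertices[0], grid724.vertices[500]],
                    [0.8, 0.2], [0.1, 0.3])
        assert noddi_style_maps(c)["odi"] == pytest.approx(0.8 * 0.1 + 0.2 * 0.3)


class TestPeaksAndSegmentation:
    def _mixed(self, f_wm):
        rest = 1.0 - f_wm
        return _config(1, [[0.0, 0.0, 1.0]], [1.0], [0.1],
                       f_wm=f_wm, f_gm=rest / 2, f_fw=rest / 2)

    def test_sub_threshold_wm_suppresses_peaks(self):
        peaks, w, seg = peaks_and_segmentation(self._mixed(0.4), FitConfig(wm_threshold=0.5))
        assert np.all(peaks == 0) and np.all(w == 0)

    def test_lower_threshold_reports_peaks(self):
        peaks, w, _ = peaks_and_segmentation(self._mixed(0.4), FitConfig(wm_threshold=0.3))
        assert np.allclose(peaks[0], [0, 0, 1.0])
        assert w[0] == 1.0

    def test_segmentation_sums_to_one(self):
        _, _, seg = peaks_and_segmentation(self._mixed(0.4), FitConfig())
        assert sum(seg) == pytest.approx(1.0, abs=1e-12)

    def test_peaks_ordered_by_weight(self, grid724):
        c = _config(2, [grid724.vertices[0], grid724.vertices[500]],
                    [0.3, 0.7], [0.1, 0.1])
        peaks, w, _ = peaks_and_segmentation(c, FitConfig())
        assert np.allclose(peaks[0], grid724.vertices[500])
        assert w[0] == pytest.approx(0.7)


class TestVoxelMaps:
    def test_all_scalars_in_valid_ranges(self, grid724, rng):
        from fibermatch.dictionary import sample_config

        for _ in range(5):
            c = sample_config(rng, "invivo", grid724)
            vm = compute_voxel_maps(c, grid724)
            assert 0 <= vm.fa <= 1 and 0 <= vm.kfa <= 1
            assert vm.md >= 0 and vm.ad >= 0 and vm.rd >= 0
            assert 0 <= vm.ndi <= 1 and 0 <= vm.odi <= 1 and 0 <= vm.fw <= 1
            assert vm.f_wm + vm.f_gm + vm.f_csf == pytest.approx(1.0, abs=1e-9)
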