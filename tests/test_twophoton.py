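"""Two-photon amyloid quantification: preprocessing, CAA, plaques."""

import numpy as np
import pytest

from mesovasc import synth, twophoton
from mesovasc.types import PathologyResult, TwoPhotonVolume


def _vol(methoxy, sr101=None):
    if sr101 is None:
        sr101 = np.zeros_like(np.asarray(methoxy, dtype=float))
    return TwoPhotonVolume(methoxy, sr101)


def test_in_plane_resolution_from_fov():
    assert round(twophoton.in_plane_resolution(1130.0, 512), 3) == 2.207
    with pytest.raises(ValueError):
        twophoton.in_plane_resolution(0, 512)


class TestPreprocess:
    def test_constant_volume_unchanged(self):
        vol = _vol(np.full((8, 30, 30), 4.2))
        out = twophoton.preprocess_volume(vol)
        np.testing.assert_allclose(out.methoxy, 4.2, rtol=1e-9)

    def test_depth_decay_equalised_across_bins(self):
        Z = 8
        decay = 0.5 ** (np.arange(Z) // 2)  # halves every 2-slice bin
        vol = _vol(np.ones((Z, 40, 40)) * decay[:, None, None])
        out = twophoton.preprocess_volume(vol, n_depth_bins=4)
        bin_means = [out.methoxy[2 * b : 2 * b + 2].mean() for b in range(4)]
        for m in bin_means[1:]:
            assert m == pytest.approx(bin_means[0], rel=0.01)

    def test_median_rejects_salt_and_pepper(self):
        vol_arr = np.full((4, 50, 50), 1.0)
        vol_arr[2, 3::7, 4::7] = 10.0  # strictly isolated impulses
        out = twophoton.preprocess_volume(_vol(vol_arr), flat_sigma=1e6).methoxy
        # every impulse removed: the slice is flat apart from tiny rescaling
        assert np.abs(out[2] - out[2].mean()).max() < 0.05

    def test_single_slice_skips_depth_correction(self, caplog):
        with caplog.at_level("WARNING"):
            out = twophoton.preprocess_volume(_vol(np.ones((1, 20, 20))))
        assert "depth correction skipped" in caplog.text
        assert out.methoxy.shape == (1, 20, 20)


class TestCAACoverage:
    def _outline(self, shape=(30, 30)):
        lab = np.zeros(shape, dtype=int)
        lab[5:25, 5:25] = 1
        return lab

    def test_uniform_vessel_gives_zero_coverage(self):
        vol = _vol(np.full((3, 30, 30), 2.0))
        res = twophoton.caa_coverage(vol, self._outline())
        assert res.coverage == 0.0  # strict threshold on zero-SD intensities

    def test_planted_bright_fraction_recovered(self, rng):
        arr = np.full((2, 30, 30), 1.0) + rng.normal(0, 0.02, (2, 30, 30))
        lab = self._outline()
        sel = np.argwhere(lab == 1)
        bright = sel[rng.permutation(len(sel))[: int(0.3 * len(sel))]]
        arr[:, bright[:, 0], bright[:, 1]] = 5.0  # ~ mu + 4 sigma of the rest
        res = twophoton.caa_coverage(_vol(arr), lab)
        assert res.coverage == pytest.approx(30.0, abs=2.0)

    def test_two_vessels_pool_by_pixel(self, rng):
        # the mean + 1.5 SD rule can only flag minority-bright fractions
        # (above ~36% the threshold exceeds the bright level), so the pooled
        # arithmetic is checked with 10% and 25% vessels -> 17.5% combined
        arr = np.full((1, 20, 40), 1.0) + rng.normal(0, 0.01, (1, 20, 40))
        lab = np.zeros((20, 40), int)
        lab[5:15, 2:12] = 1
        lab[5:15, 22:32] = 2
        v1 = np.argwhere(lab == 1)
        v2 = np.argwhere(lab == 2)
        arr[:, v1[:10, 0], v1[:10, 1]] = 6.0  # 10% of 100 px
        arr[:, v2[:25, 0], v2[:25, 1]] = 6.0  # 25% of 100 px
        res = twophoton.caa_coverage(_vol(arr), lab)
        assert res.coverage == pytest.approx(17.5, abs=1.0)
        assert res.per_vessel[1] == pytest.approx(10.0, abs=1.0)
        assert res.per_vessel[2] == pytest.approx(25.0, abs=1.0)

    def test_gain_invariance(self, rng):
        arr = np.full((2, 30, 30), 1.0) + rng.normal(0, 0.1, (2, 30, 30))
        lab = self._outline()
        r1 = twophoton.caa_coverage(_vol(arr), lab)
        r2 = twophoton.caa_coverage(_vol(arr * 11.0), lab)
        assert r1.coverage == r2.coverage

    def test_no_outlines_rejected(self):
        with pytest.raises(ValueError):
            twophoton.caa_coverage(_vol(np.ones((2, 10, 10))), np.zeros((10, 10), int))


class TestPlaqueVolume:
    def test_empty_volume(self):
        vol = _vol(np.zeros((5, 20, 20)))
        assert twophoton.plaque_volume(vol) == (0.0, 0)

    def test_constructed_cube_counted_exactly(self):
        arr = np.full((10, 20, 20), 0.1)
        arr[3:6, 5:8, 5:8] = 1.0  # 27-voxel cube
        vol = _vol(arr)
        volume, n = twophoton.plaque_volume(vol)
        assert n == 1
        assert volume == pytest.approx(27 * vol.voxel_volume)

    def test_15_voxel_blob_rejected_16_kept(self):
        arr = np.full((10, 20, 20), 0.1)
        arr[2, 2:7, 2:5] = 1.0  # 5x3 = 15 voxels, strictly-greater rule
        assert twophoton.plaque_volume(_vol(arr)) == (0.0, 0)
        arr[3, 2, 2] = 1.0  # 16th voxel, 26-connected
        volume, n = twophoton.plaque_volume(_vol(arr))
        assert n == 1
        assert volume == pytest.approx(16 * _vol(arr).voxel_volume)

    def test_connectivity_flag(self):
        arr = np.full((6, 12, 12), 0.0)
        arr[1, 2:6, 2:6] = 1.0  # 16 voxels
        arr[2, 6, 6] = 1.0  # diagonal neighbour of the block corner
        arr[2:5, 7:10, 7:10] = 1.0  # separate 27-voxel cube... touching? no
        v26, n26 = twophoton.plaque_volume(_vol(arr), connectivity=26)
        v6, n6 = twophoton.plaque_volume(_vol(arr), connectivity=6)
        assert n26 <= n6 or v26 >= v6  # merging can only join components

    def test_caa_mask_extruded_and_removed(self):
        arr = np.full((6, 20, 20), 0.1)
        arr[:, 3:7, 3:7] = 5.0  # bright CAA column, 16 px x 6 z = 96 voxels
        caa = np.zeros((20, 20), bool)
        caa[3:7, 3:7] = True
        volume, n = twophoton.plaque_volume(_vol(arr), caa_mask=caa)
        assert (volume, n) == (0.0, 0)

    def test_threshold_monotonicity(self, twophoton_volume):
        vol, outlines, _ = twophoton_volume
        caa = twophoton.caa_coverage(vol, outlines)
        vols = [
            twophoton.plaque_volume(vol, caa.caa_mask, threshold_factor=f)[0]
            for f in (0.4, 0.5, 0.6, 0.7, 0.8)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))


class TestSessionAverage:
    def test_single_image_is_identity(self):
        r = PathologyResult(10.0, 500.0, 2)
        out = twophoton.session_average([r])
        assert (out.caa_coverage, out.plaque_volume, out.n_plaques) == (10.0, 500.0, 2)

    def test_mean_of_two(self):
        rs = [PathologyResult(10.0, 100.0, 1), PathologyResult(20.0, 300.0, 3)]
        out = twophoton.session_average(rs)
        assert out.caa_coverage == 15.0
        assert out.plaque_volume == 200.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            twophoton.session_average([])


class TestGeneratedRecovery:
    def test_zero_pathology_volume(self):
        # no amyloid anywhere: methoxy uniform at background, SR101 vessels only
        cfg = synth.TwoPhotonConfig(
            caa_fraction=0.0, plaque_radii_vox=(), wall_level=0.2, snr=0.0
        )
        vol, outlines, truth = synth.gen_twophoton_volume(cfg, seed=9)
        res = twophoton.quantify_image(vol, outlines)
        assert res.caa_coverage == 0.0  # strict > on zero-SD intensities
        assert (res.plaque_volume, res.n_plaques) == (0.0, 0)

    def test_full_chain_coverage_and_count(self, twophoton_volume):
        vol, outlines, truth = twophoton_volume
        res = twophoton.quantify_image(vol, outlines)
        assert res.caa_coverage == pytest.approx(truth["caa_coverage_pct"], abs=3.0)
        assert res.n_plaques == len(truth["plaque_voxels"])

    def test_sphere_volumes_exact_at_op_level(self, twophoton_volume):
        vol, outlines, truth = twophoton_volume
        caa = twophoton.caa_coverage(vol, outlines)
        volume, n = twophoton.plaque_volume(vol, caa.caa_mask)
        assert n == len(truth["plaque_voxels"])
        assert volume == pytest.approx(truth["plaque_volume_um3"], rel=0.05)

    def test_small_sphere_rejected_by_generator_truthing(self):
        cfg = synth.TwoPhotonConfig(plaque_radii_vox=(2.0, 2.5, 1.4))
        vol, outlines, truth = synth.gen_twophoton_volume(cfg, seed=4)
        sizes = truth["plaque_voxels"]
        assert min(sizes) <= 15  # the r=1.4 sphere is sub-threshold
        caa = twophoton.caa_coverage(vol, outlines)
        volume, n = twophoton.plaque_volume(vol, caa.caa_mask)
        kept = [s for s in sizes if s > 15]
        assert n == len(kept)
        assert volume == pytest.approx(sum(kept) * vol.voxel_volume, rel=0.05)

    def test_session_average_of_generated_truths(self):
        results, truths = [], []
        for seed in (21, 22, 23):
            vol, outlines, truth = synth.gen_twophoton_volume(seed=seed)
            results.append(twophoton.quantify_image(vol, outlines))
            truths.append(truth["caa_coverage_pct"])
        avg = twophoton.session_average(results)
        assert avg.caa_coverage == pytest.approx(np.mean(truths), abs=3.0)
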