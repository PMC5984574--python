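"""Kernel-regression synthesis: estimator exactness, curve shapes,
transfer correction, periventricular capping and the residual map."""

import dataclasses

import numpy as np
import pytest

from lesionsynth.phantom import PhantomParams, generate_cohort
from lesionsynth.synthesis import (
    PseudoHealthySynthesizer,
    compute_lsyn,
    estimate_transfer,
    kernel_regress,
)
from lesionsynth.volumes import VolumeGrid


def nw_oracle(t, f, h, grid):
    """Direct-summation Nadaraya-Watson, written independently."""
    out = []
    for k in grid:
        w = [np.exp(-0.5 * ((k - ti) / h) ** 2) / np.sqrt(2 * np.pi) for ti in t]
        out.append(sum(wi * fi for wi, fi in zip(w, f)) / sum(w))
    return np.array(out)


class TestKernelRegress:
    def test_constant_response(self):
        out = kernel_regress([1.0, 5.0, 9.0], [4.0, 4.0, 4.0], 2.0, np.linspace(0, 10, 7))
        assert np.allclose(out, 4.0)

    def test_symmetric_midpoint(self):
        out = kernel_regress([500.0, 1000.0], [800.0, 1200.0], 200.0, [750.0])
        assert out[0] == pytest.approx(1000.0)

    def test_matches_direct_summation_oracle(self, rng):
        """1000 random evaluations agree with brute-force summation to 1e-9."""
        for _ in range(50):
            n = int(rng.integers(1, 30))
            t = rng.uniform(0, 1500, n)
            f = rng.uniform(0, 2000, n)
            h = float(rng.uniform(5, 300))
            grid = rng.uniform(0, 1500, 20)
            assert np.allclose(
                kernel_regress(t, f, h, grid), nw_oracle(t, f, h, grid), atol=1e-9
            )

    def test_underflow_falls_back_to_nearest(self):
        # k is ~400 bandwidths from both points: kernel underflows
        out = kernel_regress([0.0, 10.0], [5.0, 7.0], 0.01, [4000.0])
        assert out[0] == pytest.approx(7.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kernel_regress([], [], 1.0, [0.0])
        with pytest.raises(ValueError):
            kernel_regress([1.0], [1.0], 0.0, [0.0])


@pytest.fixture(scope="module")
def bank(small_train_cohort):
    return PseudoHealthySynthesizer().fit(small_train_cohort)


class TestModelBank:

    @staticmethod
    def _slab_bundles(rng, labels_along_x):
        """Tiny bundles whose x-slabs carry fixed (t1, flair) tissue levels.

        Uses the normalised-scale class levels: CSF (345, 258), GM (827,
        1097), WM (1170, 903)."""
        from lesionsynth.volumes import SubjectBundle

        levels = {"CSF": (345.0, 258.0), "GM": (827.0, 1097.0), "WM": (1170.0, 903.0)}
        shape = (len(labels_along_x), 8, 8)
        bundles = []
        for _ in range(4):
            t1 = np.empty(shape)
            fl = np.empty(shape)
            for x, lab in enumerate(labels_along_x):
                mt, mf = levels[lab]
                t1[x] = mt + 26.0 * rng.standard_normal((8, 8))
                fl[x] = mf + 26.0 * rng.standard_normal((8, 8))
            ones = np.ones(shape)
            zeros = np.zeros(shape)
            bundles.append(
                SubjectBundle(
                    t1=VolumeGrid(t1), flair=VolumeGrid(fl),
                    wm_prob=VolumeGrid(ones), gm_prob=VolumeGrid(zeros),
                    ventricle_mask=VolumeGrid(zeros), atlas=VolumeGrid(zeros),
                )
            )
        return bundles

    def test_wm_only_patch_curve_is_flat(self, rng):
        """A patch containing a single tissue cluster extrapolates the same
        FLAIR level across the whole k range: curve spread stays below the
        sample SD of the pooled FLAIR intensities."""
        bundles = self._slab_bundles(rng, ["WM"] * 8)
        bank = PseudoHealthySynthesizer().fit(bundles)
        pooled_sd = np.std(np.concatenate([b.flair.data.ravel() for b in bundles]))
        # interior voxels pool complete patches; edge voxels see smaller,
        # noisier pools
        interior = np.zeros((8, 8, 8), dtype=bool)
        interior[2:-2, 2:-2, 2:-2] = True
        curves = bank.curves_[interior.ravel()]
        assert np.all(curves.std(axis=1) < pooled_sd)

    def test_mixed_patch_curve_has_interior_gm_peak(self, rng):
        """A WM/GM/CSF patch's curve peaks at GM-like T1 intensity."""
        bundles = self._slab_bundles(rng, ["CSF", "CSF", "GM", "GM", "WM", "WM"])
        bank = PseudoHealthySynthesizer().fit(bundles)
        # a voxel in the middle of the volume pools all three tissues
        idx = np.ravel_multi_index((3, 4, 4), (6, 8, 8))
        curve = bank.curves_[idx]
        peak = int(np.argmax(curve))
        assert 0 < peak < bank.m - 1  # interior maximum
        # peak sits at GM-like T1 (~830 normalised), not at the WM end
        assert 600 < bank.k_grid_[peak] < 1100
        # and the WM end predicts WM-like FLAIR, below the GM peak
        wm_end = curve[np.searchsorted(bank.k_grid_, 1170)]
        assert wm_end < curve[peak]

    def test_binned_fit_matches_exact_kernel_regression(self, small_train_cohort):
        """The histogram-binned bank agrees with the exact estimator run on
        the same pooled pairs, to well under the within-tissue noise."""
        est = PseudoHealthySynthesizer(a=3, t_bins=600)
        est.fit(small_train_cohort)
        shape = small_train_cohort[0].t1.shape
        rng = np.random.default_rng(1)
        vox = rng.choice(np.flatnonzero(~est.background_), size=15, replace=False)
        for idx in vox:
            i, j, k = np.unravel_index(idx, shape)
            ts, fs = [], []
            for b in small_train_cohort:
                sl = tuple(
                    slice(max(0, c - 1), min(n, c + 2))
                    for c, n in zip((i, j, k), shape)
                )
                ts.append(np.clip(b.t1.data[sl].ravel(), 0, est.t_max))
                fs.append(b.flair.data[sl].ravel())
            t_all = np.concatenate(ts)
            exact = kernel_regress(t_all, np.concatenate(fs), est.h, est.k_grid_)
            # compare on the data-supported part of the curve (within one
            # bandwidth of a training t) — the only region synthesis reads,
            # since test T1 values follow the training distribution; in the
            # no-data gaps between clusters the kernel ratio is dominated by
            # far tails and any t-quantisation is exponentially amplified
            m = np.abs(est.k_grid_[:, None] - t_all[None, :]).min(axis=1) < est.h
            if m.any():
                err = np.abs(est.curves_[idx][m] - exact[m])
                assert err.max() < 2.0

    def test_all_background_patch_flagged_and_synthesised_zero(self, rng):
        """Patches that pool no brain voxel get the zero sentinel."""
        bundles = self._slab_bundles(rng, ["WM"] * 6)
        for b in bundles:
            pad = [(np.pad(v.data, 4), v.spacing) for v in (b.t1, b.flair)]
            b.t1 = VolumeGrid(*pad[0])
            b.flair = VolumeGrid(*pad[1])
            for name in ("wm_prob", "gm_prob", "ventricle_mask", "atlas"):
                setattr(b, name, VolumeGrid(np.pad(getattr(b, name).data, 4)))
        bank = PseudoHealthySynthesizer(a=3).fit(bundles)
        corner = np.ravel_multi_index((0, 0, 0), bundles[0].t1.shape)
        assert bank.background_[corner]
        assert np.all(bank.curves_[corner] == 0.0)
        syn = bank.transform(bundles[0].t1)
        assert syn.data[0, 0, 0] == 0.0

    def test_synthesis_index_mapping(self, bank):
        """t=750 -> index 50; above-cap t -> index m."""
        t = VolumeGrid(np.full(bank.shape_, 750.0), bank.spacing_)
        raw = bank._lookup(t)
        expected = bank.curves_[:, 49].reshape(bank.shape_)
        assert np.array_equal(raw.data, expected)
        t_hi = VolumeGrid(np.full(bank.shape_, 1800.0), bank.spacing_)
        raw_hi = bank._lookup(t_hi)
        assert np.array_equal(raw_hi.data, bank.curves_[:, 99].reshape(bank.shape_))

    def test_pseudo_healthy_inside_lesion(self, bank, small_lesion_subject):
        """A T1-hypointense lesion is synthesised as healthy-WM FLAIR."""
        s = small_lesion_subject
        syn = bank.transform(s.t1)
        les = s.lesion_truth.data > 0
        wm_mean = 0.70 * 1000 / 0.775  # healthy WM FLAIR, normalised scale
        wm_sd = 0.028 * 1000 / 0.775  # class + scanner noise
        assert abs(syn.data[les].mean() - wm_mean) < wm_sd

    def test_periventricular_cap_invariant(self, bank, small_lesion_subject):
        syn = bank.transform(small_lesion_subject.t1)
        assert np.all(syn.data[bank.pv_shell_] <= bank.pv_cap_ + 1e-9)

    def test_single_subject_warns_but_fits(self, small_train_cohort):
        with pytest.warns(UserWarning, match="single subject"):
            PseudoHealthySynthesizer().fit(small_train_cohort[:1])

    def test_save_load_roundtrip(self, bank, tmp_path, small_lesion_subject):
        bank.save(tmp_path / "bank")
        back = PseudoHealthySynthesizer.load(tmp_path / "bank")
        a = bank.transform(small_lesion_subject.t1)
        b = back.transform(small_lesion_subject.t1)
        assert np.allclose(a.data, b.data, atol=1e-4)


class TestTransfer:
    def test_identity_when_synthetic_equals_flair(self, rng):
        vols = [
            VolumeGrid(rng.uniform(100, 1900, (10, 10, 10)), (1, 1, 1))
            for _ in range(3)
        ]
        tf = estimate_transfer(vols, vols)
        inner = (tf.knots > 150) & (tf.knots < 1850)
        assert np.allclose(tf.median_curve[inner], tf.knots[inner], atol=25)

    def test_median_across_subject_slopes(self, rng):
        base = rng.uniform(100, 1900, (12, 12, 12))
        flair = [VolumeGrid(base * s, (1, 1, 1)) for s in (0.9, 1.0, 1.1)]
        syn = [VolumeGrid(base, (1, 1, 1))] * 3
        tf = estimate_transfer(syn, flair)
        inner = (tf.knots > 200) & (tf.knots < 1700)
        slope = np.polyfit(tf.knots[inner], tf.median_curve[inner], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_restores_compressed_contrast(self, rng):
        """Mapping a toward-the-mean-compressed image through the estimated
        transfer restores the 5th/95th percentile spread within 5%."""
        truth = [
            VolumeGrid(rng.normal(1000, 200, (14, 14, 14)).clip(1, None), (1, 1, 1))
            for _ in range(4)
        ]
        compressed = [
            VolumeGrid(1000 + 0.5 * (v.data - 1000), v.spacing) for v in truth
        ]
        tf = estimate_transfer(compressed, truth)
        for c, t in zip(compressed, truth):
            restored = tf(c.data)
            spread_r = np.subtract(*np.percentile(restored, [95, 5]))
            spread_t = np.subtract(*np.percentile(t.data, [95, 5]))
            assert abs(spread_r - spread_t) / spread_t < 0.05

    def test_single_subject_warns(self, rng):
        v = [VolumeGrid(rng.uniform(1, 2, (6, 6, 6)), (1, 1, 1))]
        with pytest.warns(UserWarning):
            estimate_transfer(v, v)


class TestLsyn:
    def test_zero_for_identical_volumes(self, rng):
        v = VolumeGrid(rng.uniform(0, 1, (5, 5, 5)), (1, 1, 1))
        assert np.all(compute_lsyn(v, v).data == 0)

    def test_signed_subtraction(self):
        f = VolumeGrid(np.full((2, 2, 2), 1300.0), (1, 1, 1))
        s = VolumeGrid(np.full((2, 2, 2), 1000.0), (1, 1, 1))
        assert np.all(compute_lsyn(f, s).data == 300.0)

    def test_healthy_residual_small(self, small_train_cohort):
        """On a held-out healthy subject the mean absolute residual stays
        within twice the scanner-noise level."""
        bank = PseudoHealthySynthesizer().fit(small_train_cohort)
        from lesionsynth.normalise import normalise_bundle
        from lesionsynth.phantom import generate_subject

        hb = normalise_bundle(
            generate_subject(
                PhantomParams(
                    shape=(32, 32, 32), seed=555, n_lesions=0, band_cap_intensity=0.0
                )
            )
        )
        lsyn = compute_lsyn(hb.flair, bank.transform(hb.t1))
        brain = hb.flair.data > 0
        noise_norm = 0.02 * 1000 / 0.775
        assert np.abs(lsyn.data[brain]).mean() < 2 * noise_norm
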