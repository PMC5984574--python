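"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from lesionsynth.metrics import (
    SegPair,
    agreement_stats,
    fazekas_correlation,
    icc_a1,
    overlap_metrics,
    surface_metrics,
    volume_binned_dsc,
)
from lesionsynth.volumes import VolumeGrid


def _pair(a, t, spacing=(1.0, 1.0, 1.0)):
    return SegPair(
        computed=VolumeGrid(np.asarray(a, float), spacing),
        reference=VolumeGrid(np.asarray(t, float), spacing),
    )


def _random_mask(rng, shape=(8, 8, 8), p=0.2):
    return (rng.random(shape) < p).astype(float)


# ---------------------------------------------------------------- overlap


class TestOverlap:
    def test_identical_masks_perfect(self, rng):
        m = _random_mask(rng)
        m[0, 0, 0] = 1
        out = overlap_metrics(_pair(m, m))
        assert out == {"dsc": 1.0, "precision": 1.0, "recall": 1.0}

    def test_half_overlap_formula(self):
        a = np.zeros((2, 2, 2))
        t = np.zeros((2, 2, 2))
        a.ravel()[[0, 1, 2, 3]] = 1
        t.ravel()[[2, 3, 4, 5]] = 1
        assert overlap_metrics(_pair(a, t))["dsc"] == pytest.approx(0.5)

    def test_empty_conventions(self):
        z = np.zeros((2, 2, 2))
        o = np.ones((2, 2, 2))
        assert overlap_metrics(_pair(z, z))["dsc"] == 1.0
        assert overlap_metrics(_pair(o, z))["dsc"] == 0.0
        assert overlap_metrics(_pair(z, o))["dsc"] == 0.0

    def test_random_masks_match_set_oracle(self, rng):
        """100 random mask pairs agree with explicit voxel-set arithmetic."""
        for _ in range(100):
            a = _random_mask(rng, p=float(rng.uniform(0.05, 0.6)))
            t = _random_mask(rng, p=float(rng.uniform(0.05, 0.6)))
            got = overlap_metrics(_pair(a, t))
            A = {tuple(v) for v in np.argwhere(a > 0)}
            T = {tuple(v) for v in np.argwhere(t > 0)}
            inter = len(A & T)
            assert got["dsc"] == pytest.approx(2 * inter / (len(A) + len(T)), abs=1e-12)
            assert got["precision"] == pytest.approx(inter / len(A), abs=1e-12)
            assert got["recall"] == pytest.approx(inter / len(T), abs=1e-12)


# ---------------------------------------------------------------- surfaces


def _surface_oracle(mask):
    """6-connected boundary voxels by explicit neighbour checking."""
    pts = []
    idx = np.argwhere(mask > 0)
    for p in idx:
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = p + d
            if np.any(q < 0) or np.any(q >= mask.shape) or mask[tuple(q)] == 0:
                pts.append(p)
                break
    return np.array(pts)


class TestSurface:
    def test_identical_masks_zero(self, rng):
        m = _random_mask(rng)
        m[2, 2, 2] = 1
        out = surface_metrics(_pair(m, m))
        assert out == {"assd": 0.0, "hd": 0.0}

    def test_two_point_masks_distance(self):
        a = np.zeros((8, 4, 4))
        t = np.zeros((8, 4, 4))
        a[1, 1, 1] = 1
        t[4, 1, 1] = 1
        out = surface_metrics(_pair(a, t))
        assert out["assd"] == pytest.approx(3.0)
        assert out["hd"] == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 4, 4))
        t = np.zeros((8, 4, 4))
        a[1, 1, 1] = 1
        t[4, 1, 1] = 1
        out = surface_metrics(_pair(a, t, spacing=(2.0, 1.0, 1.0)))
        assert out["hd"] == pytest.approx(6.0)

    def test_empty_mask_undefined(self):
        z = np.zeros((3, 3, 3))
        o = np.ones((3, 3, 3))
        with pytest.raises(ValueError):
            surface_metrics(_pair(z, o))

    def test_random_masks_match_allpairs_oracle(self, rng):
        """Brute O(n^2) pairwise distances reproduce ASSD and HD to 1e-9."""
        spacing = (1.0, 1.5, 2.0)
        for _ in range(30):
            a = _random_mask(rng, (6, 6, 6), 0.3)
            t = _random_mask(rng, (6, 6, 6), 0.3)
            if not a.any() or not t.any():
                continue
            got = surface_metrics(_pair(a, t, spacing))
            pa = _surface_oracle(a) * spacing
            pt = _surface_oracle(t) * spacing
            d = np.sqrt(((pa[:, None, :] - pt[None, :, :]) ** 2).sum(-1))
            d_at = d.min(axis=1)
            d_ta = d.min(axis=0)
            assert got["assd"] == pytest.approx(
                0.5 * (d_at.mean() + d_ta.mean()), abs=1e-9
            )
            assert got["hd"] == pytest.approx(max(d_at.max(), d_ta.max()), abs=1e-9)


# ---------------------------------------------------------------- ICC


def _icc_oracle_pingouin(a, t):
    import pandas as pd
    import pingouin as pg

    n = len(a)
    df = pd.DataFrame(
        {
            "targets": list(range(n)) * 2,
            "raters": ["a"] * n + ["t"] * n,
            "ratings": list(a) + list(t),
        }
    )
    res = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
    return float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])


class TestICC:
    def test_perfect_agreement(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert icc_a1(v, v) == pytest.approx(1.0)

    def test_constant_shift_penalised(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert icc_a1(v + 2.0, v) < 1.0

    def test_matches_independent_anova_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 15))
            t = rng.uniform(0, 30, n)
            a = t + rng.normal(0, 3, n)
            assert icc_a1(a, t) == pytest.approx(_icc_oracle_pingouin(a, t), abs=1e-9)

    def test_length_checks(self):
        with pytest.raises(ValueError):
            icc_a1([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            icc_a1([1, 2], [1, 2])


# ---------------------------------------------------------------- binned DSC


class TestBinnedDsc:
    def test_lesion_volume_bins(self):
        # 5-voxel lesion at 1 mm spacing = 0.005 ml -> "very small" bin
        t = np.zeros((10, 10, 10))
        t[1, 1, 1:6] = 1
        a = t.copy()
        out = volume_binned_dsc([_pair(a, t)], mode="lesion")
        assert out == {"<0.01": 1.0}

    def test_lesion_bin_boundaries(self):
        # 12-voxel lesion = 0.012 ml -> "0.01-0.1"; 150 voxels -> "0.1-1"
        t = np.zeros((12, 12, 12))
        t[1, 1:4, 1:5] = 1  # 12 voxels
        t[6:12, 6:11, 6:11] = 1  # 150 voxels
        out = volume_binned_dsc([_pair(t, t)], mode="lesion")
        assert set(out) == {"0.01-0.1", "0.1-1"}

    def test_subject_volume_bins(self):
        # 12 ml total -> "10-15" bin
        t = np.zeros((30, 30, 30))
        t.ravel()[:12000] = 1
        out = volume_binned_dsc([_pair(t, t)], mode="subject")
        assert out == {"10-15": 1.0}

    def test_dsc_inside_bounding_box_only(self):
        """False positives outside a lesion's bounding box do not affect
        its per-lesion DSC."""
        t = np.zeros((12, 12, 12))
        t[2:5, 2:5, 2:5] = 1
        a = t.copy()
        a[9:12, 9:12, 9:12] = 1  # far-away false positive blob
        out = volume_binned_dsc([_pair(a, t)], mode="lesion")
        assert out["0.01-0.1"] == pytest.approx(1.0)

    def test_components_use_26_connectivity(self):
        t = np.zeros((8, 8, 8))
        t[1, 1, 1] = 1
        t[2, 2, 2] = 1  # diagonal neighbour: one component under 26-conn
        lab, n = ndimage.label(t, structure=np.ones((3, 3, 3)))
        assert n == 1
        out = volume_binned_dsc([_pair(t, t)], mode="lesion")
        assert len(out) == 1


# ---------------------------------------------------------------- agreement


def _agreement_oracle(va, vt, icv):
    x = np.asarray(vt) / np.asarray(icv)
    y = np.asarray(va) / np.asarray(icv)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    d = (y - x) / (0.5 * (x + y))
    sd = np.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    return slope, intercept, r * r, 1.96 * sd


class TestAgreement:
    def test_identical_volumes(self):
        v = [1.0, 2.0, 3.0, 4.0]
        icv = [10.0] * 4
        out = agreement_stats(v, v, icv)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert out["r2"] == pytest.approx(1.0)
        assert out["rpc"] == pytest.approx(0.0, abs=1e-12)
        assert out["mean_diff"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relation(self):
        t = np.array([1.0, 2.0, 3.0, 5.0])
        out = agreement_stats(1.1 * t, t, np.full(4, 10.0))
        assert out["slope"] == pytest.approx(1.1)
        assert out["sse"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 14))
            vt = rng.uniform(1, 30, n)
            va = vt * rng.uniform(0.8, 1.2, n)
            icv = rng.uniform(1000, 1500, n)
            out = agreement_stats(va, vt, icv)
            slope, intercept, r2, rpc = _agreement_oracle(va, vt, icv)
            assert out["slope"] == pytest.approx(slope, abs=1e-9)
            assert out["intercept"] == pytest.approx(intercept, abs=1e-9)
            assert out["r2"] == pytest.approx(r2, abs=1e-9)
            assert out["rpc"] == pytest.approx(rpc, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [10.0] * 3)


# ---------------------------------------------------------------- Fazekas


def _spearman_oracle(v, f):
    def ranks(x):
        order = np.argsort(x, kind="mergesort")
        r = np.empty(len(x))
        i = 0
        x = np.asarray(x, dtype=float)
        sx = x[order]
        while i < len(x):
            j = i
            while j < len(x) and sx[j] == sx[i]:
                j += 1
            r[order[i:j]] = (i + j - 1) / 2.0 + 1
            i = j
        return r
    ra, rb = ranks(v), ranks(f)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


class TestFazekas:
    def test_monotone_relation_gives_one(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        f = [0, 1, 2, 3, 4, 5, 6]
        assert fazekas_correlation(v, np.ones(7), f) == pytest.approx(1.0)

    def test_constant_scores_undefined(self):
        out = fazekas_correlation([1.0, 2.0, 3.0], np.ones(3), [2, 2, 2])
        assert np.isnan(out)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            fazekas_correlation([1.0, 2.0], [1.0, 1.0], [0, 7])

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        for _ in range(10):
            n = 8
            v = rng.uniform(0, 5, n).round(1)  # rounded -> ties likely
            f = rng.integers(0, 7, n)
            if np.ptp(v) == 0 or np.ptp(f) == 0:
                continue
            got = fazekas_correlation(v, np.ones(n), f)
            assert got == pytest.approx(_spearman_oracle(v, f), abs=1e-12)
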