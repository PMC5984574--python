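"""Pseudo-healthy FLAIR synthesis from T1-w by voxel-wise kernel regression.

At every voxel of the common lattice a Nadaraya-Watson regression relates
T1 intensity to FLAIR intensity, fitted on the pooled voxels of an
``a``-by-``a``-by-``a`` patch around that voxel across all training
subjects.  The fitted curve is evaluated once on a fixed grid of ``m``
T1 intensities between 0 and ``t_max``; synthesis is then a table lookup.

Where a patch contains a single tissue (e.g. deep WM) the curve is nearly
constant, so a T1-hypointense lesion is still synthesised as healthy WM —
the property that makes the residual F - S a lesion likelihood map.

Kernel smoothing pulls synthetic intensities toward the mean, compressing
contrast; a monotone per-subject histogram-matching transfer function
(median across training subjects) restores it.  Finally, synthetic WM
within 15 mm of the ventricles is capped at a healthy-WM intensity so that
benign periventricular "bands and caps" present in healthy training data
are not reproduced as pathology.

The bank fit bins T1 intensities on a fine grid so the per-voxel kernel
sums become histogram-matrix products; :func:`kernel_regress` is the exact
direct-summation estimator used both at small scale and as the reference
the binned fit is validated against.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .volumes import SubjectBundle, VolumeGrid

__all__ = [
    "kernel_regress",
    "TransferFunction",
    "estimate_transfer",
    "PseudoHealthySynthesizer",
    "fit_model_bank",
    "synthesise",
    "compute_lsyn",
]

#: Distance (mm) from the ventricles within which synthetic WM is capped.
PV_CAP_RADIUS_MM = 15.0

#: Upper end of the transfer-function knot range, normalised units.
TRANSFER_RANGE = 2000.0


def kernel_regress(
    t: np.ndarray, f: np.ndarray, h: float, grid: np.ndarray
) -> np.ndarray:
    """Nadaraya-Watson regression with a Gaussian kernel.

    ``M(k) = sum_i K((k - t_i)/h) f_i / sum_i K((k - t_i)/h)`` with
    ``K(p) = exp(-p^2/2)/sqrt(2*pi)``.  Where the denominator underflows,
    the prediction falls back to ``f`` of the nearest ``t`` (the
    extrapolation contract of a local average).
    """
    t = np.asarray(t, dtype=np.float64).ravel()
    f = np.asarray(f, dtype=np.float64).ravel()
    grid = np.asarray(grid, dtype=np.float64).ravel()
    if t.size == 0 or t.size != f.size:
        raise ValueError("t and f must be non-empty and of equal length")
    if not (h > 0):
        raise ValueError(f"bandwidth must be positive, got {h}")
    z = (grid[:, None] - t[None, :]) / h
    w = np.exp(-0.5 * z * z)  # the 1/sqrt(2*pi) factor cancels
    den = w.sum(axis=1)
    num = w @ f
    out = np.empty_like(den)
    ok = den > np.finfo(np.float64).tiny
    out[ok] = num[ok] / den[ok]
    if not np.all(ok):
        nearest = np.abs(grid[~ok, None] - t[None, :]).argmin(axis=1)
        out[~ok] = f[nearest]
    return out


@dataclasses.dataclass
class TransferFunction:
    """Monotone piecewise-linear intensity maps sampled at fixed knots.

    ``curves`` holds one map per training subject (quantile matching of the
    synthetic image onto its true FLAIR); ``median_curve`` is their
    pointwise median and is the map applied at synthesis time.
    """

    knots: np.ndarray
    curves: np.ndarray  # (n_subjects, n_knots)
    median_curve: np.ndarray

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.knots, self.median_curve)


def estimate_transfer(
    synthetic_train: Sequence[VolumeGrid],
    flair_train: Sequence[VolumeGrid],
    n_knots: int = 256,
    intensity_max: float = TRANSFER_RANGE,
) -> TransferFunction:
    """Per-subject quantile-matching transfer functions and their median.

    For each subject, the map sends the empirical quantiles of the
    synthetic brain intensities onto the quantiles of the true FLAIR brain
    intensities.  The brain mask is taken from the true FLAIR (nonzero
    voxels), so near-zero synthetic values outside the brain cannot skew
    the quantile correspondence.  Quantile maps are monotone by
    construction.
    """
    if len(synthetic_train) != len(flair_train) or len(synthetic_train) == 0:
        raise ValueError("need equal, nonzero numbers of synthetic and FLAIR volumes")
    if len(synthetic_train) < 2:
        import warnings

        warnings.warn("fewer than 2 subjects: transfer median degenerates to a "
                      "single function", stacklevel=2)
    knots = np.linspace(0.0, intensity_max, n_knots)
    curves = np.empty((len(synthetic_train), n_knots))
    for i, (syn, fl) in enumerate(zip(synthetic_train, flair_train)):
        if not syn.same_lattice(fl):
            raise ValueError(f"subject {i}: synthetic/FLAIR lattice mismatch")
        brain = fl.data > 0
        s = np.sort(syn.data[brain].ravel())
        fvals = np.sort(fl.data[brain].ravel())
        if s.size == 0 or fvals.size == 0:
            raise ValueError(f"subject {i}: no brain (nonzero) voxels")
        # CDF position of each knot under the synthetic distribution,
        # then the FLAIR quantile at that position
        pos = np.searchsorted(s, knots, side="right") / s.size
        curves[i] = np.quantile(fvals, np.clip(pos, 0.0, 1.0))
    return TransferFunction(
        knots=knots, curves=curves, median_curve=np.median(curves, axis=0)
    )


class PseudoHealthySynthesizer(BaseEstimator):
    """Per-voxel kernel-regression bank mapping T1 to pseudo-healthy FLAIR.

    Parameters
    ----------
    m : int
        Number of evaluation points of each per-voxel curve.
    t_max : float
        T1 intensity cap in normalised units; training and test T1 values
        above it are clamped.
    h : float
        Gaussian kernel bandwidth in normalised units.  Roughly 1/30 of
        ``t_max`` keeps curves smooth without erasing the GM peak.
    a : int
        Training patch edge in voxels; each voxel's fit pools the
        ``a**3`` patch across all training subjects (clipped at edges).
    t_bins : int
        Number of T1 histogram bins used by the fast binned fit.
    pv_radius_mm : float
        Periventricular capping radius.
    transfer_knots : int
        Knot count of the histogram-matching transfer function.

    Attributes
    ----------
    curves_ : ndarray (n_voxels, m)
        Per-voxel predicted FLAIR at the ``m`` grid points.
    background_ : ndarray (n_voxels,) of bool
        Voxels whose pooled patch was empty; their curve is an all-zero
        sentinel and synthesis outputs 0.
    transfer_ : TransferFunction
    pv_shell_ : ndarray of bool
        WM voxels within ``pv_radius_mm`` of the ventricles.
    pv_cap_ : float
        Healthy-WM FLAIR intensity used as the cap on the shell (median of
        training FLAIR over shell WM voxels; the median is robust to the
        thin band/cap shell itself).
    """

    def __init__(
        self,
        m: int = 100,
        t_max: float = 1500.0,
        h: float = 50.0,
        a: int = 5,
        t_bins: int = 150,
        pv_radius_mm: float = PV_CAP_RADIUS_MM,
        transfer_knots: int = 256,
    ):
        self.m = m
        self.t_max = t_max
        self.h = h
        self.a = a
        self.t_bins = t_bins
        self.pv_radius_mm = pv_radius_mm
        self.transfer_knots = transfer_knots

    # -- fitting -----------------------------------------------------------

    @property
    def k_grid_(self) -> np.ndarray:
        """Evaluation points k = t_max * j / m, j = 1..m."""
        return self.t_max * np.arange(1, self.m + 1) / self.m

    def fit(self, bundles: Sequence[SubjectBundle]) -> "PseudoHealthySynthesizer":
        if len(bundles) == 0:
            raise ValueError("empty training cohort")
        if len(bundles) < 2:
            import warnings

            warnings.warn(
                "fitting the synthesis bank on a single subject: the "
                "transfer-function median degenerates to one function",
                stacklevel=2,
            )
        ref = bundles[0].t1
        for i, b in enumerate(bundles):
            if not b.t1.same_lattice(ref):
                raise ValueError(f"subject {i} is on a different lattice")
        self.shape_ = ref.shape
        self.spacing_ = ref.spacing
        nvox = int(np.prod(ref.shape))
        nb = self.t_bins
        width = self.t_max / nb

        # per-voxel T1-bin histograms: counts and FLAIR sums
        counts = np.zeros((nvox, nb), dtype=np.float32)
        fsums = np.zeros((nvox, nb), dtype=np.float32)
        brain_hits = np.zeros(ref.shape, dtype=np.float32)
        vox_idx = np.arange(nvox)
        for b in bundles:
            t = np.clip(b.t1.data.ravel(), 0.0, self.t_max)
            bins = np.minimum((t / width).astype(np.int64), nb - 1)
            flat = vox_idx * nb + bins
            counts.ravel()[:] += np.bincount(flat, minlength=nvox * nb).astype(
                np.float32
            )
            fsums.ravel()[:] += np.bincount(
                flat, weights=b.flair.data.ravel(), minlength=nvox * nb
            ).astype(np.float32)
            brain_hits += (b.t1.data > 0).astype(np.float32)

        # pool the a^3 patch: box-sum with zero padding == edge clipping
        size = (self.a, self.a, self.a, 1)
        vol_shape = ref.shape + (nb,)
        scale = float(self.a**3)
        counts = (
            ndimage.uniform_filter(
                counts.reshape(vol_shape), size=size, mode="constant", cval=0.0
            )
            * scale
        ).reshape(nvox, nb)
        fsums = (
            ndimage.uniform_filter(
                fsums.reshape(vol_shape), size=size, mode="constant", cval=0.0
            )
            * scale
        ).reshape(nvox, nb)

        centres = (np.arange(nb) + 0.5) * width
        z = (self.k_grid_[None, :] - centres[:, None]) / self.h
        kmat = np.exp(-0.5 * z * z)  # (nb, m)
        den = counts.astype(np.float64) @ kmat
        num = fsums.astype(np.float64) @ kmat
        # all-background patches (no brain voxel pooled from any subject)
        # get an all-zero sentinel curve and are flagged
        pooled_brain = ndimage.uniform_filter(
            brain_hits, size=(self.a,) * 3, mode="constant", cval=0.0
        ) * scale
        self.background_ = pooled_brain.ravel() < 0.5
        curves = np.zeros((nvox, self.m))
        ok = (den > np.finfo(np.float64).tiny) & ~self.background_[:, None]
        curves[ok] = num[ok] / den[ok]
        # rare underflow with occupied patches: nearest occupied bin's mean
        starved = ~ok & ~self.background_[:, None]
        if starved.any():
            vs, ks = np.nonzero(starved)
            for v, k in zip(vs, ks):
                occ = np.nonzero(counts[v] > 0)[0]
                j = occ[np.abs(centres[occ] - self.k_grid_[k]).argmin()]
                curves[v, k] = fsums[v, j] / counts[v, j]
        self.curves_ = curves

        # transfer function from raw synthetic vs true FLAIR
        raw = [self._lookup(b.t1) for b in bundles]
        self.transfer_ = estimate_transfer(
            raw, [b.flair for b in bundles], n_knots=self.transfer_knots
        )

        # periventricular capping shell and cap level
        vent = np.mean([b.ventricle_mask.data for b in bundles], axis=0) > 0.5
        wm = np.mean([b.wm_prob.data for b in bundles], axis=0) > 0.5
        dist = ndimage.distance_transform_edt(~vent, sampling=ref.spacing)
        self.pv_shell_ = wm & (dist <= self.pv_radius_mm)
        shell_flair = np.concatenate(
            [b.flair.data[self.pv_shell_] for b in bundles]
        )
        self.pv_cap_ = float(np.median(shell_flair)) if shell_flair.size else np.inf
        return self

    # -- synthesis ---------------------------------------------------------

    def _lookup(self, t1: VolumeGrid) -> VolumeGrid:
        """Raw curve lookup: S_x = curve_x[ceil(m t / t_max)] (no transfer,
        no capping)."""
        t = np.clip(t1.data.ravel(), 0.0, self.t_max)
        i = np.ceil(self.m * t / self.t_max).astype(np.int64)
        i = np.clip(i, 1, self.m) - 1  # 1-based index into the k grid
        s = self.curves_[np.arange(t.size), i]
        s[self.background_] = 0.0
        s[t1.data.ravel() <= 0] = 0.0  # skull-stripped background stays 0
        return t1.like(s.reshape(t1.shape))

    def transform(self, t1: VolumeGrid) -> VolumeGrid:
        """Synthesise a pseudo-healthy FLAIR: lookup, transfer correction,
        then periventricular capping."""
        if t1.shape != self.shape_:
            raise ValueError(f"t1 shape {t1.shape} does not match bank {self.shape_}")
        raw = self._lookup(t1)
        s = self.transfer_(raw.data)
        s[(raw.data == 0) | (t1.data <= 0)] = 0.0
        s[self.pv_shell_] = np.minimum(s[self.pv_shell_], self.pv_cap_)
        return t1.like(s)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path.with_suffix(".npz"),
            curves=self.curves_.astype(np.float32),
            background=self.background_,
            pv_shell=self.pv_shell_,
            transfer_knots=self.transfer_.knots,
            transfer_curves=self.transfer_.curves,
            transfer_median=self.transfer_.median_curve,
        )
        meta = dict(
            m=self.m, t_max=self.t_max, h=self.h, a=self.a, t_bins=self.t_bins,
            pv_radius_mm=self.pv_radius_mm, transfer_knots=self.transfer_knots,
            shape=list(self.shape_), spacing=list(self.spacing_),
            pv_cap=self.pv_cap_,
        )
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PseudoHealthySynthesizer":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(
            m=meta["m"], t_max=meta["t_max"], h=meta["h"], a=meta["a"],
            t_bins=meta["t_bins"], pv_radius_mm=meta["pv_radius_mm"],
            transfer_knots=meta["transfer_knots"],
        )
        with np.load(path.with_suffix(".npz")) as z:
            est.curves_ = z["curves"].astype(np.float64)
            est.background_ = z["background"]
            est.pv_shell_ = z["pv_shell"]
            est.transfer_ = TransferFunction(
                knots=z["transfer_knots"],
                curves=z["transfer_curves"],
                median_curve=z["transfer_median"],
            )
        est.shape_ = tuple(meta["shape"])
        est.spacing_ = tuple(meta["spacing"])
        est.pv_cap_ = meta["pv_cap"]
        return est


def fit_model_bank(
    train: Sequence[SubjectBundle], **params
) -> PseudoHealthySynthesizer:
    """Fit the synthesis bank on normalised training bundles."""
    return PseudoHealthySynthesizer(**params).fit(train)


def synthesise(t1: VolumeGrid, bank: PseudoHealthySynthesizer) -> VolumeGrid:
    """Pseudo-healthy FLAIR for a normalised T1 volume."""
    return bank.transform(t1)


def compute_lsyn(flair: VolumeGrid, synthetic: VolumeGrid) -> VolumeGrid:
    """Synthesis residual likelihood map: L^SYN = F - S (signed)."""
    if not flair.same_lattice(synthetic):
        raise ValueError("FLAIR and synthetic volumes are on different lattices")
    return flair.like(flair.data - synthetic.data)
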