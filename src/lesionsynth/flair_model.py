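"""Per-voxel two-component Gaussian mixtures of healthy FLAIR intensity.

Across co-registered training images, the intensities seen at one voxel
come from either a single tissue class or, at tissue boundaries, a mixture
of two — hence a two-component 1-D Gaussian mixture per voxel, fitted by
EM on the nonzero intensities pooled from a ``b``-cubed patch around the
voxel across all training subjects.

At test time the mixture density at the observed FLAIR intensity is turned
into an abnormality map: the negative log-density, anchored so the most
ordinary brain voxel sits at 0, and hard-zeroed below the normalised
intensity 1000 (the WM/GM fixed point) so that only *hyper*-intensity is
flagged.

The bank fit runs a weighted EM over intensity-histogram bins, which is EM
on intensities quantised to bin centres; :func:`em_fit_two_component` is
the exact sample-level EM used directly and as the reference for the bank.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .volumes import VolumeGrid

__all__ = [
    "VoxelGMM",
    "em_fit_two_component",
    "VoxelwiseGMM",
    "fit_gmm_bank",
    "compute_lflair",
    "HYPERINTENSITY_THRESHOLD",
]

#: Normalised FLAIR intensity below which the abnormality map is exactly 0
#: (the WM/GM fixed point set during normalisation).
HYPERINTENSITY_THRESHOLD = 1000.0

#: Guard added to the density before taking the log.
DENSITY_EPS = 1e-300

SIGMA_FLOOR = 1.0
MIN_SAMPLES = 8

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclasses.dataclass
class VoxelGMM:
    """Two-component 1-D Gaussian mixture (w, mu, sigma) at one voxel."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sigmas: tuple[float, float]
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        if abs(self.weights[0] + self.weights[1] - 1.0) > 1e-9:
            raise ValueError(f"weights {self.weights} do not sum to 1")
        if min(self.weights) < 0:
            raise ValueError("negative mixture weight")
        if min(self.sigmas) < SIGMA_FLOOR - 1e-12:
            raise ValueError(f"sigma below floor {SIGMA_FLOOR}")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        out = np.zeros_like(x, dtype=np.float64)
        for w, mu, sd in zip(self.weights, self.means, self.sigmas):
            out += w * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * _SQRT2PI)
        return out


def _degenerate(value: float, n: int = 0) -> VoxelGMM:
    return VoxelGMM(
        weights=(0.5, 0.5),
        means=(value, value),
        sigmas=(SIGMA_FLOOR, SIGMA_FLOOR),
        converged=True,
        n_iter=n,
    )


def em_fit_two_component(
    samples: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    sigma_floor: float = SIGMA_FLOOR,
) -> VoxelGMM:
    """EM fit of a two-component 1-D Gaussian mixture.

    Initialisation splits the sample at its median (equal weights); the
    observed-data log-likelihood is checked to be non-decreasing at every
    iteration.  Fewer than 8 samples, or an all-identical sample, takes
    the degenerate path: both components at the sample mean with
    ``sigma_floor``.  ``seed`` is accepted for interface stability; the
    fit itself is deterministic.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if x.size < MIN_SAMPLES or np.ptp(x) == 0:
        return _degenerate(float(x.mean()))
    med = np.median(x)
    lowmask = x <= med
    if lowmask.all() or not lowmask.any():
        lowmask = x < med
    groups = (x[lowmask], x[~lowmask])
    w = np.array([g.size / x.size for g in groups])
    mu = np.array([g.mean() for g in groups])
    sd = np.maximum([g.std() for g in groups], sigma_floor)

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        comp = w[None, :] * np.exp(
            -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
        ) / (sd[None, :] * _SQRT2PI)
        total = comp.sum(axis=1)
        ll = float(np.log(total + DENSITY_EPS).sum())
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll} at iter {it}"
            )
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        r = comp / total[:, None]
        # M step
        nk = r.sum(axis=0)
        if (nk < 1e-12).any():  # one component starved: collapse to single
            return _degenerate(float(x.mean()), it)
        w = nk / x.size
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sigma_floor)
    order = np.argsort(mu)
    return VoxelGMM(
        weights=(float(w[order[0]]), float(w[order[1]])),
        means=(float(mu[order[0]]), float(mu[order[1]])),
        sigmas=(float(sd[order[0]]), float(sd[order[1]])),
        converged=converged,
        n_iter=it,
    )


class VoxelwiseGMM(BaseEstimator):
    """Bank of per-voxel two-component FLAIR intensity mixtures.

    Parameters
    ----------
    b : int
        Pooling patch edge in voxels.
    n_bins : int
        Intensity histogram bins for the vectorised weighted EM.
    tol, max_iter : EM stopping rule (per voxel, on the log-likelihood).
    sigma_floor : minimum component SD, normalised units.

    Attributes
    ----------
    weights_, means_, sigmas_ : ndarray (n_voxels, 2)
    n_samples_ : ndarray (n_voxels,)  pooled nonzero sample count
    converged_ : ndarray (n_voxels,) of bool
    n_iter_ : ndarray (n_voxels,)
    """

    def __init__(
        self,
        b: int = 5,
        n_bins: int = 200,
        tol: float = 1e-6,
        max_iter: int = 100,
        sigma_floor: float = SIGMA_FLOOR,
        seed: int = 0,
    ):
        self.b = b
        self.n_bins = n_bins
        self.tol = tol
        self.max_iter = max_iter
        self.sigma_floor = sigma_floor
        self.seed = seed

    def fit(self, flair_train: Sequence[VolumeGrid]) -> "VoxelwiseGMM":
        if len(flair_train) == 0:
            raise ValueError("empty training set")
        if len(flair_train) < 2:
            import warnings

            warnings.warn(
                "fitting the GMM bank on a single FLAIR volume: per-voxel "
                "pools carry only one subject", stacklevel=2,
            )
        ref = flair_train[0]
        for i, v in enumerate(flair_train):
            if not v.same_lattice(ref):
                raise ValueError(f"volume {i} is on a different lattice")
        self.shape_ = ref.shape
        self.spacing_ = ref.spacing
        nvox = int(np.prod(ref.shape))
        top = max(float(v.data.max()) for v in flair_train)
        top = max(top, 1.0)
        nb = self.n_bins
        width = top / nb
        centres = (np.arange(nb) + 0.5) * width

        counts = np.zeros((nvox, nb), dtype=np.float32)
        vox_idx = np.arange(nvox)
        for v in flair_train:
            d = v.data.ravel()
            nz = d > 0  # boundary handling: nonzero intensities only
            bins = np.minimum((d[nz] / width).astype(np.int64), nb - 1)
            flat = vox_idx[nz] * nb + bins
            counts.ravel()[:] += np.bincount(flat, minlength=nvox * nb).astype(
                np.float32
            )
        size = (self.b, self.b, self.b, 1)
        counts = (
            ndimage.uniform_filter(
                counts.reshape(ref.shape + (nb,)), size=size, mode="constant",
                cval=0.0,
            )
            * float(self.b**3)
        ).reshape(nvox, nb)
        counts = np.maximum(np.rint(counts), 0.0)

        self.n_samples_ = counts.sum(axis=1)
        self._fit_binned(counts, centres)
        return self

    def _fit_binned(
        self, counts: np.ndarray, centres: np.ndarray, chunk: int = 16384
    ) -> None:
        """Weighted EM over histogram bins, vectorised across voxels.

        Voxels are processed in chunks to bound memory; within a chunk an
        active set drops voxels as their log-likelihood converges.
        """
        nvox, nb = counts.shape
        out = [np.empty((nvox, 2)) for _ in range(3)]
        conv_all = np.zeros(nvox, dtype=bool)
        iter_all = np.zeros(nvox, dtype=np.int32)
        for lo in range(0, nvox, chunk):
            sl = slice(lo, min(lo + chunk, nvox))
            w, mu, sd, cv, it = self._em_chunk(
                np.asarray(counts[sl], dtype=np.float64), centres
            )
            out[0][sl], out[1][sl], out[2][sl] = w, mu, sd
            conv_all[sl], iter_all[sl] = cv, it
        w, mu, sd = out
        order = np.argsort(mu, axis=1)
        rows = np.arange(nvox)[:, None]
        self.weights_ = w[rows, order]
        self.means_ = mu[rows, order]
        self.sigmas_ = sd[rows, order]
        self.converged_ = conv_all
        self.n_iter_ = iter_all

    def _em_chunk(self, counts: np.ndarray, centres: np.ndarray):
        nvox, nb = counts.shape
        n = counts.sum(axis=1)
        w = np.full((nvox, 2), 0.5)
        mu = np.zeros((nvox, 2))
        sd = np.full((nvox, 2), self.sigma_floor)
        conv = np.zeros(nvox, dtype=bool)
        iters = np.zeros(nvox, dtype=np.int32)

        has = n > 0
        mean_all = np.zeros(nvox)
        mean_all[has] = (counts[has] * centres).sum(axis=1) / n[has]
        # degenerate voxels: too few samples or a single occupied bin
        spread = (counts > 0).sum(axis=1)
        degen = has & ((n < MIN_SAMPLES) | (spread < 2))
        mu[degen] = mean_all[degen, None]
        conv[degen | ~has] = True

        active = np.nonzero(has & ~degen)[0]
        if active.size:
            # median-split initialisation on the histogram
            c = counts[active]
            cum = np.cumsum(c, axis=1)
            half = n[active] / 2.0
            medbin = (cum < half[:, None]).sum(axis=1)
            below = np.arange(nb)[None, :] <= medbin[:, None]
            for side, m_ in ((below, 0), (~below, 1)):
                cw = c * side
                ns = cw.sum(axis=1)
                ns = np.maximum(ns, 1e-12)
                m0 = (cw * centres).sum(axis=1) / ns
                v0 = (cw * (centres[None, :] - m0[:, None]) ** 2).sum(axis=1) / ns
                mu[active, m_] = m0
                sd[active, m_] = np.maximum(np.sqrt(v0), self.sigma_floor)
                w[active, m_] = ns / n[active]

        prev_ll = np.full(nvox, -np.inf)
        for it in range(1, self.max_iter + 1):
            if active.size == 0:
                break
            c = counts[active]
            na = n[active]
            dev = (centres[None, :, None] - mu[active, None, :]) / sd[active, None, :]
            comp = (
                w[active, None, :]
                * np.exp(-0.5 * dev * dev)
                / (sd[active, None, :] * _SQRT2PI)
            )
            tot = comp.sum(axis=2)
            ll = (c * np.log(tot + DENSITY_EPS)).sum(axis=1)
            bad = ll < prev_ll[active] - 1e-6 * np.maximum(1.0, np.abs(prev_ll[active]))
            if bad.any():
                raise AssertionError("binned EM log-likelihood decreased")
            # tol acts per pooled sample so voxels with large pools do not
            # need absurdly many iterations
            done = np.abs(ll - prev_ll[active]) < self.tol * na
            prev_ll[active] = ll
            iters[active] = it
            # empty bins can have zero density; their responsibilities are
            # irrelevant (weighted by zero counts) but must stay finite
            r = comp / np.maximum(tot[:, :, None], DENSITY_EPS)
            nk = (c[:, :, None] * r).sum(axis=1)
            starved = (nk < 1e-12).any(axis=1)
            w[active] = nk / na[:, None]
            safe_nk = np.maximum(nk, 1e-12)
            mu_new = (c[:, :, None] * r * centres[None, :, None]).sum(axis=1) / safe_nk
            var = (
                c[:, :, None]
                * r
                * (centres[None, :, None] - mu_new[:, None, :]) ** 2
            ).sum(axis=1) / safe_nk
            mu[active] = mu_new
            sd[active] = np.maximum(np.sqrt(var), self.sigma_floor)
            if starved.any():
                si = active[starved]
                mu[si] = mean_all[si, None]
                sd[si] = self.sigma_floor
                w[si] = 0.5
                done = done | starved
            conv[active[done]] = True
            active = active[~done]

        return w, mu, sd, conv, iters

    # -- evaluation --------------------------------------------------------

    def density(self, flair: VolumeGrid) -> np.ndarray:
        """Per-voxel mixture density evaluated at the observed intensity."""
        if flair.shape != self.shape_:
            raise ValueError(
                f"FLAIR shape {flair.shape} does not match bank {self.shape_}"
            )
        f = flair.data.ravel()[:, None]
        dev = (f - self.means_) / self.sigmas_
        comp = self.weights_ * np.exp(-0.5 * dev * dev) / (self.sigmas_ * _SQRT2PI)
        return comp.sum(axis=1)

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path.with_suffix(".npz"),
            weights=self.weights_, means=self.means_, sigmas=self.sigmas_,
            n_samples=self.n_samples_, converged=self.converged_,
            n_iter=self.n_iter_,
        )
        meta = dict(
            b=self.b, n_bins=self.n_bins, tol=self.tol, max_iter=self.max_iter,
            sigma_floor=self.sigma_floor, seed=self.seed,
            shape=list(self.shape_), spacing=list(self.spacing_),
        )
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "VoxelwiseGMM":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(
            b=meta["b"], n_bins=meta["n_bins"], tol=meta["tol"],
            max_iter=meta["max_iter"], sigma_floor=meta["sigma_floor"],
            seed=meta["seed"],
        )
        with np.load(path.with_suffix(".npz")) as z:
            est.weights_ = z["weights"]
            est.means_ = z["means"]
            est.sigmas_ = z["sigmas"]
            est.n_samples_ = z["n_samples"]
            est.converged_ = z["converged"]
            est.n_iter_ = z["n_iter"]
        est.shape_ = tuple(meta["shape"])
        est.spacing_ = tuple(meta["spacing"])
        return est


def fit_gmm_bank(flair_train: Sequence[VolumeGrid], **params) -> VoxelwiseGMM:
    """Fit the per-voxel GMM bank on normalised training FLAIR volumes."""
    return VoxelwiseGMM(**params).fit(flair_train)


def compute_lflair(
    flair: VolumeGrid,
    bank: VoxelwiseGMM,
    threshold: float = HYPERINTENSITY_THRESHOLD,
    mode: str = "neglog",
) -> VolumeGrid:
    """GMM abnormality map.

    ``mode="neglog"`` (default): negative log mixture density, shifted by
    its minimum over the scored voxels so healthy tissue anchors near 0,
    floored at 0; exactly 0 wherever the intensity is below ``threshold``
    or no model exists (background).  ``mode="density"`` returns the raw
    mixture density on the scored voxels instead (small = abnormal), with
    the same hard zero below the threshold.
    """
    f = flair.data.ravel()
    scored = (f >= threshold) & (bank.n_samples_ > 0)
    out = np.zeros(f.size)
    if scored.any():
        d = bank.density(flair)[scored]
        if mode == "neglog":
            neglog = -np.log(d + DENSITY_EPS)
            out[scored] = np.maximum(neglog - neglog.min(), 0.0)
        elif mode == "density":
            out[scored] = d
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return flair.like(out.reshape(flair.shape))
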