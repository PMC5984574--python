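"""Synthetic co-registered T1/FLAIR phantom cohorts.

The segmentation pipeline is voxel-wise in a common space, so it can be
exercised end-to-end on any reproducible layout that provides the three
tissue classes, a "ventricle" structure, and lesions with the right contrast
signature (hyperintense on FLAIR, optionally hypointense on T1).  The
phantom uses concentric shells on a cubic lattice: a CSF core standing in
for the ventricles, a WM shell, and a GM rim.  Intensities are per-class
Gaussian draws passed through a partial-volume smoothing kernel, with
scanner noise added afterwards.

Healthy subjects can carry periventricular "bands and caps" — benign FLAIR
brightening in a thin shell around the ventricles — which reproduces the
known failure mode where a synthesis model trained on such subjects
hallucinates periventricular hyperintensity.

Tissue probability maps emulate a T1-driven anatomical segmenter: smooth
and near 1 inside each class, and deliberately degraded inside lesions
(whose T1 intensity resembles GM), so lesion voxels never pass a
high-confidence WM filter — the behaviour the lesion-load-invariant
normalisation relies on.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volumes import SubjectBundle, VolumeGrid, write_volume

__all__ = [
    "PhantomParams",
    "PhantomSubject",
    "generate_subject",
    "generate_cohort",
    "generate_atlas",
]

# Tissue class codes in the label image
BG, GM, WM, CSF = 0, 1, 2, 3

#: Shell radii as fractions of the half-extent of the volume.
VENTRICLE_FRAC = 0.25
WM_FRAC = 0.70
GM_FRAC = 0.88

#: Decay length (mm) of the analytic periventricular lesion prior.
ATLAS_TAU_MM = 5.0

#: Width (voxels) of the periventricular shell carrying bands and caps.
BAND_SHELL_VOX = 2

#: Tissue-probability values assigned inside lesions, emulating a T1-based
#: segmenter confusing hypointense lesion tissue with GM.
LESION_WM_PROB = 0.45
LESION_GM_PROB = 0.50


@dataclasses.dataclass
class PhantomParams:
    """Generator settings; same params + seed give a bit-identical subject.

    Intensity values live on an arbitrary pre-normalisation scale of order
    one.  Defaults place FLAIR healthy WM below the post-normalisation
    hyperintensity threshold and lesions well above it.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # per-class (mean, sd) pairs; sd is within-tissue biological variability
    t1_means: dict = dataclasses.field(
        default_factory=lambda: {"WM": 0.85, "GM": 0.60, "CSF": 0.25}
    )
    t1_sds: dict = dataclasses.field(
        default_factory=lambda: {"WM": 0.02, "GM": 0.02, "CSF": 0.02}
    )
    flair_means: dict = dataclasses.field(
        default_factory=lambda: {"WM": 0.70, "GM": 0.85, "CSF": 0.20}
    )
    flair_sds: dict = dataclasses.field(
        default_factory=lambda: {"WM": 0.02, "GM": 0.02, "CSF": 0.02}
    )
    n_lesions: int = 3
    lesion_radius_range: tuple[float, float] = (2.0, 4.0)  # mm
    lesion_flair_contrast: float = 0.30  # additive, hyperintense
    lesion_t1_contrast: float = -0.15  # additive, hypointense
    band_cap_intensity: float = 0.15  # healthy periventricular brightening
    band_prevalence: float = 0.6  # fraction of healthy subjects with bands
    noise_sd: float = 0.02  # additive scanner noise after smoothing
    pv_smoothing_sigma: float = 0.5  # mm, partial-volume blur
    seed: int = 0

    def validate(self) -> "PhantomParams":
        lo, hi = self.lesion_radius_range
        min_sp = min(self.spacing)
        if lo < min_sp:
            raise ValueError(f"lesion radius {lo} mm below one voxel ({min_sp} mm)")
        if hi < lo:
            raise ValueError("lesion_radius_range must be (lo, hi) with hi >= lo")
        for v in (self.lesion_flair_contrast, self.lesion_t1_contrast,
                  self.band_cap_intensity, self.noise_sd):
            if not np.isfinite(v):
                raise ValueError("contrasts and noise_sd must be finite")
        return self


class PhantomSubject(SubjectBundle):
    """A generated subject; ``lesion_truth`` is always present."""


def _radial_mm(shape, spacing):
    centre = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, centre)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(xx * xx + yy * yy + zz * zz)


def _labels(params: PhantomParams):
    r = _radial_mm(params.shape, params.spacing)
    half = min(n * s for n, s in zip(params.shape, params.spacing)) / 2.0
    lab = np.full(params.shape, BG, dtype=np.int8)
    lab[r < GM_FRAC * half] = GM
    lab[r < WM_FRAC * half] = WM
    lab[r < VENTRICLE_FRAC * half] = CSF
    return lab, r, half


def _place_lesions(params: PhantomParams, rng, r_mm, half):
    """Spherical lesion truth mask confined to the WM shell.

    Centres sit on voxel centres; a voxel belongs to a lesion iff the
    Euclidean distance between voxel centres is <= the lesion radius, so the
    voxel count of each lesion equals the discrete-ball count at that
    radius.  Lesions are pairwise disjoint.
    """
    truth = np.zeros(params.shape, dtype=np.float64)
    if params.n_lesions == 0:
        return truth
    r_v, r_wm = VENTRICLE_FRAC * half, WM_FRAC * half
    spacing = np.asarray(params.spacing)
    centre = (np.asarray(params.shape) - 1) / 2.0
    placed: list[tuple[np.ndarray, float]] = []
    lo, hi = params.lesion_radius_range
    max_tries = 2000
    for _ in range(params.n_lesions):
        rad = float(rng.uniform(lo, hi))
        for attempt in range(max_tries):
            idx = np.array([rng.integers(0, n) for n in params.shape])
            d_centre = np.linalg.norm((idx - centre) * spacing)
            # ball must fit strictly inside the WM shell
            if not (r_v + rad + 1.0 <= d_centre <= r_wm - rad - 1.0):
                continue
            if any(
                np.linalg.norm((idx - c) * spacing) <= rad + prev_rad + 1.0
                for c, prev_rad in placed
            ):
                continue
            break
        else:
            raise RuntimeError(
                f"could not place lesion of radius {rad:.2f} mm inside the WM "
                f"shell after {max_tries} attempts; reduce n_lesions or radii"
            )
        placed.append((idx, rad))
        # discrete ball via brute lattice window
        w = tuple(int(np.ceil(rad / s)) for s in spacing)
        sl = tuple(
            slice(max(0, i - wi), min(n, i + wi + 1))
            for i, wi, n in zip(idx, w, params.shape)
        )
        grids = np.meshgrid(
            *[np.arange(s.start, s.stop) for s in sl], indexing="ij"
        )
        dist = np.sqrt(
            sum(((g - i) * s) ** 2 for g, i, s in zip(grids, idx, spacing))
        )
        region = truth[sl]
        region[dist <= rad] = 1.0
        truth[sl] = region
    return truth


def generate_subject(params: PhantomParams) -> PhantomSubject:
    """Generate one co-registered T1/FLAIR pair with maps and truth mask."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    lab, r_mm, half = _labels(params)
    brain = lab != BG

    truth = _place_lesions(params, rng, r_mm, half)

    def tissue_image(means, sds):
        img = np.zeros(params.shape)
        for code, name in ((GM, "GM"), (WM, "WM"), (CSF, "CSF")):
            m = lab == code
            img[m] = means[name] + sds[name] * rng.standard_normal(int(m.sum()))
        return img

    t1 = tissue_image(params.t1_means, params.t1_sds)
    flair = tissue_image(params.flair_means, params.flair_sds)

    t1[truth > 0] += params.lesion_t1_contrast
    flair[truth > 0] += params.lesion_flair_contrast

    ventricle = (lab == CSF).astype(np.float64)
    if params.band_cap_intensity > 0:
        # thin periventricular WM shell of benign brightening
        dil = ndimage.binary_dilation(ventricle > 0, iterations=BAND_SHELL_VOX)
        band = dil & (lab == WM)
        flair[band] += params.band_cap_intensity

    sig = [params.pv_smoothing_sigma / s for s in params.spacing]
    if params.pv_smoothing_sigma > 0:
        t1 = ndimage.gaussian_filter(t1, sig)
        flair = ndimage.gaussian_filter(flair, sig)

    if params.noise_sd > 0:
        t1 = t1 + params.noise_sd * rng.standard_normal(params.shape)
        flair = flair + params.noise_sd * rng.standard_normal(params.shape)
    t1[~brain] = 0.0
    flair[~brain] = 0.0
    t1 = np.clip(t1, 0.0, None)
    flair = np.clip(flair, 0.0, None)

    def prob_map(code):
        p = (lab == code).astype(np.float64)
        if params.pv_smoothing_sigma > 0:
            p = ndimage.gaussian_filter(p, sig)
        return np.clip(p, 0.0, 1.0)

    wm_prob = prob_map(WM)
    gm_prob = prob_map(GM)
    # segmenter confusion inside lesions: T1 there looks GM-like
    les = truth > 0
    wm_prob[les] = LESION_WM_PROB
    gm_prob[les] = LESION_GM_PROB

    # analytic periventricular lesion prior: exp(-d/tau) outside the
    # ventricles, zero inside them and outside the brain
    d_out = ndimage.distance_transform_edt(ventricle == 0, sampling=params.spacing)
    atlas = np.exp(-d_out / ATLAS_TAU_MM)
    atlas[ventricle > 0] = 0.0
    atlas[~brain] = 0.0

    sp = params.spacing
    return PhantomSubject(
        t1=VolumeGrid(t1, sp),
        flair=VolumeGrid(flair, sp),
        wm_prob=VolumeGrid(wm_prob, sp),
        gm_prob=VolumeGrid(gm_prob, sp),
        ventricle_mask=VolumeGrid(ventricle, sp),
        atlas=VolumeGrid(atlas, sp),
        lesion_truth=VolumeGrid(truth, sp),
    )


def generate_cohort(
    n: int, params: PhantomParams, healthy: bool = False
) -> list[PhantomSubject]:
    """Generate ``n`` subjects with per-subject seeds fanned out from
    ``params.seed``.

    ``healthy=True`` forces zero lesions; a ``band_prevalence`` fraction of
    the healthy subjects carry the periventricular band/cap brightening
    (benign brightening is common in ageing cohorts but not universal, and
    a one-class model must see both periventricular states as normal).
    ``healthy=False`` keeps lesions and drops the bands (the band term
    exists to contaminate the *training* set).
    """
    if n < 1:
        raise ValueError("need n >= 1 subjects")
    seeds = np.random.SeedSequence(params.seed).generate_state(n) % (2**31)
    band_rng = np.random.default_rng(params.seed)
    out = []
    for s in seeds:
        p = dataclasses.replace(params, seed=int(s))
        if healthy:
            has_band = band_rng.random() < params.band_prevalence
            p = dataclasses.replace(
                p,
                n_lesions=0,
                band_cap_intensity=p.band_cap_intensity if has_band else 0.0,
            )
        else:
            p = dataclasses.replace(p, band_cap_intensity=0.0)
        out.append(generate_subject(p))
    return out


def generate_atlas(cohort: Sequence[SubjectBundle]) -> VolumeGrid:
    """Population lesion-frequency atlas.

    Voxel-wise mean of the cohort's truth masks; when every subject is
    lesion-free the mean of the analytic periventricular priors is returned
    instead (they coincide across subjects of identical geometry).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    ref = cohort[0].t1
    truths = [s.lesion_truth for s in cohort if s.lesion_truth is not None]
    if truths and any(t.data.any() for t in truths):
        data = np.mean([t.data for t in truths], axis=0)
    else:
        data = np.mean([s.atlas.data for s in cohort], axis=0)
    return VolumeGrid(np.clip(data, 0.0, 1.0), ref.spacing)


def write_cohort(cohort: Sequence[SubjectBundle], out_dir) -> None:
    """Write one NIfTI set per subject plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, subj in enumerate(cohort):
        sub = out_dir / f"subject_{i:03d}"
        entry = {"id": f"subject_{i:03d}"}
        for name, vol in subj.members().items():
            p = sub / f"{name}.nii.gz"
            write_volume(vol, p)
            entry[name] = str(p.relative_to(out_dir))
        manifest.append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
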