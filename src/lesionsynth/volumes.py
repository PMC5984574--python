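"""Volume data model and NIfTI I/O.

Every image in the pipeline — T1-w, FLAIR, likelihood maps, masks,
probability maps — travels as a :class:`VolumeGrid`: a 3-D scalar field on a
fixed voxel lattice with isotropic-or-not spacing in mm.  All cross-volume
operations in the package require identical shape and spacing; there is no
implicit resampling, so voxel correspondence between volumes is always the
identity.  Masks are stored as {0,1} volumes and probabilities as real
volumes in [0,1]; the distinction is a role, not a storage format.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "SubjectBundle",
    "read_volume",
    "write_volume",
    "check_bundle",
]


@dataclasses.dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel spacing in mm.

    Parameters
    ----------
    data : ndarray of shape (nx, ny, nz)
        Finite voxel intensities (arbitrary or normalised units).
    spacing : tuple of 3 floats
        Voxel edge length per axis, mm; strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid needs a 3-D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            idx = tuple(int(i) for i in np.argwhere(~np.isfinite(self.data))[0])
            raise ValueError(f"non-finite intensity at voxel {idx}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same lattice and different data."""
        return VolumeGrid(np.asarray(data, dtype=np.float64), self.spacing)

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.spacing)

    def same_lattice(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )


def _require_same_lattice(name: str, v: VolumeGrid, ref: VolumeGrid) -> None:
    if v.shape != ref.shape:
        raise ValueError(f"{name}: shape {v.shape} does not match reference {ref.shape}")
    if not v.same_lattice(ref):
        raise ValueError(
            f"{name}: spacing {v.spacing} does not match reference {ref.spacing}"
        )


@dataclasses.dataclass
class SubjectBundle:
    """Per-subject inputs: co-registered, skull-stripped volume set.

    All members share one lattice.  ``lesion_truth`` is optional; when
    present it is a {0,1} reference mask (phantoms always carry one).
    """

    t1: VolumeGrid
    flair: VolumeGrid
    wm_prob: VolumeGrid
    gm_prob: VolumeGrid
    ventricle_mask: VolumeGrid
    atlas: VolumeGrid
    lesion_truth: Optional[VolumeGrid] = None

    def members(self) -> dict[str, VolumeGrid]:
        out = {
            "t1": self.t1,
            "flair": self.flair,
            "wm_prob": self.wm_prob,
            "gm_prob": self.gm_prob,
            "ventricle_mask": self.ventricle_mask,
            "atlas": self.atlas,
        }
        if self.lesion_truth is not None:
            out["lesion_truth"] = self.lesion_truth
        return out


def check_bundle(bundle: SubjectBundle) -> SubjectBundle:
    """Validate lattice consistency and value ranges; return the bundle.

    Raises
    ------
    ValueError
        Naming the offending member on shape/spacing mismatch, a probability
        outside [0,1], or a non-binary mask.
    """
    ref = bundle.t1
    for name, vol in bundle.members().items():
        _require_same_lattice(name, vol, ref)
    for name in ("wm_prob", "gm_prob", "atlas"):
        d = getattr(bundle, name).data
        if d.min() < 0.0 or d.max() > 1.0:
            raise ValueError(
                f"{name}: values outside [0,1] (min={d.min():.4g}, max={d.max():.4g})"
            )
    for name in ("ventricle_mask", "lesion_truth"):
        vol = getattr(bundle, name)
        if vol is None:
            continue
        d = vol.data
        if not np.all((d == 0) | (d == 1)):
            raise ValueError(f"{name}: mask is not binary {{0,1}}")
    return bundle


def read_volume(path) -> VolumeGrid:
    """Read a 3-D NIfTI-1 volume.

    Spacing is taken from the header zooms; intensities are passed through
    unchanged.  Non-3-D payloads and non-finite voxels are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(data))[0])
        raise ValueError(f"{path}: non-finite intensity at voxel {idx}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(data, spacing)


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine from the spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
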