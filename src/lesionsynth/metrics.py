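"""Segmentation evaluation battery.

Overlap (Dice, precision, recall), surface distances (average symmetric
surface distance and Hausdorff distance between 6-connected boundary
voxels, Euclidean in mm), volume agreement (ICC(A,1), Bland-Altman
statistics on intracranial-volume-normalised lesion loads), rank
correlation with combined Fazekas scores, and Dice binned by lesion or
subject volume.

Empty-mask conventions: both masks empty gives Dice/precision/recall of 1;
exactly one empty gives Dice 0 and undefined (missing) surface distances.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .volumes import VolumeGrid

__all__ = [
    "SegPair",
    "overlap_metrics",
    "surface_metrics",
    "icc_a1",
    "volume_binned_dsc",
    "agreement_stats",
    "fazekas_correlation",
    "evaluate_cohort",
    "LESION_BINS_ML",
    "SUBJECT_BINS_ML",
]

#: Lesion-volume bin edges (ml): very small, small, medium, large, very large.
LESION_BINS_ML = (0.01, 0.1, 1.0, 10.0)
LESION_BIN_LABELS = ("<0.01", "0.01-0.1", "0.1-1", "1-10", ">=10")

#: Subject total-volume bin edges (ml).
SUBJECT_BINS_ML = (5.0, 10.0, 15.0)
SUBJECT_BIN_LABELS = ("<5", "5-10", "10-15", ">15")

#: 26-connectivity structure for lesion components.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass
class SegPair:
    """Computed mask V_a against reference mask V_t on one lattice."""

    computed: VolumeGrid
    reference: VolumeGrid

    def __post_init__(self):
        if not self.computed.same_lattice(self.reference):
            raise ValueError("computed and reference masks on different lattices")
        for name in ("computed", "reference"):
            d = getattr(self, name).data
            if not np.all((d == 0) | (d == 1)):
                raise ValueError(f"{name} mask is not binary")

    @property
    def voxel_volume_ml(self) -> float:
        return self.computed.voxel_volume_ml


def overlap_metrics(pair: SegPair) -> dict[str, float]:
    """Dice, precision and recall of a mask pair."""
    a = pair.computed.data > 0
    t = pair.reference.data > 0
    na, nt = int(a.sum()), int(t.sum())
    inter = int((a & t).sum())
    if na == 0 and nt == 0:
        return {"dsc": 1.0, "precision": 1.0, "recall": 1.0}
    dsc = 2.0 * inter / (na + nt)
    precision = inter / na if na else 0.0
    recall = inter / nt if nt else 0.0
    return {"dsc": dsc, "precision": precision, "recall": recall}


def _surface_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Boundary voxels: mask voxels with a 6-neighbour outside the mask."""
    er = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    pts = np.argwhere(mask & ~er)
    return pts * np.asarray(spacing)


def surface_metrics(pair: SegPair) -> dict[str, float]:
    """ASSD and Hausdorff distance in mm between mask surfaces.

    ASSD is the mean of the two directed mean minimum distances; HD the
    max of the two directed maxima.  Raises on an empty mask (the caller
    reports the metric as missing).
    """
    a = pair.computed.data > 0
    t = pair.reference.data > 0
    if not a.any() or not t.any():
        raise ValueError("surface metrics are undefined for an empty mask")
    sp = pair.computed.spacing
    pa = _surface_points_mm(a, sp)
    pt = _surface_points_mm(t, sp)
    d_at = cKDTree(pt).query(pa)[0]
    d_ta = cKDTree(pa).query(pt)[0]
    return {
        "assd": float(0.5 * (d_at.mean() + d_ta.mean())),
        "hd": float(max(d_at.max(), d_ta.max())),
    }


def icc_a1(volumes_a: Sequence[float], volumes_t: Sequence[float]) -> float:
    """ICC(A,1): two-way mixed model, absolute agreement, single measure.

    Computed from the two-rater ANOVA decomposition (McGraw & Wong):
    ``(MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E))``.
    """
    a = np.asarray(volumes_a, dtype=np.float64)
    t = np.asarray(volumes_t, dtype=np.float64)
    if a.size != t.size:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 subjects")
    data = np.column_stack([a, t])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e)
    if denom == 0:
        return 1.0 if ms_r == ms_e else 0.0
    return float((ms_r - ms_e) / denom)


def volume_binned_dsc(
    pairs: Sequence[SegPair], mode: str = "lesion"
) -> dict[str, float]:
    """Mean Dice per volume bin.

    ``mode="lesion"``: reference-mask connected components (26-conn) are
    binned by their volume and Dice is computed inside each component's
    axis-aligned bounding box.  ``mode="subject"``: subjects are binned by
    total reference volume and whole-volume Dice is averaged per bin.
    Empty bins are absent from the result.
    """
    acc: dict[str, list[float]] = {}
    if mode == "lesion":
        for pair in pairs:
            ref = pair.reference.data > 0
            comp = pair.computed.data
            lab, nlab = ndimage.label(ref, structure=CONN26)
            for sl, li in zip(ndimage.find_objects(lab), range(1, nlab + 1)):
                vol_ml = int((lab == li).sum()) * pair.voxel_volume_ml
                label = LESION_BIN_LABELS[
                    int(np.searchsorted(LESION_BINS_ML, vol_ml, side="right"))
                ]
                sub = SegPair(
                    computed=VolumeGrid(comp[sl], pair.computed.spacing),
                    reference=VolumeGrid(
                        (lab[sl] == li).astype(float), pair.reference.spacing
                    ),
                )
                acc.setdefault(label, []).append(overlap_metrics(sub)["dsc"])
    elif mode == "subject":
        for pair in pairs:
            vol_ml = int((pair.reference.data > 0).sum()) * pair.voxel_volume_ml
            label = SUBJECT_BIN_LABELS[
                int(np.searchsorted(SUBJECT_BINS_ML, vol_ml, side="right"))
            ]
            acc.setdefault(label, []).append(overlap_metrics(pair)["dsc"])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {k: float(np.mean(v)) for k, v in acc.items()}


def agreement_stats(
    volumes_a: Sequence[float],
    volumes_t: Sequence[float],
    icv: Sequence[float],
) -> dict[str, float]:
    """Bland-Altman and best-fit summary on ICV-normalised volumes.

    Differences follow the ratio convention
    ``d = (va - vt) / (0.5 (va + vt))`` on normalised volumes
    ``v = V / V_ic``; RPC = 1.96 SD(d); CV = 100 SD(d) / mean of the
    pairwise averages; the mean difference carries a two-sided one-sample
    t-test p-value.
    """
    va = np.asarray(volumes_a, dtype=np.float64)
    vt = np.asarray(volumes_t, dtype=np.float64)
    ic = np.asarray(icv, dtype=np.float64)
    if not (va.size == vt.size == ic.size):
        raise ValueError("length mismatch")
    if (ic <= 0).any():
        raise ValueError("intracranial volumes must be positive")
    x = vt / ic
    y = va / ic
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance volumes: r^2 undefined")
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    sse = float(((y - (slope * x + intercept)) ** 2).sum())
    mean_pair = 0.5 * (y + x)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (y - x) / mean_pair
    d = d[np.isfinite(d)]
    sd_d = float(d.std(ddof=1)) if d.size > 1 else 0.0
    if d.size > 1 and sd_d > 0:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        p = float("nan")
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": float(r * r),
        "sse": sse,
        "rpc": 1.96 * sd_d,
        "cv": 100.0 * sd_d / float(mean_pair.mean()) if mean_pair.mean() else float("nan"),
        "mean_diff": float(d.mean()) if d.size else float("nan"),
        "mean_diff_p": p,
    }


def fazekas_correlation(
    volumes_a: Sequence[float],
    icv: Sequence[float],
    fazekas: Sequence[int],
) -> float:
    """Spearman rank correlation between normalised lesion volume and the
    combined (periventricular + deep, 0-6) Fazekas score."""
    va = np.asarray(volumes_a, dtype=np.float64)
    ic = np.asarray(icv, dtype=np.float64)
    fz = np.asarray(fazekas)
    if not np.all((fz >= 0) & (fz <= 6) & (fz == fz.astype(int))):
        raise ValueError("Fazekas scores must be integers in [0, 6]")
    v = va / ic
    if np.ptp(v) == 0 or np.ptp(fz) == 0:
        return float("nan")  # undefined: zero variance
    return float(stats.spearmanr(v, fz).statistic)


def evaluate_cohort(
    pairs: Sequence[SegPair],
    icv: Optional[Sequence[float]] = None,
    fazekas: Optional[Sequence[int]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-subject metric table plus cohort summary."""
    rows = []
    for i, pair in enumerate(pairs):
        row = {"subject": i}
        row.update(overlap_metrics(pair))
        try:
            row.update(surface_metrics(pair))
        except ValueError:
            row.update({"assd": np.nan, "hd": np.nan})
        row["volume_computed_ml"] = float(
            (pair.computed.data > 0).sum() * pair.voxel_volume_ml
        )
        row["volume_reference_ml"] = float(
            (pair.reference.data > 0).sum() * pair.voxel_volume_ml
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    va = table["volume_computed_ml"].to_numpy()
    vt = table["volume_reference_ml"].to_numpy()
    summary: dict = {
        "mean_dsc": float(table["dsc"].mean()),
        "mean_assd": float(table["assd"].mean()),
        "mean_hd": float(table["hd"].mean()),
        "mean_precision": float(table["precision"].mean()),
        "mean_recall": float(table["recall"].mean()),
        "dsc_by_lesion_volume": volume_binned_dsc(pairs, "lesion"),
        "dsc_by_subject_volume": volume_binned_dsc(pairs, "subject"),
    }
    if len(pairs) >= 3 and np.ptp(vt) > 0:
        summary["icc_a1"] = icc_a1(va, vt)
    if icv is not None:
        try:
            summary["bland_altman"] = agreement_stats(va, vt, icv)
        except ValueError:
            summary["bland_altman"] = None
        if fazekas is not None:
            summary["fazekas_spearman"] = fazekas_correlation(va, icv, fazekas)
    return table, summary
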