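"""Tumor-size indexes and objective-response categorization.

Per reader and patient, six longitudinal indexes are computed between the
baseline (pre) and restaging (post) timepoints:

``%dSLD``   percent change in the longest axial diameter (RECIST index);
``%dSDP``   percent change in the product of longest and perpendicular
            axial diameters (WHO index);
``%dV_seg`` percent change in directly segmented tumor volume;
``%dV_reg`` percent change in tumor volume where the post volume is the
            baseline tumor mask propagated by deformable registration;
``dB_seg``  change in tumor burden, the tumor/pancreas volume ratio
            difference (post minus pre) in percentage points, from direct
            segmentations;
``dB_reg``  the same burden change with the registered tumor volume in
            place of the post segmentation.

The study concerns a solitary lesion, so the "sums" SLD and SDP reduce to
the single longest diameter and the single diameter product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .imaging import LabelMask, ReaderAnnotation, mask_volume
from .registration import DeformationField, warp_mask

__all__ = [
    "DiameterResult",
    "ResponseRecord",
    "longest_axial_diameter",
    "perpendicular_diameter",
    "percent_change",
    "tumor_burden_change",
    "registered_post_volume",
    "recist_category",
    "who_category",
    "build_response_records",
    "records_to_frame",
]

CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class DiameterResult:
    """Longest in-plane diameter of a mask: length, slice, and endpoints."""

    length: float  # mm
    slice_index: int
    endpoints: tuple[tuple[int, int], tuple[int, int]]  # voxel (i, j) pairs


def _slice_points(mask_2d: np.ndarray) -> np.ndarray:
    return np.argwhere(mask_2d)


def _max_pair(points_vox: np.ndarray, sx: float, sy: float) -> tuple[float, tuple, tuple]:
    """Maximum pairwise center distance within one slice, with deterministic ties.

    Uses the convex hull to prune candidates (the farthest pair is always a
    pair of hull vertices), falling back to all points for degenerate
    inputs; ties resolved to the lexicographically smallest ordered
    endpoint pair.
    """
    pts_mm = points_vox * np.array([sx, sy])
    cand = points_vox
    if len(points_vox) > 16:
        try:
            hull = ConvexHull(pts_mm)
            cand = points_vox[hull.vertices]
        except QhullError:
            cand = points_vox  # collinear / degenerate
    cand_mm = cand * np.array([sx, sy])
    d = cand_mm[:, None, :] - cand_mm[None, :, :]
    dist = np.sqrt((d**2).sum(axis=-1))
    dmax = float(dist.max())
    ii, jj = np.nonzero(dist >= dmax - 1e-9)
    pairs = []
    for a, b in zip(ii, jj):
        if a == b and dmax > 0:
            continue
        p, q = tuple(cand[a]), tuple(cand[b])
        pairs.append((min(p, q), max(p, q)))
    p, q = min(pairs)
    return dmax, p, q


def longest_axial_diameter(mask: LabelMask) -> DiameterResult:
    """Longest axial-plane diameter of a lesion mask.

    For every axial slice, the maximum Euclidean distance (mm) between
    centers of lesion voxels in that slice; the global maximum is
    returned.  Ties are broken by lowest slice index, then by
    lexicographic endpoint order.  A single-voxel slice has diameter 0.
    """
    if mask.is_empty():
        raise ValueError("empty mask has no diameter")
    sx, sy, _ = mask.spacing
    best: DiameterResult | None = None
    for k in range(mask.shape[2]):
        pts = _slice_points(mask.voxels[:, :, k])
        if len(pts) == 0:
            continue
        if len(pts) == 1:
            d, p, q = 0.0, tuple(pts[0]), tuple(pts[0])
        else:
            d, p, q = _max_pair(pts, sx, sy)
        if best is None or d > best.length + 1e-9:
            best = DiameterResult(d, k, (p, q))
    assert best is not None
    return best


def perpendicular_diameter(mask: LabelMask, longest: DiameterResult) -> float:
    """Extent of the lesion perpendicular to its longest diameter.

    In the slice attaining the longest diameter, all lesion voxel centers
    are projected onto the in-plane unit vector perpendicular to the
    longest-diameter direction; the result is max − min of the projections
    in mm (0 for degenerate slices).
    """
    if mask.is_empty():
        raise ValueError("empty mask has no diameter")
    sx, sy, _ = mask.spacing
    (p1, p2) = longest.endpoints
    v = np.array([(p2[0] - p1[0]) * sx, (p2[1] - p1[1]) * sy])
    norm = np.linalg.norm(v)
    if norm == 0:
        return 0.0
    perp = np.array([-v[1], v[0]]) / norm
    pts = _slice_points(mask.voxels[:, :, longest.slice_index]).astype(float)
    proj = pts[:, 0] * sx * perp[0] + pts[:, 1] * sy * perp[1]
    return float(proj.max() - proj.min())


def percent_change(pre: float, post: float) -> float:
    """``(post − pre) / pre × 100``; requires ``pre > 0``."""
    if pre <= 0:
        raise ValueError(f"baseline value must be > 0, got {pre}")
    return (post - pre) / pre * 100.0


def tumor_burden_change(v_t_pre: float, v_p_pre: float, v_t_post: float, v_p_post: float) -> float:
    """Change in tumor burden: tumor/pancreas volume-ratio difference, percentage points."""
    if v_p_pre <= 0 or v_p_post <= 0:
        raise ValueError("pancreas volumes must be > 0")
    if v_t_pre < 0 or v_t_post < 0:
        raise ValueError("tumor volumes must be >= 0")
    return (v_t_post / v_p_post - v_t_pre / v_p_pre) * 100.0


def registered_post_volume(tumor_pre: LabelMask, field: DeformationField) -> float:
    """Post volume (mm³) of the baseline tumor mask propagated through ``field``."""
    return mask_volume(warp_mask(tumor_pre, field))


def recist_category(index_pct: float, post_size: float) -> str:
    """RECIST v1.1 category from an index-score percent change.

    CR if the lesion disappeared (``post_size == 0``); PR if the index
    dropped by at least 30%; PD if it rose by at least 20%; SD otherwise.
    Thresholds are inclusive ("at least 30%/20%").  Applies identically
    whether the index is the diameter change or a volumetric substitute.
    """
    if post_size == 0:
        return "CR"
    if not np.isfinite(index_pct):
        raise ValueError("non-finite index score for a non-vanished lesion")
    if index_pct >= 20.0:
        return "PD"
    if index_pct <= -30.0:
        return "PR"
    return "SD"


def who_category(pct_dsdp: float, post_sdp: float) -> str:
    """WHO bidimensional category: CR on disappearance, PR at ≤ −50%, PD at ≥ +25%."""
    if post_sdp == 0:
        return "CR"
    if not np.isfinite(pct_dsdp):
        raise ValueError("non-finite index score for a non-vanished lesion")
    if pct_dsdp >= 25.0:
        return "PD"
    if pct_dsdp <= -50.0:
        return "PR"
    return "SD"


@dataclass(frozen=True)
class ResponseRecord:
    """All size indexes and response categories for one patient × reader."""

    patient_id: str
    reader_id: str
    experience: str
    sld_pre: float
    sld_post: float
    sdp_pre: float
    sdp_post: float
    v_tumor_pre: float
    v_tumor_post_seg: float
    v_tumor_post_reg: float
    v_pancreas_pre: float
    v_pancreas_post: float
    pct_dsld: float
    pct_dsdp: float
    pct_dv_seg: float
    pct_dv_reg: float
    db_seg: float
    db_reg: float
    recist_sld: str
    who_sdp: str
    recist_vseg: str
    recist_vreg: str


_RECORD_COLUMNS = [f.strip() for f in ResponseRecord.__dataclass_fields__]


def _make_record(
    patient_id: str,
    pre: ReaderAnnotation,
    post: ReaderAnnotation,
    field: DeformationField,
) -> ResponseRecord:
    v_t_pre = mask_volume(pre.tumor_mask)
    v_t_post = mask_volume(post.tumor_mask)
    v_p_pre = mask_volume(pre.pancreas_mask)
    v_p_post = mask_volume(post.pancreas_mask)
    v_t_reg = registered_post_volume(pre.tumor_mask, field)
    sld_pre, sld_post = pre.longest_diameter, post.longest_diameter
    sdp_pre = pre.longest_diameter * pre.perpendicular_diameter
    sdp_post = post.longest_diameter * post.perpendicular_diameter
    pct_dsld = percent_change(sld_pre, sld_post)
    pct_dsdp = percent_change(sdp_pre, sdp_post)
    pct_dv_seg = percent_change(v_t_pre, v_t_post)
    pct_dv_reg = percent_change(v_t_pre, v_t_reg)
    return ResponseRecord(
        patient_id=patient_id,
        reader_id=pre.reader_id,
        experience=pre.experience,
        sld_pre=sld_pre,
        sld_post=sld_post,
        sdp_pre=sdp_pre,
        sdp_post=sdp_post,
        v_tumor_pre=v_t_pre,
        v_tumor_post_seg=v_t_post,
        v_tumor_post_reg=v_t_reg,
        v_pancreas_pre=v_p_pre,
        v_pancreas_post=v_p_post,
        pct_dsld=pct_dsld,
        pct_dsdp=pct_dsdp,
        pct_dv_seg=pct_dv_seg,
        pct_dv_reg=pct_dv_reg,
        db_seg=tumor_burden_change(v_t_pre, v_p_pre, v_t_post, v_p_post),
        db_reg=tumor_burden_change(v_t_pre, v_p_pre, v_t_reg, v_p_post),
        recist_sld=recist_category(pct_dsld, sld_post),
        who_sdp=who_category(pct_dsdp, sdp_post),
        recist_vseg=recist_category(pct_dv_seg, v_t_post),
        recist_vreg=recist_category(pct_dv_reg, v_t_reg),
    )


def build_response_records(
    annotations: Mapping[tuple[str, str, str], ReaderAnnotation],
    fields: Mapping[str, DeformationField],
) -> list[ResponseRecord]:
    """Assemble one :class:`ResponseRecord` per patient × reader.

    Parameters
    ----------
    annotations :
        Mapping ``(patient_id, reader_id, timepoint) -> ReaderAnnotation``
        with both ``"pre"`` and ``"post"`` present for every pair.
    fields :
        One registration field per patient (fixed = post, moving = pre);
        the same field serves every reader of that patient.
    """
    pairs = sorted({(p, r) for (p, r, _t) in annotations})
    records = []
    for patient_id, reader_id in pairs:
        try:
            pre = annotations[(patient_id, reader_id, "pre")]
            post = annotations[(patient_id, reader_id, "post")]
        except KeyError as e:
            raise KeyError(f"missing annotation for patient {patient_id}, reader {reader_id}: {e}") from None
        if patient_id not in fields:
            raise KeyError(f"missing deformation field for patient {patient_id}")
        records.append(_make_record(patient_id, pre, post, fields[patient_id]))
    return records


def records_to_frame(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=_RECORD_COLUMNS)
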