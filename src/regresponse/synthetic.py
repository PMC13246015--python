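"""Synthetic multi-reader response study generator.

Builds everything a desk-scale reliability study needs, with known ground
truth at every stage:

1. a CT-like abdominal phantom per patient — an elongated curved pancreas
   containing a low-contrast ellipsoidal tumor (organ ≈ 90, tumor ≈ 70,
   background ≈ 30 HU-like units, Gaussian noise);
2. a known diffeomorphic interval deformation composed of a global smooth
   random warp and a local radial contraction calibrated so the tumor
   changes volume by a prescribed ratio ρ;
3. multi-reader segmentations with experience-dependent boundary noise:
   each reader's mask is a level set of the true signed distance function
   perturbed by a smooth random field, plus a signed systematic offset
   (negative = under-segmentation);
4. per-reader axial diameter annotations derived from the reader's own
   tumor mask, plus a ground-truth "pathology" diameter;
5. survival outcomes whose hazard depends on the true tumor-burden change.

Randomness is organized as one independent stream per (patient, reader,
timepoint, structure), derived from the master seed by stable hashing, so
adding readers or patients never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import ndimage

from . import _fields, response
from .config import ReaderNoiseParams, StudyConfig
from .imaging import (
    LabelMask,
    ReaderAnnotation,
    SurvivalRecord,
    VolumeImage,
    annotations_to_frame,
    mask_volume,
    write_annotations,
    write_mask,
    write_survival,
    write_volume,
)
from .registration import DeformationField, jacobian_determinant, warp_mask

__all__ = [
    "PatientTruth",
    "PatientData",
    "Cohort",
    "make_phantom",
    "make_interval_deformation",
    "simulate_reader",
    "generate_cohort",
    "write_cohort",
]

# stream tags for stable per-component seeding
_TAG_PHANTOM = 1
_TAG_RHO = 2
_TAG_DEFORM = 3
_TAG_READER = 10
_TAG_SURVIVAL = 5

_STRUCTURES = ("pancreas", "tumor")
_TIMEPOINTS = ("pre", "post")


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


@dataclass(frozen=True)
class PatientTruth:
    """Ground truth for one synthetic patient."""

    pre_image: VolumeImage
    post_image: VolumeImage
    true_pancreas_pre: LabelMask
    true_pancreas_post: LabelMask
    true_tumor_pre: LabelMask
    true_tumor_post: LabelMask
    true_deformation: DeformationField
    true_volume_ratio: float  # measured on the rasterized masks
    rho_target: float
    true_pathology_diameter: float  # mm, longest axial diameter of true post tumor

    def __post_init__(self) -> None:
        if abs(self.true_volume_ratio - self.rho_target) > 0.05 * self.rho_target:
            raise ValueError(
                f"rasterized volume ratio {self.true_volume_ratio:.3f} misses target "
                f"{self.rho_target:.3f} by more than 5%"
            )
        if np.any(self.true_tumor_pre.voxels & ~self.true_pancreas_pre.voxels):
            raise ValueError("true pre tumor extends outside the pancreas")

    @property
    def true_pct_dv(self) -> float:
        return (self.true_volume_ratio - 1.0) * 100.0

    @property
    def true_db(self) -> float:
        return response.tumor_burden_change(
            mask_volume(self.true_tumor_pre),
            mask_volume(self.true_pancreas_pre),
            mask_volume(self.true_tumor_post),
            mask_volume(self.true_pancreas_post),
        )


@dataclass(frozen=True)
class PatientData:
    patient_id: str
    truth: PatientTruth
    annotations: dict  # (reader_id, timepoint) -> ReaderAnnotation


@dataclass(frozen=True)
class Cohort:
    """A fully simulated study: patients, reader annotations, outcomes."""

    config: StudyConfig
    patients: tuple[PatientData, ...]
    survival: tuple[SurvivalRecord, ...]

    def annotation_mapping(self) -> dict:
        """Flatten to ``(patient_id, reader_id, timepoint) -> ReaderAnnotation``."""
        out = {}
        for p in self.patients:
            for (rid, tp), ann in p.annotations.items():
                out[(p.patient_id, rid, tp)] = ann
        return out

    def reader_ids(self, experience: str | None = None) -> list[str]:
        return [r.reader_id for r in self.config.readers if experience in (None, r.experience)]

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "rho": p.truth.true_volume_ratio,
                    "true_pct_dv": p.truth.true_pct_dv,
                    "true_db": p.truth.true_db,
                    "pathology_diameter_mm": p.truth.true_pathology_diameter,
                }
                for p in self.patients
            ]
        )


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


def _physical_grid(shape, spacing):
    idx = np.indices(shape, dtype=np.float64)
    return idx * np.asarray(spacing).reshape(3, 1, 1, 1)


def make_phantom(
    config: StudyConfig, seed_key: tuple[int, ...]
) -> tuple[VolumeImage, LabelMask, LabelMask]:
    """Build one baseline phantom: image, pancreas mask, tumor mask.

    The pancreas is a curved tube of tapering radius along the x axis; the
    tumor is an axis-aligned ellipsoid centered on the organ centerline.
    Deterministic given the seed key.
    """
    shape = tuple(config.grid_shape)
    spacing = tuple(config.spacing)
    if any(n < m for n, m in zip(shape, (64, 64, 24))):
        raise ValueError(f"phantom grid must be at least 64x64x24, got {shape}")
    rng = _rng(*seed_key)
    ext = np.array(shape) * np.array(spacing)  # physical extent, mm

    # organ centerline and tapering radius, with mild per-patient jitter
    t = np.linspace(0.0, 1.0, 192)
    amp = 0.08 * ext[1] * rng.uniform(0.85, 1.15)
    cx = ext[0] * (0.15 + 0.70 * t)
    cy = ext[1] * 0.5 + amp * np.sin(np.pi * t)
    cz = ext[2] * 0.5 + 0.05 * ext[2] * (t - 0.5) * rng.uniform(-1, 1)
    r_head, r_tail = 13.0, 9.0
    radius = (r_head - (r_head - r_tail) * t) * rng.uniform(0.95, 1.15)

    # distance to the rasterized centerline (anisotropic EDT), radius taken
    # from the nearest centerline sample
    line = np.zeros(shape, dtype=bool)
    rad_at = np.zeros(shape, dtype=np.float64)
    iv = np.clip(np.round(cx / spacing[0]).astype(int), 0, shape[0] - 1)
    jv = np.clip(np.round(cy / spacing[1]).astype(int), 0, shape[1] - 1)
    kv = np.clip(np.round(cz / spacing[2]).astype(int), 0, shape[2] - 1)
    line[iv, jv, kv] = True
    rad_at[iv, jv, kv] = radius  # later samples overwrite earlier at shared voxels
    dist, (ni, nj, nk) = ndimage.distance_transform_edt(
        ~line, sampling=spacing, return_indices=True
    )
    pancreas = dist <= rad_at[ni, nj, nk]

    # tumor: ellipsoid on the centerline where the organ runs straight
    tc = 0.45
    center = np.array(
        [np.interp(tc, t, cx), np.interp(tc, t, cy), np.interp(tc, t, cz)]
    )
    jit = config.tumor_semiaxes_jitter
    axes = np.asarray(config.tumor_semiaxes) * rng.uniform(1 - jit, 1 + jit, size=3)
    if axes[0] < 3 * spacing[0] or axes[1] < 3 * spacing[1]:
        raise ValueError("tumor radius below 3 in-plane voxels")
    pos = _physical_grid(shape, spacing)
    d = (pos - center.reshape(3, 1, 1, 1)) / axes.reshape(3, 1, 1, 1)
    tumor = (d**2).sum(axis=0) <= 1.0

    if np.any(tumor & ~pancreas):
        raise ValueError("tumor does not fit inside pancreas for requested radii")

    img = np.full(shape, config.background_intensity, dtype=np.float64)
    img[pancreas] = config.pancreas_intensity
    img[tumor] = config.tumor_intensity
    if config.image_noise_sigma > 0:
        img += rng.normal(0.0, config.image_noise_sigma, size=shape)
    if config.image_smoothing_voxels > 0:
        img = ndimage.gaussian_filter(img, sigma=config.image_smoothing_voxels)

    image = VolumeImage(img, spacing)
    return (
        image,
        LabelMask.on_grid_of(image, pancreas.astype(np.uint8)),
        LabelMask.on_grid_of(image, tumor.astype(np.uint8)),
    )


# ---------------------------------------------------------------------------
# interval deformation
# ---------------------------------------------------------------------------


def _smooth_field_fast(shape, sigma_vox, rng) -> np.ndarray:
    """White noise smoothed to a correlated field, synthesized on a coarse
    grid when the correlation length spans many voxels (same statistics,
    much cheaper)."""
    factors = [max(1, int(s / 2.0)) for s in sigma_vox]
    coarse_shape = [max(4, -(-n // f)) for n, f in zip(shape, factors)]
    coarse_sigma = [s / f for s, f in zip(sigma_vox, factors)]
    f = ndimage.gaussian_filter(rng.standard_normal(coarse_shape), sigma=coarse_sigma, truncate=3.0)
    if tuple(coarse_shape) != tuple(shape):
        zoom = [n / c for n, c in zip(shape, coarse_shape)]
        f = ndimage.zoom(f, zoom, order=1, mode="nearest")
    return f


def _random_velocity(config: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth random stationary velocity field (mm), max magnitude = amplitude."""
    shape = tuple(config.grid_shape)
    spacing = np.asarray(config.spacing)
    sig = config.deformation_correlation / spacing
    v = np.stack([_smooth_field_fast(shape, sig, rng) for _ in range(3)])
    mag = np.sqrt((v**2).sum(axis=0)).max()
    if mag > 0 and config.deformation_amplitude > 0:
        v *= config.deformation_amplitude / mag
    else:
        v[:] = 0.0
    return v.astype(np.float32)


def _radial_inverse_table(a: float, r_plateau: float, r_outer: float, r_max: float):
    """1D monotone forward radial profile g(r) and its inverse sample table."""
    r = np.linspace(0.0, max(r_max, r_outer) * 1.5, 4096)
    u = np.clip((r - r_plateau) / max(r_outer - r_plateau, 1e-9), 0.0, 1.0)
    blend = u * u * (3.0 - 2.0 * u)  # smoothstep
    g = r * (a + (1.0 - a) * blend)
    if np.any(np.diff(g) <= 0):
        raise ValueError(f"radial profile not monotone for scale {a:.3f}")
    return g, r


def make_interval_deformation(
    pre_image: VolumeImage,
    true_pancreas_pre: LabelMask,
    true_tumor_pre: LabelMask,
    rho: float,
    config: StudyConfig,
    seed_key: tuple[int, ...],
) -> tuple[DeformationField, VolumeImage, LabelMask, LabelMask]:
    """Apply a known diffeomorphic interval change with tumor volume ratio ρ.

    The forward map composes a global random diffeomorphism (exponential of
    a smooth stationary velocity field) with a local radial contraction
    centered at the tumor centroid, calibrated by bisection so the
    rasterized warped tumor volume is ``rho`` × the baseline volume.
    Returns the *inverse* mapping (restaging grid → baseline coordinates),
    which is the direction registration recovers and masks are propagated
    through, plus the restaging image and true restaging masks.
    """
    if not (0.0 < rho <= 1.3):
        raise ValueError(f"volume ratio must be in (0, 1.3], got {rho}")
    shape = tuple(config.grid_shape)
    spacing = np.asarray(config.spacing)
    rng = _rng(*seed_key)

    v = _random_velocity(config, rng)
    sp = spacing.reshape(3, 1, 1, 1).astype(np.float32)
    ginv_disp_mm = _fields.exp_velocity(-v / sp, n_steps=8) * sp  # G^-1 displacement

    pos = _physical_grid(shape, spacing).astype(np.float32)
    y = pos + ginv_disp_mm  # pre-space positions under the global inverse

    tum = true_tumor_pre.voxels.astype(bool)
    idx = np.argwhere(tum)
    center = (idx * spacing).mean(axis=0)
    d = y - center.reshape(3, 1, 1, 1).astype(np.float32)
    r = np.sqrt((d.astype(np.float64) ** 2).sum(axis=0))
    surf = np.sqrt((((idx * spacing) - center) ** 2).sum(axis=1)).max()
    r_plateau = surf + 2.0
    r_outer = r_plateau + 18.0
    v_pre = float(tum.sum())

    def field_for(a: float) -> DeformationField:
        g, rr = _radial_inverse_table(a, r_plateau, r_outer, float(r.max()))
        rinv = np.interp(r, g, rr)  # S^-1 radius
        scale = np.ones_like(r)
        nz = r > 1e-9
        scale[nz] = rinv[nz] / r[nz]
        mapped = center.reshape(3, 1, 1, 1) + d * scale[None].astype(np.float32)
        return DeformationField(
            (mapped - pos).astype(np.float32),
            tuple(config.spacing),
            pre_image.origin,
            provenance={"kind": "synthetic_truth", "rho": rho, "radial_scale": a},
        )

    def ratio_for(field: DeformationField) -> float:
        warped = warp_mask(true_tumor_pre, field, method="nn")
        return float(warped.voxels.sum()) / v_pre

    # bisection on the forward radial scale; ratio increases with a
    a_lo, a_hi = 0.75 * rho ** (1 / 3), min(1.3 * rho ** (1 / 3), 1.35)
    f_lo, f_hi = ratio_for(field_for(a_lo)), ratio_for(field_for(a_hi))
    tries = 0
    while f_lo > rho and tries < 4:
        a_lo *= 0.85
        f_lo = ratio_for(field_for(a_lo))
        tries += 1
    while f_hi < rho and tries < 8:
        a_hi *= 1.1
        f_hi = ratio_for(field_for(a_hi))
        tries += 1
    a = (a_lo + a_hi) / 2
    for _ in range(20):
        a = 0.5 * (a_lo + a_hi)
        fr = ratio_for(field_for(a))
        if abs(fr - rho) <= 0.02 * rho:
            break
        if fr < rho:
            a_lo = a
        else:
            a_hi = a
    field = field_for(a)

    jac = jacobian_determinant(field)
    if float(jac[1:-1, 1:-1, 1:-1].min()) <= 0:
        raise ValueError("requested deformation amplitude breaks diffeomorphism")

    disp_vox = field.displacement_voxels()
    post_vox = _fields.warp_linear(np.asarray(pre_image.voxels, dtype=np.float32), disp_vox)
    post_vox = post_vox.astype(np.float64)
    if config.image_noise_sigma > 0:
        post_vox += rng.normal(0.0, config.image_noise_sigma, size=shape)
    post_image = VolumeImage(post_vox, pre_image.spacing, pre_image.origin)

    pancreas_post = warp_mask(true_pancreas_pre, field, method="nn")
    tumor_post = warp_mask(true_tumor_pre, field, method="nn")
    return field, post_image, pancreas_post, tumor_post


# ---------------------------------------------------------------------------
# reader model
# ---------------------------------------------------------------------------


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance to the region boundary (mm, negative inside).

    The voxel-to-voxel EDT measures distance to the nearest voxel *center*
    across the boundary; the surface itself lies closer — half a step for a
    face-on boundary, less for oblique incidence (~0.38 steps averaged over
    directions on rasterized spheres).  That mean offset is subtracted so
    the zero level set sits on the surface rather than the far centers.
    """
    inside = mask.astype(bool)
    delta = 0.38 * float(min(spacing))
    d_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
    d_in = ndimage.distance_transform_edt(inside, sampling=spacing)
    return np.where(inside, -(d_in - delta), d_out - delta)


def _smooth_unit_field(shape, spacing, corr_mm, rng) -> np.ndarray:
    sig = np.asarray(corr_mm) / np.asarray(spacing)
    f = _smooth_field_fast(shape, sig, rng)
    sd = f.std()
    return f / sd if sd > 0 else f


def _measurable(mask: LabelMask) -> bool:
    """True if bidimensional diameters can be annotated on the mask."""
    longest = response.longest_axial_diameter(mask)
    return longest.length > 0 and response.perpendicular_diameter(mask, longest) > 0


def _reader_mask_from_sdf(
    sdf: np.ndarray,
    geometry: LabelMask,
    params: ReaderNoiseParams,
    seed_key: tuple[int, ...],
    require_measurable: bool = False,
) -> LabelMask:
    for attempt in range(10):
        rng = _rng(*seed_key, attempt)
        if params.sigma_boundary > 0:
            eps = params.sigma_boundary * _smooth_unit_field(
                geometry.shape, geometry.spacing, params.correlation_length, rng
            )
        else:
            eps = 0.0
        vox = (sdf <= params.tau_bias + eps).astype(np.uint8)
        if vox.any():
            mask = LabelMask.on_grid_of(geometry, vox)
            # a reader would not submit a lesion contour too degenerate to
            # measure; resample such draws like empty ones
            if not require_measurable or _measurable(mask):
                return mask
    raise RuntimeError("reader simulation produced an empty mask 10 times; degenerate parameters")


def simulate_reader(
    true_mask: LabelMask, params: ReaderNoiseParams, seed_key: tuple[int, ...]
) -> LabelMask:
    """One reader's segmentation of a true region.

    The reader mask is the sublevel set ``SDF(x) <= tau_bias + eps(x)`` of
    the true signed distance, where ``eps`` is a smooth zero-mean Gaussian
    field (pointwise sd ``sigma_boundary``, correlation length
    ``correlation_length``).  Empty results are resampled with an
    incremented seed, at most 10 times.
    """
    sdf = _signed_distance(true_mask.voxels, true_mask.spacing)
    return _reader_mask_from_sdf(sdf, true_mask, params, seed_key)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _draw_rho(config: StudyConfig, rng: np.random.Generator) -> float:
    for _ in range(1000):
        rho = float(np.exp(np.log(config.rho_median) + config.rho_log_sd * rng.standard_normal()))
        if config.rho_min < rho < config.rho_max:
            return rho
    raise RuntimeError("volume-ratio distribution rejection sampling failed")


def _annotate(
    patient_idx: int,
    reader_idx: int,
    reader_id: str,
    experience: str,
    timepoint: str,
    truth_pancreas: LabelMask,
    truth_tumor: LabelMask,
    config: StudyConfig,
    sdf_cache: dict | None = None,
) -> ReaderAnnotation:
    seed = config.seed
    masks = {}
    for s_idx, structure in enumerate(_STRUCTURES):
        params = config.noise_for(experience, structure, timepoint)
        true_mask = truth_pancreas if structure == "pancreas" else truth_tumor
        key = (seed, patient_idx, _TAG_READER + reader_idx, _TIMEPOINTS.index(timepoint), s_idx)
        cache_key = (timepoint, structure)
        if sdf_cache is not None and cache_key in sdf_cache:
            sdf = sdf_cache[cache_key]
        else:
            sdf = _signed_distance(true_mask.voxels, true_mask.spacing)
            if sdf_cache is not None:
                sdf_cache[cache_key] = sdf
        masks[structure] = _reader_mask_from_sdf(
            sdf, true_mask, params, key, require_measurable=(structure == "tumor")
        )
    longest = response.longest_axial_diameter(masks["tumor"])
    perp = response.perpendicular_diameter(masks["tumor"], longest)
    return ReaderAnnotation(
        reader_id=reader_id,
        experience=experience,
        timepoint=timepoint,
        pancreas_mask=masks["pancreas"],
        tumor_mask=masks["tumor"],
        longest_diameter=longest.length,
        perpendicular_diameter=perp,
        slice_index=longest.slice_index,
    )


def _calibrate_censoring(times: np.ndarray, u: np.ndarray, target: float) -> np.ndarray:
    """Uniform(0, C) censoring times with C tuned to the target censored fraction."""
    if target <= 0:
        return np.full_like(times, np.inf)
    scale = float(np.median(times))
    lo, hi = 1e-3 * scale, 200.0 * scale
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(u * mid < times))
        if frac > target:
            lo = mid
        else:
            hi = mid
    return u * 0.5 * (lo + hi)


def _simulate_survival(
    patient_ids: list[str], true_db: np.ndarray, config: StudyConfig
) -> list[SurvivalRecord]:
    sd = true_db.std()
    z = (true_db - true_db.mean()) / sd if sd > 0 else np.zeros_like(true_db)
    records = []
    for e_idx, (endpoint, median_days) in enumerate(
        (("OS", config.os_median_days), ("RFS", config.rfs_median_days))
    ):
        rng = _rng(config.seed, _TAG_SURVIVAL, e_idx)
        h0 = np.log(2.0) / median_days
        hazards = h0 * np.exp(config.survival_beta * z)
        times = rng.exponential(1.0 / hazards)
        u = rng.uniform(size=len(times))
        cens = _calibrate_censoring(times, u, config.censoring_fraction)
        for pid, t, c in zip(patient_ids, times, cens):
            observed = min(t, c)
            records.append(
                SurvivalRecord(
                    patient_id=pid,
                    time=max(float(observed), 1e-3),
                    event=int(t <= c),
                    endpoint=endpoint,
                )
            )
    return records


def generate_cohort(config: StudyConfig) -> Cohort:
    """Simulate the full study described by ``config`` (deterministic)."""
    patients = []
    for p_idx in range(config.n_patients):
        pid = f"P{p_idx:03d}"
        pre_image, panc_pre, tum_pre = make_phantom(config, (config.seed, p_idx, _TAG_PHANTOM))
        rho = _draw_rho(config, _rng(config.seed, p_idx, _TAG_RHO))
        field, post_image, panc_post, tum_post = make_interval_deformation(
            pre_image, panc_pre, tum_pre, rho, config, (config.seed, p_idx, _TAG_DEFORM)
        )
        ratio = mask_volume(tum_post) / mask_volume(tum_pre)
        pathology = response.longest_axial_diameter(tum_post).length
        truth = PatientTruth(
            pre_image=pre_image,
            post_image=post_image,
            true_pancreas_pre=panc_pre,
            true_pancreas_post=panc_post,
            true_tumor_pre=tum_pre,
            true_tumor_post=tum_post,
            true_deformation=field,
            true_volume_ratio=ratio,
            rho_target=rho,
            true_pathology_diameter=pathology,
        )
        annotations = {}
        sdf_cache: dict = {}
        for r_idx, spec in enumerate(config.readers):
            for tp in _TIMEPOINTS:
                truth_p = panc_pre if tp == "pre" else panc_post
                truth_t = tum_pre if tp == "pre" else tum_post
                annotations[(spec.reader_id, tp)] = _annotate(
                    p_idx, r_idx, spec.reader_id, spec.experience, tp, truth_p, truth_t, config, sdf_cache
                )
        patients.append(PatientData(patient_id=pid, truth=truth, annotations=annotations))

    ids = [p.patient_id for p in patients]
    dbs = np.array([p.truth.true_db for p in patients])
    survival = _simulate_survival(ids, dbs, config)
    return Cohort(config=config, patients=tuple(patients), survival=tuple(survival))


# ---------------------------------------------------------------------------
# on-disk layout (CLI `simulate`)
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write images, masks, annotation/survival/truth tables, and config.

    Layout: ``<outdir>/<patient_id>/{pre,post}_image.nii.gz``, true masks
    alongside, reader masks as
    ``<patient>/reader_<id>_<tp>_{pancreas,tumor}.nii.gz``, plus
    ``annotations.csv``, ``survival.csv``, ``truth.csv``, ``config.json``
    at the top level.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        pdir = outdir / p.patient_id
        pdir.mkdir(exist_ok=True)
        write_volume(p.truth.pre_image, pdir / "pre_image.nii.gz")
        write_volume(p.truth.post_image, pdir / "post_image.nii.gz")
        write_mask(p.truth.true_pancreas_pre, pdir / "true_pancreas_pre.nii.gz")
        write_mask(p.truth.true_pancreas_post, pdir / "true_pancreas_post.nii.gz")
        write_mask(p.truth.true_tumor_pre, pdir / "true_tumor_pre.nii.gz")
        write_mask(p.truth.true_tumor_post, pdir / "true_tumor_post.nii.gz")
        for (rid, tp), ann in sorted(p.annotations.items()):
            write_mask(ann.pancreas_mask, pdir / f"reader_{rid}_{tp}_pancreas.nii.gz")
            write_mask(ann.tumor_mask, pdir / f"reader_{rid}_{tp}_tumor.nii.gz")
            rows.append((p.patient_id, ann))
    write_annotations(annotations_to_frame(rows), outdir / "annotations.csv")
    write_survival(cohort.survival, outdir / "survival.csv")
    cohort.truth_frame().to_csv(outdir / "truth.csv", index=False)
    cohort.config.to_json(outdir / "config.json")
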