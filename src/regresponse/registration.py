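"""Diffeomorphic intensity-based deformable registration.

A self-contained log-domain demons-style engine: a stationary velocity
field is greedily optimized over a multiresolution pyramid, exponentiated
by scaling-and-squaring at every step, with dual Gaussian regularization
("fluid" smoothing of each incremental force, "elastic" smoothing of the
accumulated velocity).  The similarity metric is local normalized
cross-correlation (LNCC) by default, which is insensitive to affine
intensity changes between timepoints; sum-of-squared-differences is
available as a cheaper alternative.

The engine is *unsupervised* in the strict sense required by the
registration-assisted response workflow: :func:`register` sees only the
two intensity images — segmentations never influence the recovered
mapping, so all readers' baseline regions of interest are propagated
through one and the same patient-level field.

Convention: the *fixed* image is the restaging (post-treatment) scan and
the *moving* image is the baseline scan.  The recovered field lives on the
fixed grid and maps fixed-grid points into moving-image physical space, so
warping a baseline mask through it carries the region forward in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np
from scipy import ndimage

from . import _fields
from .imaging import GeometryError, LabelMask, VolumeImage

__all__ = [
    "RegistrationParams",
    "DeformationField",
    "RegistrationError",
    "register",
    "warp_mask",
    "warp_image",
    "jacobian_determinant",
    "compose_fields",
]


class RegistrationError(RuntimeError):
    """Raised when registration fails its diffeomorphism or geometry contract."""


@dataclass(frozen=True)
class RegistrationParams:
    """Tunable parameters of the demons engine (defaults are study defaults)."""

    n_levels: int = 3
    iterations: tuple[int, ...] = (100, 80, 60)  # coarsest -> finest
    metric: str = "lncc"  # "lncc" | "ssd"
    lncc_window: int = 5  # voxels, isotropic window edge
    sigma_fluid: float = 2.0  # mm, smoothing of each incremental update
    sigma_elastic: float = 1.0  # mm, smoothing of the accumulated velocity
    step: float = 1.0  # mm, max displacement added per accepted iteration
    ss_steps: int = 6  # scaling-and-squaring cap
    conv_tol: float = 1e-4  # relative metric change ...
    conv_window: int = 5  # ... over this many iterations

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if len(self.iterations) != self.n_levels:
            raise ValueError("iterations must have one entry per level")
        if self.metric not in ("lncc", "ssd"):
            raise ValueError(f"unknown metric {self.metric!r}")
        for name in ("sigma_fluid", "sigma_elastic", "step", "conv_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class DeformationField:
    """Dense mapping from the fixed grid into moving-image physical space.

    ``displacement`` has shape ``(3, nx, ny, nz)`` in millimetres: the
    mapped physical position of fixed voxel ``(i, j, k)`` is its own
    physical position plus ``displacement[:, i, j, k]``.
    """

    displacement: np.ndarray  # (3, nx, ny, nz), mm
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=np.float32)
        if disp.ndim != 4 or disp.shape[0] != 3:
            raise ValueError(f"displacement must have shape (3, nx, ny, nz), got {disp.shape}")
        if not np.all(np.isfinite(disp)):
            raise ValueError("non-finite displacement values")
        object.__setattr__(self, "displacement", disp)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[1:]  # type: ignore[return-value]

    def displacement_voxels(self) -> np.ndarray:
        """Displacement in voxel units of the (shared) grid."""
        sp = np.asarray(self.spacing, dtype=np.float32).reshape(3, 1, 1, 1)
        return self.displacement / sp

    @classmethod
    def identity(cls, shape: tuple[int, int, int], spacing, origin=(0.0, 0.0, 0.0)) -> "DeformationField":
        return cls(np.zeros((3, *shape), dtype=np.float32), tuple(spacing), tuple(origin))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rescale_intensity(img: np.ndarray) -> np.ndarray:
    """Robust rescale to [0, 1] (1st-99th percentile window)."""
    lo, hi = np.percentile(img, [1.0, 99.0])
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float32)
    out = (img.astype(np.float32) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def _downsample(img: np.ndarray) -> np.ndarray:
    sm = ndimage.gaussian_filter(img, sigma=1.0, truncate=2.0)
    return np.ascontiguousarray(sm[::2, ::2, ::2], dtype=np.float32)


def _upsample_field(v: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    out = np.empty((3, *shape), dtype=np.float32)
    factors = [t / s for t, s in zip(shape, v.shape[1:])]
    for c in range(3):
        out[c] = ndimage.zoom(v[c], factors, order=1, mode="nearest", grid_mode=False)
    return out


def _smooth_field(v: np.ndarray, sigma_mm: float, spacing: np.ndarray) -> np.ndarray:
    sig_vox = sigma_mm / spacing
    for c in range(3):
        ndimage.gaussian_filter(v[c], sigma=sig_vox, output=v[c], truncate=2.0)
    return v


def _gradient_mm(img: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    g = np.gradient(img, *spacing)
    return np.stack([gi.astype(np.float32) for gi in g])


class _LnccForce:
    """LNCC metric and ascent force, with fixed-image stats precomputed.

    The force uses the *symmetric* spatial gradient (mean of fixed and
    warped-image gradients), which removes most of the sub-voxel boundary
    bias that a one-sided gradient produces when edge profiles differ
    between timepoints.
    """

    def __init__(self, fixed: np.ndarray, window: int, spacing: np.ndarray):
        self.window = window
        self.spacing = spacing
        self.mean_f = ndimage.uniform_filter(fixed, window)
        self.fc = fixed - self.mean_f
        self.var_f = ndimage.uniform_filter(self.fc * self.fc, window)
        self.grad_f = _gradient_mm(fixed, spacing)
        self.eps = 1e-5

    def __call__(self, warped: np.ndarray) -> tuple[float, np.ndarray]:
        w = self.window
        mean_w = ndimage.uniform_filter(warped, w)
        wc = warped - mean_w
        var_w = ndimage.uniform_filter(wc * wc, w)
        cov = ndimage.uniform_filter(self.fc * wc, w)
        denom = self.var_f * var_w
        valid = denom > self.eps**2
        cc = np.zeros_like(warped)
        np.divide(cov * cov, denom, out=cc, where=valid)
        loss = -float(cc[valid].mean()) if valid.any() else 0.0
        # d(cc)/d(warped) = 2 cov / denom * (fc - cov/var_w * wc)
        coef = np.zeros_like(warped)
        np.divide(2.0 * cov, denom, out=coef, where=valid)
        ratio = np.zeros_like(warped)
        np.divide(cov, var_w, out=ratio, where=var_w > self.eps**2)
        dcc = coef * (self.fc - ratio * wc)
        grad = 0.5 * (_gradient_mm(warped, self.spacing) + self.grad_f)
        force = dcc[None] * grad
        return loss, force


class _SsdForce:
    """Classic demons force for the SSD metric."""

    def __init__(self, fixed: np.ndarray, spacing: np.ndarray):
        self.fixed = fixed
        self.spacing = spacing
        self.kappa2 = float(np.mean(spacing)) ** 2

    def __call__(self, warped: np.ndarray) -> tuple[float, np.ndarray]:
        diff = self.fixed - warped
        loss = float(np.mean(diff * diff))
        grad = _gradient_mm(warped, self.spacing)
        gsq = (grad**2).sum(axis=0)
        denom = gsq + diff * diff / self.kappa2
        coef = np.zeros_like(diff)
        np.divide(diff, denom, out=coef, where=denom > 1e-9)
        return loss, coef[None] * grad


def _optimize_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    v_mm: np.ndarray,
    spacing: np.ndarray,
    params: RegistrationParams,
    n_iter: int,
) -> np.ndarray:
    sp = spacing.reshape(3, 1, 1, 1).astype(np.float32)
    if params.metric == "lncc":
        force_fn = _LnccForce(fixed, params.lncc_window, spacing)
    else:
        force_fn = _SsdForce(fixed, spacing)

    step = params.step
    min_step = 0.05 * params.step

    def evaluate(v):
        u = _fields.exp_velocity(v / sp, params.ss_steps)
        warped = _fields.warp_linear(moving, u)
        loss, force = force_fn(warped)
        return loss, force

    best_v = v_mm.copy()
    best_loss, force = evaluate(best_v)
    history = [best_loss]
    for _ in range(n_iter):
        upd = _smooth_field(force.astype(np.float32), params.sigma_fluid, spacing)
        mag = np.sqrt((upd**2).sum(axis=0)).max()
        if mag < 1e-12:
            break
        upd *= step / mag
        cand = best_v + upd
        cand = _smooth_field(cand, params.sigma_elastic, spacing)
        loss, cand_force = evaluate(cand)
        if loss < best_loss:
            best_v = cand
            best_loss = loss
            force = cand_force
            history.append(best_loss)
            if len(history) > params.conv_window:
                past = history[-params.conv_window - 1]
                if abs(past - best_loss) < params.conv_tol * max(abs(past), 1e-12):
                    break
        else:
            step *= 0.6
            if step < min_step:
                break
    return best_v


def register(
    fixed: VolumeImage,
    moving: VolumeImage,
    params: Optional[RegistrationParams] = None,
) -> DeformationField:
    """Register ``moving`` onto ``fixed``; returns the fixed→moving mapping.

    The two images must share grid shape and spacing (same physical extent
    within one voxel).  The returned field satisfies the diffeomorphism
    contract (positive Jacobian determinant everywhere) or an error is
    raised.
    """
    params = params or RegistrationParams()
    if fixed.shape != moving.shape:
        raise GeometryError(f"image shapes differ: {fixed.shape} vs {moving.shape}")
    if not np.allclose(fixed.spacing, moving.spacing, atol=1e-3):
        raise GeometryError(f"image spacings differ: {fixed.spacing} vs {moving.spacing}")
    max_sp = max(fixed.spacing)
    if not np.allclose(fixed.origin, moving.origin, atol=max_sp):
        raise GeometryError("image origins differ by more than one voxel")

    fix = _rescale_intensity(np.asarray(fixed.voxels))
    mov = _rescale_intensity(np.asarray(moving.voxels))

    # image pyramid, coarsest first
    pyramid = [(fix, mov, np.asarray(fixed.spacing, dtype=np.float64))]
    for _ in range(params.n_levels - 1):
        f, m, sp = pyramid[0]
        if min(f.shape) < 8:
            break
        pyramid.insert(0, (_downsample(f), _downsample(m), sp * 2.0))
    iters = params.iterations[-len(pyramid):]

    v_mm = np.zeros((3, *pyramid[0][0].shape), dtype=np.float32)
    for level, ((f, m, sp), n_iter) in enumerate(zip(pyramid, iters)):
        if level > 0:
            v_mm = _upsample_field(v_mm, f.shape)
        v_mm = _optimize_level(f, m, v_mm, sp.astype(np.float32), params, n_iter)

    sp = np.asarray(fixed.spacing, dtype=np.float32).reshape(3, 1, 1, 1)
    disp_vox = _fields.exp_velocity(v_mm / sp, params.ss_steps)
    disp_mm = disp_vox * sp
    out = DeformationField(
        displacement=disp_mm,
        spacing=fixed.spacing,
        origin=fixed.origin,
        provenance={"metric": params.metric, "n_levels": len(pyramid)},
    )
    jac = jacobian_determinant(out)
    jmin = float(jac[1:-1, 1:-1, 1:-1].min())
    if jmin <= 0:
        raise RegistrationError(f"non-diffeomorphic result: min Jacobian {jmin:.4f}")
    return out


def warp_image(image: VolumeImage, field: DeformationField) -> VolumeImage:
    """Resample ``image`` through ``field`` onto the fixed grid (linear)."""
    if not np.allclose(image.spacing, field.spacing, atol=1e-3):
        raise GeometryError("image/field spacing mismatch")
    u = field.displacement_voxels()
    # account for origin offset between fixed grid and the sampled image
    off = (np.asarray(field.origin) - np.asarray(image.origin)) / np.asarray(image.spacing)
    if np.any(np.abs(off) > 1e-9):
        u = u + off.astype(np.float32).reshape(3, 1, 1, 1)
    out = _fields.warp_linear(np.asarray(image.voxels, dtype=np.float32), u)
    return VolumeImage(out.astype(np.float64), field.spacing, field.origin)


def warp_mask(mask: LabelMask, field: DeformationField, method: str = "linear") -> LabelMask:
    """Propagate a mask through a deformation field onto the fixed grid.

    The binary mask is interpolated as a [0, 1] function and thresholded at
    0.5 (``method="linear"``), or resampled nearest-neighbor
    (``method="nn"``).
    """
    if mask.shape != field.shape:
        raise GeometryError(f"mask shape {mask.shape} does not match field {field.shape}")
    if not np.allclose(mask.spacing, field.spacing, atol=1e-3):
        raise GeometryError("mask/field spacing mismatch")
    u = field.displacement_voxels()
    off = (np.asarray(field.origin) - np.asarray(mask.origin)) / np.asarray(mask.spacing)
    if np.any(np.abs(off) > 1e-9):
        u = u + off.astype(np.float32).reshape(3, 1, 1, 1)
    src = mask.voxels.astype(np.float32)
    if method == "linear":
        out = _fields.warp_linear(src, u) >= 0.5
    elif method == "nn":
        out = _fields.warp_nn(src, u) >= 0.5
    else:
        raise ValueError(f"unknown method {method!r}")
    return LabelMask(out.astype(np.uint8), field.spacing, field.origin)


def jacobian_determinant(field: DeformationField) -> np.ndarray:
    """Pointwise Jacobian determinant of the mapping ``x + u(x)``.

    Derivatives are central differences in physical coordinates (one-sided
    at volume borders); the identity field gives 1.0 everywhere.
    """
    sp = field.spacing
    disp = field.displacement.astype(np.float64)
    jac = np.empty((3, 3, *field.shape))
    for c in range(3):
        grads = np.gradient(disp[c], *sp)
        for a in range(3):
            jac[c, a] = grads[a]
        jac[c, c] += 1.0
    a, b, c = jac[0], jac[1], jac[2]
    det = (
        a[0] * (b[1] * c[2] - b[2] * c[1])
        - a[1] * (b[0] * c[2] - b[2] * c[0])
        + a[2] * (b[0] * c[1] - b[1] * c[0])
    )
    return det


def compose_fields(first: DeformationField, second: DeformationField) -> DeformationField:
    """Composition: apply ``first`` (on its grid), then ``second`` at the mapped points."""
    if first.shape != second.shape or not np.allclose(first.spacing, second.spacing, atol=1e-3):
        raise GeometryError("fields must share a grid for composition")
    sp = np.asarray(first.spacing, dtype=np.float32).reshape(3, 1, 1, 1)
    u = first.displacement / sp
    v = second.displacement / sp
    comp = _fields.compose_disp(u, v)
    return DeformationField(comp * sp, first.spacing, first.origin)
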