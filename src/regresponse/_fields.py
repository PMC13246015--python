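"""Low-level dense-field primitives (numba kernels).

All kernels work in *voxel units* on a single grid: a displacement field
``u`` has shape ``(3, nx, ny, nz)`` and ``u[:, i, j, k]`` is the offset, in
fractional voxels, from grid point ``(i, j, k)``.  Out-of-volume samples
are clamped to the nearest edge.  Conversion to/from physical millimetres
happens in the callers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "compose_disp",
    "warp_linear",
    "warp_nn",
    "exp_velocity",
    "identity_grid",
]


@njit(cache=True, fastmath=True)
def _compose_disp(u, v, out):  # pragma: no cover - exercised via wrapper
    # out(x) = v(x + u(x)) + u(x)
    nx, ny, nz = u.shape[1], u.shape[2], u.shape[3]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                x = i + u[0, i, j, k]
                y = j + u[1, i, j, k]
                z = k + u[2, i, j, k]
                if x < 0.0:
                    x = 0.0
                elif x > nx - 1:
                    x = nx - 1.0
                if y < 0.0:
                    y = 0.0
                elif y > ny - 1:
                    y = ny - 1.0
                if z < 0.0:
                    z = 0.0
                elif z > nz - 1:
                    z = nz - 1.0
                x0 = int(x)
                y0 = int(y)
                z0 = int(z)
                x1 = min(x0 + 1, nx - 1)
                y1 = min(y0 + 1, ny - 1)
                z1 = min(z0 + 1, nz - 1)
                fx = x - x0
                fy = y - y0
                fz = z - z0
                for c in range(3):
                    c00 = v[c, x0, y0, z0] * (1 - fx) + v[c, x1, y0, z0] * fx
                    c10 = v[c, x0, y1, z0] * (1 - fx) + v[c, x1, y1, z0] * fx
                    c01 = v[c, x0, y0, z1] * (1 - fx) + v[c, x1, y0, z1] * fx
                    c11 = v[c, x0, y1, z1] * (1 - fx) + v[c, x1, y1, z1] * fx
                    c0 = c00 * (1 - fy) + c10 * fy
                    c1 = c01 * (1 - fy) + c11 * fy
                    out[c, i, j, k] = c0 * (1 - fz) + c1 * fz + u[c, i, j, k]


@njit(cache=True, fastmath=True)
def _warp_linear(img, u, out):  # pragma: no cover
    nx, ny, nz = img.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                x = i + u[0, i, j, k]
                y = j + u[1, i, j, k]
                z = k + u[2, i, j, k]
                if x < 0.0:
                    x = 0.0
                elif x > nx - 1:
                    x = nx - 1.0
                if y < 0.0:
                    y = 0.0
                elif y > ny - 1:
                    y = ny - 1.0
                if z < 0.0:
                    z = 0.0
                elif z > nz - 1:
                    z = nz - 1.0
                x0 = int(x)
                y0 = int(y)
                z0 = int(z)
                x1 = min(x0 + 1, nx - 1)
                y1 = min(y0 + 1, ny - 1)
                z1 = min(z0 + 1, nz - 1)
                fx = x - x0
                fy = y - y0
                fz = z - z0
                c00 = img[x0, y0, z0] * (1 - fx) + img[x1, y0, z0] * fx
                c10 = img[x0, y1, z0] * (1 - fx) + img[x1, y1, z0] * fx
                c01 = img[x0, y0, z1] * (1 - fx) + img[x1, y0, z1] * fx
                c11 = img[x0, y1, z1] * (1 - fx) + img[x1, y1, z1] * fx
                c0 = c00 * (1 - fy) + c10 * fy
                c1 = c01 * (1 - fy) + c11 * fy
                out[i, j, k] = c0 * (1 - fz) + c1 * fz


@njit(cache=True, fastmath=True)
def _warp_nn(img, u, out):  # pragma: no cover
    nx, ny, nz = img.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                x = i + u[0, i, j, k]
                y = j + u[1, i, j, k]
                z = k + u[2, i, j, k]
                xi = int(round(x))
                yi = int(round(y))
                zi = int(round(z))
                if xi < 0:
                    xi = 0
                elif xi > nx - 1:
                    xi = nx - 1
                if yi < 0:
                    yi = 0
                elif yi > ny - 1:
                    yi = ny - 1
                if zi < 0:
                    zi = 0
                elif zi > nz - 1:
                    zi = nz - 1
                out[i, j, k] = img[xi, yi, zi]


def _f32(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(a, dtype=np.float32)


def compose_disp(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Compose two voxel-unit displacement fields: result of ``x -> x+u`` then ``x -> x+v``."""
    u = _f32(u)
    v = _f32(v)
    out = np.empty_like(u)
    _compose_disp(u, v, out)
    return out


def warp_linear(img: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Trilinearly sample ``img`` at ``x + u(x)`` with edge clamping."""
    img = _f32(img)
    out = np.empty_like(img)
    _warp_linear(img, _f32(u), out)
    return out


def warp_nn(img: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Nearest-neighbor sample of ``img`` at ``x + u(x)``."""
    img = _f32(img)
    out = np.empty_like(img)
    _warp_nn(img, _f32(u), out)
    return out


def exp_velocity(v: np.ndarray, n_steps: int = 6) -> np.ndarray:
    """Exponentiate a stationary velocity field by scaling and squaring.

    ``v`` is a voxel-unit velocity field; the result is the voxel-unit
    displacement of ``exp(v)``.  ``n_steps`` caps the number of squarings;
    fewer are used when the field is already small (max half-voxel initial
    step), which loses no accuracy.
    """
    v = _f32(v)
    vmax = float(np.sqrt((v**2).sum(axis=0)).max())
    if vmax == 0.0:
        return v.copy()
    needed = int(np.ceil(np.log2(max(vmax / 0.5, 1e-12))))
    k = int(min(max(needed, 1), n_steps))
    u = v / (2.0**k)
    for _ in range(k):
        u = compose_disp(u, u)
    return u


def identity_grid(shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel-index grid, shape ``(3, nx, ny, nz)`` (float32)."""
    return np.indices(shape, dtype=np.float32)
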