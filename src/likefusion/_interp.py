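"""Trilinear interpolation kernels for map composition and image warping.

Edge-clamped (coordinates outside the grid are clamped to the boundary),
matching ``scipy.ndimage.map_coordinates(order=1, mode="nearest")``, which is
also the fallback when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    import numba as _nb

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _interp_image_scipy(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    from scipy.ndimage import map_coordinates

    return map_coordinates(image, coords, order=1, mode="nearest", output=np.float32)


if _HAVE_NUMBA:

    @_nb.njit(fastmath=True, cache=False)
    def _trilerp_core(field: np.ndarray, coords: np.ndarray, out: np.ndarray) -> None:
        # field: (C, n0, n1, n2); coords: (3, N) flat; out: (C, N)
        n0, n1, n2 = field.shape[1], field.shape[2], field.shape[3]
        n_ch = field.shape[0]
        n = coords.shape[1]
        for i in range(n):
            x = min(max(coords[0, i], 0.0), n0 - 1.0)
            y = min(max(coords[1, i], 0.0), n1 - 1.0)
            z = min(max(coords[2, i], 0.0), n2 - 1.0)
            x0 = int(x)
            y0 = int(y)
            z0 = int(z)
            x1 = min(x0 + 1, n0 - 1)
            y1 = min(y0 + 1, n1 - 1)
            z1 = min(z0 + 1, n2 - 1)
            fx = x - x0
            fy = y - y0
            fz = z - z0
            w000 = (1 - fx) * (1 - fy) * (1 - fz)
            w001 = (1 - fx) * (1 - fy) * fz
            w010 = (1 - fx) * fy * (1 - fz)
            w011 = (1 - fx) * fy * fz
            w100 = fx * (1 - fy) * (1 - fz)
            w101 = fx * (1 - fy) * fz
            w110 = fx * fy * (1 - fz)
            w111 = fx * fy * fz
            for c in range(n_ch):
                out[c, i] = (
                    w000 * field[c, x0, y0, z0] + w001 * field[c, x0, y0, z1]
                    + w010 * field[c, x0, y1, z0] + w011 * field[c, x0, y1, z1]
                    + w100 * field[c, x1, y0, z0] + w101 * field[c, x1, y0, z1]
                    + w110 * field[c, x1, y1, z0] + w111 * field[c, x1, y1, z1]
                )

    def interp_channels(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
        """Interpolate a (C, n0, n1, n2) field at (3, ...) coords."""
        spatial = coords.shape[1:]
        flat = np.ascontiguousarray(coords.reshape(3, -1), dtype=np.float32)
        fld = np.ascontiguousarray(field, dtype=np.float32)
        out = np.empty((field.shape[0], flat.shape[1]), dtype=np.float32)
        _trilerp_core(fld, flat, out)
        return out.reshape((field.shape[0], *spatial))

else:  # pragma: no cover

    def interp_channels(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
        return np.stack([_interp_image_scipy(field[c], coords) for c in range(field.shape[0])])


def interp_image(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear sample of one scalar image at (3, ...) coords, edge clamp."""
    return interp_channels(image[None], coords)[0]
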